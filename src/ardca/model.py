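"""The autoregressive sequence model (arDCA).

The joint distribution over aligned sequences factorizes along a chosen site
order into soft-max conditionals,

    P(a_1, ..., a_L) = prod_k P(a_k | a_{k-1}, ..., a_1),
    P(a_k | prefix)  = exp( h_k(a_k) + sum_{j<k} J_kj(a_k, a_j) ) / z_k(prefix),

with local partition functions z_k summing the exponential over the q states.
Fields h and couplings J are indexed in MODEL (permuted) positions; every
public input/output — sequences, samples, per-site reports — is in ORIGINAL
alignment coordinates, with the permutation an internal detail.

Because every conditional is explicitly normalized, log P is exact: the model
gives normalized sequence probabilities, ancestral sampling is i.i.d. and
cheap, and the statistical energy is simply E = -log P.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .msa import DEFAULT_ALPHABET, Alphabet, EncodedMSA
from .ordering import SiteOrder, direct_order

_FORMAT_VERSION = 1


@dataclass
class ARModel:
    """Ordered autoregressive model with fields and triangular couplings.

    Attributes
    ----------
    h : (L, q) fields, h[k] for model position k
    J : list of length L; J[k] has shape (k, q, q) with J[k][j, a, b] the
        directed coupling from model position j (< k) onto position k
        (state a at k, state b at j).  J[0] is an empty (0, q, q) block.
    order : the column permutation (model position -> original column)
    meta : free-form training provenance (regularization, Meff, ...)
    """

    h: np.ndarray
    J: list[np.ndarray]
    order: SiteOrder
    alphabet: Alphabet = field(default_factory=lambda: DEFAULT_ALPHABET)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=np.float64)
        L, q = self.h.shape
        if self.order.L != L:
            raise ValueError("order length does not match fields")
        if len(self.J) != L:
            raise ValueError("J must have one block list per position")
        self.J = [np.asarray(Jk, dtype=np.float64).reshape(k, q, q)
                  for k, Jk in enumerate(self.J)]
        if not np.all(np.isfinite(self.h)) or any(
            not np.all(np.isfinite(Jk)) for Jk in self.J
        ):
            raise ValueError("parameters must be finite")

    @property
    def L(self) -> int:
        return self.h.shape[0]

    @property
    def q(self) -> int:
        return self.h.shape[1]

    # ----- conditionals ---------------------------------------------------

    def conditional_logits(self, k: int, prefix: np.ndarray) -> np.ndarray:
        """Unnormalized log-weights of P(a_k | prefix) at model position k."""
        prefix = np.asarray(prefix, dtype=np.int64)
        if len(prefix) != k:
            raise ValueError(f"prefix for position {k} must have length {k}")
        logits = self.h[k].copy()
        if k:
            logits += self.J[k][np.arange(k), :, prefix].sum(axis=0)
        return logits

    def conditional_distribution(self, k: int, prefix: np.ndarray) -> np.ndarray:
        """P(a_k = . | prefix) as a length-q probability vector.

        `prefix` holds the codes of model positions 0..k-1 (possibly empty).
        Computed with max-subtraction, sums to 1 to machine precision.
        """
        if k >= self.L:
            raise ValueError("position beyond model length")
        logits = self.conditional_logits(k, prefix)
        logits -= logits.max()
        p = np.exp(logits)
        return p / p.sum()

    # ----- exact probabilities and energies -------------------------------

    def _to_model_order(self, codes: np.ndarray) -> np.ndarray:
        return codes[..., list(self.order.perm)]

    def log_probability(self, sequence: np.ndarray) -> float:
        """Exact normalized log P of one sequence (original coordinates), nats."""
        return float(self.log_probability_many(np.atleast_2d(sequence))[0])

    def log_probability_many(self, codes: np.ndarray) -> np.ndarray:
        """Exact log P for an (n, L) batch of sequences, vectorized per site."""
        codes = np.asarray(codes, dtype=np.int64)
        if codes.ndim != 2 or codes.shape[1] != self.L:
            raise ValueError(f"sequences must have length L={self.L}")
        if codes.min() < 0 or codes.max() >= self.q:
            raise ValueError("invalid codes")
        perm = self._to_model_order(codes)
        n = codes.shape[0]
        logp = np.zeros(n)
        rows = np.arange(n)
        for k in range(self.L):
            logits = np.broadcast_to(self.h[k], (n, self.q)).copy()
            for j in range(k):
                logits += self.J[k][j][:, perm[:, j]].T
            logz = logsumexp(logits, axis=1)
            logp += logits[rows, perm[:, k]] - logz
        return logp

    def energy(self, sequence: np.ndarray) -> float:
        """Statistical energy E = -log P; lower is more family-like."""
        return -self.log_probability(sequence)

    def energy_many(self, codes: np.ndarray) -> np.ndarray:
        return -self.log_probability_many(codes)

    # ----- sampling -------------------------------------------------------

    def sample(self, n: int, seed: int) -> EncodedMSA:
        """Draw n i.i.d. sequences by ancestral sampling in model order.

        Output columns are mapped back to original alignment coordinates.
        Deterministic given the seed.
        """
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = np.random.default_rng(seed)
        perm_codes = np.empty((n, self.L), dtype=np.int64)
        for k in range(self.L):
            logits = np.broadcast_to(self.h[k], (n, self.q)).copy()
            for j in range(k):
                logits += self.J[k][j][:, perm_codes[:, j]].T
            logits -= logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            u = rng.random((n, 1))
            perm_codes[:, k] = (p.cumsum(axis=1) < u).sum(axis=1)
        codes = np.empty_like(perm_codes)
        codes[:, list(self.order.perm)] = perm_codes
        ids = [f"arDCA_sample_{k}|seed={seed}" for k in range(n)]
        return EncodedMSA(codes=codes, ids=ids, alphabet=self.alphabet)

    # ----- serialization --------------------------------------------------

    def save(self, path) -> None:
        """Write the model as a zip archive: JSON metadata + float64 arrays.

        Arrays are flat little-endian float64; archives written from the
        same model are byte-identical (fixed timestamps).
        """
        meta = {
            "format_version": _FORMAT_VERSION,
            "L": self.L,
            "q": self.q,
            "alphabet": self.alphabet.symbols,
            "order": list(self.order.perm),
            "order_label": self.order.label,
            "meta": self.meta,
        }
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            def _write(name: str, data: bytes) -> None:
                info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
                info.compress_type = zipfile.ZIP_DEFLATED
                zf.writestr(info, data)

            _write("meta.json", json.dumps(meta, sort_keys=True).encode())
            _write("h.f64", self.h.astype("<f8").tobytes())
            _write(
                "J.f64",
                b"".join(Jk.astype("<f8").tobytes() for Jk in self.J),
            )

    @classmethod
    def load(cls, path) -> "ARModel":
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            if meta.get("format_version") != _FORMAT_VERSION:
                raise ValueError(
                    f"unsupported model format version {meta.get('format_version')}"
                )
            L, q = meta["L"], meta["q"]
            h_raw = np.frombuffer(zf.read("h.f64"), dtype="<f8")
            if h_raw.size != L * q:
                raise ValueError("field array 'h' has wrong size for L, q")
            h = h_raw.reshape(L, q).copy()
            J_raw = np.frombuffer(zf.read("J.f64"), dtype="<f8")
            expect = q * q * (L * (L - 1)) // 2
            if J_raw.size != expect:
                raise ValueError("coupling array 'J' has wrong size for L, q")
            J = []
            pos = 0
            for k in range(L):
                n = k * q * q
                J.append(J_raw[pos : pos + n].reshape(k, q, q).copy())
                pos += n
        order = SiteOrder(perm=tuple(meta["order"]), label=meta["order_label"])
        alphabet = Alphabet(symbols=meta["alphabet"])
        return cls(h=h, J=J, order=order, alphabet=alphabet, meta=meta["meta"])


def uniform_model(L: int, q: int | None = None,
                  alphabet: Alphabet = DEFAULT_ALPHABET) -> ARModel:
    """All-zero parameters: the uniform distribution over q^L sequences."""
    if q is None:
        q = alphabet.q
    h = np.zeros((L, q))
    J = [np.zeros((k, q, q)) for k in range(L)]
    return ARModel(h=h, J=J, order=direct_order(L), alphabet=alphabet)


def enumerate_sequences(L: int, q: int) -> np.ndarray:
    """All q^L code vectors as a (q^L, L) array, lexicographic order."""
    grids = np.indices((q,) * L).reshape(L, -1).T
    return np.ascontiguousarray(grids, dtype=np.int64)
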