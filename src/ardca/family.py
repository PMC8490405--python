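"""Family-level analyses: entropy, sequence-space size, profile baseline,
generative evaluation, PCA projection and subfamily log-odds classification.

Because the autoregressive model yields exact normalized probabilities, the
family entropy S = -sum_x P(x) log P(x) equals the ensemble mean of the
statistical energy, <E>_P, and can be estimated from an i.i.d. model sample
with a Monte-Carlo standard error.  The effective number of sequences the
model considers family-like is N ~ exp(S), reported in log10 alongside the
total q^L and their ratio, all in log-space arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import ARModel, enumerate_sequences
from .msa import DEFAULT_ALPHABET, Alphabet, EncodedMSA, SequenceWeights
from .ordering import direct_order
from .stats import (compare_statistics, empirical_frequencies,
                    site_entropies)

LN10 = math.log(10.0)


# ---------------------------------------------------------------------------
# entropy and sequence-space size
# ---------------------------------------------------------------------------

@dataclass
class EntropyEstimate:
    """Monte-Carlo estimate of the model entropy (nats)."""

    S_total: float
    stderr: float
    n_samples: int
    seed: int
    L: int

    @property
    def S_per_site(self) -> float:
        return self.S_total / self.L

    @property
    def log10_N(self) -> float:
        """log10 of the effective sequence-space size exp(S)."""
        return self.S_total / LN10


def estimate_entropy(model: ARModel, n_samples: int = 10_000,
                     seed: int = 0) -> EntropyEstimate:
    """S = <E>_P over n i.i.d. model samples, with standard error."""
    if n_samples < 2:
        raise ValueError("need at least 2 samples for a standard error")
    sample = model.sample(n_samples, seed)
    E = model.energy_many(sample.codes)
    return EntropyEstimate(
        S_total=float(E.mean()),
        stderr=float(E.std(ddof=1) / math.sqrt(n_samples)),
        n_samples=n_samples, seed=seed, L=model.L,
    )


def exact_entropy(model: ARModel, cap: int = 10**6) -> float:
    """-sum_x P(x) log P(x) by full enumeration (oracle; q^L <= cap)."""
    n_states = model.q ** model.L
    if n_states > cap:
        raise ValueError(f"q^L = {n_states} exceeds enumeration cap {cap}")
    seqs = enumerate_sequences(model.L, model.q)
    logp = model.log_probability_many(seqs)
    return float(-(np.exp(logp) * logp).sum())


@dataclass
class SequenceSpaceReport:
    """Sequence-space size bookkeeping, all in log10 (no overflow)."""

    log10_N: float          # effective family size exp(L * S_per_site)
    log10_total: float      # all q^L sequences
    log10_fraction: float   # family fraction of sequence space

    @property
    def N(self) -> float:
        return 10.0 ** self.log10_N


def sequence_space_report(S_per_site: float, L: int, q: int) -> SequenceSpaceReport:
    """Effective size exp(L * S/L) vs total q^L, exact log10 arithmetic."""
    if L <= 0 or q <= 1:
        raise ValueError("need L >= 1 and q >= 2")
    log10_N = L * S_per_site / LN10
    log10_total = L * math.log10(q)
    return SequenceSpaceReport(
        log10_N=log10_N,
        log10_total=log10_total,
        log10_fraction=log10_N - log10_total,
    )


# ---------------------------------------------------------------------------
# profile (independent-site) baseline
# ---------------------------------------------------------------------------

@dataclass
class ProfileModel:
    """Independent-site baseline: P(a_1..a_L) = prod_i f_i(a_i)."""

    f: np.ndarray                      # (L, q), rows normalized
    alphabet: Alphabet = field(default_factory=lambda: DEFAULT_ALPHABET)

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=np.float64)
        if not np.allclose(self.f.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("profile rows must be normalized")

    @property
    def L(self) -> int:
        return self.f.shape[0]

    @property
    def q(self) -> int:
        return self.f.shape[1]

    def log_probability_many(self, codes: np.ndarray) -> np.ndarray:
        codes = np.asarray(codes, dtype=np.int64)
        with np.errstate(divide="ignore"):
            logf = np.log(self.f)
        return logf[np.arange(self.L), codes].sum(axis=1)

    def log_probability(self, sequence: np.ndarray) -> float:
        return float(self.log_probability_many(np.atleast_2d(sequence))[0])

    def sample(self, n: int, seed: int) -> EncodedMSA:
        rng = np.random.default_rng(seed)
        u = rng.random((n, self.L, 1))
        codes = (self.f.cumsum(axis=1)[None, :, :] < u).sum(axis=2)
        ids = [f"profile_sample_{k}|seed={seed}" for k in range(n)]
        return EncodedMSA(codes=codes, ids=ids, alphabet=self.alphabet)

    def entropy(self) -> float:
        """Closed-form entropy sum_i s_i (independence), nats."""
        return float(site_entropies(self.f).sum())

    def to_armodel(self) -> ARModel:
        """The same distribution as an autoregressive model (J = 0)."""
        with np.errstate(divide="ignore"):
            h = np.log(np.maximum(self.f, 1e-300))
        J = [np.zeros((k, self.q, self.q)) for k in range(self.L)]
        return ARModel(h=h, J=J, order=direct_order(self.L),
                       alphabet=self.alphabet)


def profile_fit(msa: EncodedMSA, weights: SequenceWeights | None = None,
                pseudocount: float = 0.01) -> ProfileModel:
    """Weighted column frequencies with a pseudocount (default 1%).

    The pseudocount keeps every log-probability finite, which the profile
    baseline needs for scoring unseen sequences.
    """
    f = empirical_frequencies(msa, weights, pseudocount, pairwise=False)
    return ProfileModel(f=f.f1, alphabet=msa.alphabet)


# ---------------------------------------------------------------------------
# generative evaluation
# ---------------------------------------------------------------------------

def generative_report(
    natural_msa: EncodedMSA,
    model: ARModel,
    weights: SequenceWeights | None = None,
    n_samples: int = 10_000,
    n_triplets: int = 10_000,
    seed: int = 0,
) -> dict:
    """Compare natural statistics with an i.i.d. model sample.

    Natural-side frequencies are reweighted (when weights are supplied);
    the sampled side is unweighted, being i.i.d. by construction.  Returns
    Pearson agreement of f_i, C_ij and subsampled C_ijk plus the underlying
    scatter arrays.
    """
    if natural_msa.L != model.L or natural_msa.q != model.q:
        raise ValueError("model and alignment must share L and q")
    sample = model.sample(n_samples, seed)
    comp = compare_statistics(natural_msa, sample, weights_a=weights,
                              n_triplets=n_triplets, seed=seed)
    return {
        "pearson_f1": comp.pearson_f1,
        "pearson_c2": comp.pearson_c2,
        "pearson_c3": comp.pearson_c3,
        "n_samples": n_samples,
        "n_triplets": n_triplets,
        "seed": seed,
        "scatter": comp,
    }


# ---------------------------------------------------------------------------
# PCA projection
# ---------------------------------------------------------------------------

def _onehot_float(msa: EncodedMSA) -> np.ndarray:
    M, L, q = msa.M, msa.L, msa.q
    X = np.zeros((M, L * q))
    X[np.arange(M)[:, None], np.arange(L) * q + msa.codes] = 1.0
    return X


def pca_projection(
    natural_msa: EncodedMSA,
    weights: SequenceWeights | None = None,
    *other_msas: EncodedMSA,
) -> list[np.ndarray]:
    """Project alignments onto the top-2 weighted PCs of the natural data.

    Sequences are one-hot encoded over all q states (gap included — gap
    patterns carry cluster structure), centered on the weighted natural
    mean; loadings come from the weighted covariance of the NATURAL data
    only and are applied to every dataset.  Sign convention: the largest-
    magnitude entry of each loading is positive.  Returns one (M_d, 2)
    coordinate array per dataset, natural first.
    """
    for other in other_msas:
        if other.L != natural_msa.L or other.q != natural_msa.q:
            raise ValueError("all alignments must share L and q")
    w = (weights.w if weights is not None
         else np.ones(natural_msa.M)) / (
        weights.Meff if weights is not None else natural_msa.M)
    X = _onehot_float(natural_msa)
    mean = w @ X
    Xc = X - mean
    cov = (Xc * w[:, None]).T @ Xc
    vals, vecs = np.linalg.eigh(cov)
    loadings = vecs[:, ::-1][:, :2]           # top-2 eigenvectors
    for c in range(2):
        col = loadings[:, c]
        if col[np.abs(col).argmax()] < 0:
            loadings[:, c] = -col
    out = [Xc @ loadings]
    for other in other_msas:
        out.append((_onehot_float(other) - mean) @ loadings)
    return out


# ---------------------------------------------------------------------------
# subfamily log-odds classification
# ---------------------------------------------------------------------------

def log_odds_scores(model_1, model_2, msa: EncodedMSA) -> np.ndarray:
    """log P_1(seq) - log P_2(seq) per sequence; positive favors family 1.

    Both models must expose exact normalized log-probabilities (two
    autoregressive models or two profile models) and share L and q.
    """
    if model_1.L != model_2.L or model_1.q != model_2.q:
        raise ValueError("models must share L and q")
    if msa.L != model_1.L:
        raise ValueError("sequences must match model length")
    return (model_1.log_probability_many(msa.codes)
            - model_2.log_probability_many(msa.codes))


def classification_accuracy(
    model_1, model_2, msa_1: EncodedMSA, msa_2: EncodedMSA
) -> float:
    """Fraction of held-out sequences assigned to their true subfamily."""
    s1 = log_odds_scores(model_1, model_2, msa_1)
    s2 = log_odds_scores(model_1, model_2, msa_2)
    correct = (s1 > 0).sum() + (s2 < 0).sum()
    return float(correct / (len(s1) + len(s2)))
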