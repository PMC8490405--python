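"""Empirical alignment statistics: frequencies, entropies, connected correlations.

One-point frequencies f_i(a) and pairwise frequencies f_ij(a,b) are weighted
empirical averages, optionally mixed with a uniform pseudocount:

    f_i(a) = (1 - alpha) * (sum_m w_m [a_i^m = a]) / Meff + alpha / q

and analogously for pairs with alpha / q^2.  Connected correlations subtract
the lower-order products:

    C_ij(a,b)   = f_ij(a,b) - f_i(a) f_j(b)
    C_ijk(a,b,c)= f_ijk(a,b,c) - f_ij(a,b) f_k(c) - f_ik(a,c) f_j(b)
                  - f_jk(b,c) f_i(a) + 2 f_i(a) f_j(b) f_k(c)

The full three-point tensor is O(L^3 q^3); it is evaluated only on a seeded
uniform subset of (i<j<k, a, b, c) tuples, which is how model-vs-data
three-point agreement is scored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .msa import EncodedMSA, SequenceWeights, uniform_weights


@dataclass
class FrequencyTables:
    """Weighted one- and two-point frequency tables of one alignment."""

    f1: np.ndarray            # (L, q)
    f2: np.ndarray | None     # (L, L, q, q); [i, j] meaningful for i != j
    pseudocount: float
    Meff: float

    @property
    def L(self) -> int:
        return self.f1.shape[0]

    @property
    def q(self) -> int:
        return self.f1.shape[1]


def _onehot(msa: EncodedMSA, dtype=np.float64) -> np.ndarray:
    M, L, q = msa.M, msa.L, msa.q
    X = np.zeros((M, L * q), dtype=dtype)
    X[np.arange(M)[:, None], np.arange(L) * q + msa.codes] = 1.0
    return X


def empirical_frequencies(
    msa: EncodedMSA,
    weights: SequenceWeights | None = None,
    pseudocount: float = 0.0,
    pairwise: bool = True,
) -> FrequencyTables:
    """Weighted one-point (and optionally two-point) frequencies.

    ``pseudocount`` is the uniform mixing weight alpha in [0, 1); alpha = 0
    gives the raw weighted counts.
    """
    if not (0 <= pseudocount < 1):
        raise ValueError("pseudocount must lie in [0, 1)")
    if weights is None:
        weights = uniform_weights(msa)
    if len(weights.w) != msa.M:
        raise ValueError("weights length must equal number of sequences")
    L, q = msa.L, msa.q
    w = weights.w
    Meff = weights.Meff
    alpha = pseudocount

    f1 = np.zeros((L, q))
    for i in range(L):
        np.add.at(f1[i], msa.codes[:, i], w)
    f1 /= Meff
    f1 = (1 - alpha) * f1 + alpha / q

    f2 = None
    if pairwise:
        X = _onehot(msa)
        F = (X * w[:, None]).T @ X / Meff          # (L q, L q)
        f2 = F.reshape(L, q, L, q).transpose(0, 2, 1, 3)
        f2 = (1 - alpha) * f2 + alpha / q**2
    return FrequencyTables(f1=f1, f2=f2, pseudocount=alpha, Meff=Meff)


def site_entropies(f1: np.ndarray) -> np.ndarray:
    """Per-column Shannon entropies s_i = -sum_a f_i(a) log f_i(a), in nats."""
    f = np.asarray(f1, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log(f), 0.0)
    return -terms.sum(axis=1)


def connected_pair_correlations(freqs: FrequencyTables) -> np.ndarray:
    """C_ij(a,b) = f_ij(a,b) - f_i(a) f_j(b), as an (L, L, q, q) tensor.

    The diagonal blocks i == j are zeroed: they carry no pair information.
    """
    if freqs.f2 is None:
        raise ValueError("pairwise frequencies were not computed")
    c2 = freqs.f2 - np.einsum("ia,jb->ijab", freqs.f1, freqs.f1)
    idx = np.arange(freqs.L)
    c2[idx, idx] = 0.0
    return c2


def sample_triplet_tuples(
    L: int, q: int, n_triplets: int, seed: int
) -> np.ndarray:
    """Seeded uniform sample of (i, j, k, a, b, c) tuples with i < j < k.

    Returns an (n_triplets, 6) int array.  Requires L >= 3.
    """
    if L < 3:
        raise ValueError("need at least 3 columns for triplet correlations")
    if n_triplets < 1:
        raise ValueError("n_triplets must be >= 1")
    rng = np.random.default_rng(seed)
    # vectorized sampling without replacement: rank 3 smallest of L uniforms
    u = rng.random((n_triplets, L))
    sites = np.argpartition(u, 3, axis=1)[:, :3].astype(np.int64)
    sites.sort(axis=1)
    states = rng.integers(0, q, size=(n_triplets, 3))
    return np.hstack([sites, states])


def connected_triplet_values(
    msa: EncodedMSA,
    tuples: np.ndarray,
    weights: SequenceWeights | None = None,
) -> np.ndarray:
    """Connected three-point correlations C_ijk(a,b,c) at the given tuples."""
    if weights is None:
        weights = uniform_weights(msa)
    w = weights.w
    Meff = weights.Meff
    codes = msa.codes
    i, j, k, a, b, c = (tuples[:, t] for t in range(6))

    out = np.empty(len(tuples))
    # chunk over tuples to bound the (M, chunk) comparison buffers
    chunk = max(1, int(2**22 // max(msa.M, 1)))
    for start in range(0, len(tuples), chunk):
        sl = slice(start, start + chunk)
        mi = codes[:, i[sl]] == a[sl]
        mj = codes[:, j[sl]] == b[sl]
        mk = codes[:, k[sl]] == c[sl]
        fi = w @ mi / Meff
        fj = w @ mj / Meff
        fk = w @ mk / Meff
        fij = w @ (mi & mj) / Meff
        fik = w @ (mi & mk) / Meff
        fjk = w @ (mj & mk) / Meff
        fijk = w @ (mi & mj & mk) / Meff
        out[sl] = fijk - fij * fk - fik * fj - fjk * fi + 2 * fi * fj * fk
    return out


@dataclass
class StatisticsComparison:
    """Pearson agreement of one-, two- and three-point statistics."""

    pearson_f1: float
    pearson_c2: float
    pearson_c3: float
    f1_a: np.ndarray
    f1_b: np.ndarray
    c2_a: np.ndarray
    c2_b: np.ndarray
    c3_a: np.ndarray
    c3_b: np.ndarray


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if np.allclose(x, y):
        return 1.0
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(sstats.pearsonr(x, y).statistic)


def compare_statistics(
    msa_a: EncodedMSA,
    msa_b: EncodedMSA,
    weights_a: SequenceWeights | None = None,
    weights_b: SequenceWeights | None = None,
    n_triplets: int = 100_000,
    seed: int = 0,
) -> StatisticsComparison:
    """Compare the statistics of two alignments over the same columns.

    Typically `msa_a` is the natural (reweighted) alignment and `msa_b` an
    i.i.d. model sample (unweighted).  Two-point connected correlations are
    compared over all i < j entries; three-point ones over a shared seeded
    tuple subsample.
    """
    if msa_a.L != msa_b.L or msa_a.q != msa_b.q:
        raise ValueError("alignments must share L and q")
    fa = empirical_frequencies(msa_a, weights_a)
    fb = empirical_frequencies(msa_b, weights_b)
    c2a = connected_pair_correlations(fa)
    c2b = connected_pair_correlations(fb)
    iu = np.triu_indices(msa_a.L, k=1)
    c2a_flat = c2a[iu].ravel()
    c2b_flat = c2b[iu].ravel()

    tuples = sample_triplet_tuples(msa_a.L, msa_a.q, n_triplets, seed)
    c3a = connected_triplet_values(msa_a, tuples, weights_a)
    c3b = connected_triplet_values(msa_b, tuples, weights_b)

    return StatisticsComparison(
        pearson_f1=_pearson(fa.f1, fb.f1),
        pearson_c2=_pearson(c2a_flat, c2b_flat),
        pearson_c3=_pearson(c3a, c3b),
        f1_a=fa.f1, f1_b=fb.f1,
        c2_a=c2a_flat, c2_b=c2b_flat,
        c3_a=c3a, c3_b=c3b,
    )
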