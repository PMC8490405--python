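"""Synthetic ground-truth generators and brute-force oracles.

Every stage of the pipeline is testable offline against these: random
autoregressive models with known parameters, an exactly-sampled pairwise
Potts ensemble with known coupled pairs (contact-recovery truth), two-
subfamily alignments for log-odds classification, and two-cluster families
for the PCA projection.  All generators are deterministic given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import ARModel, enumerate_sequences
from .msa import Alphabet, EncodedMSA, toy_alphabet
from .ordering import direct_order, random_order

ENUMERATION_CAP = 10**6


@dataclass
class FixtureSpec:
    """Dimensions and scales of one synthetic family."""

    L: int
    q: int
    M: int = 0
    field_scale: float = 1.0
    coupling_scale: float = 1.0
    coupling_pairs: list[tuple[int, int]] | None = None
    seed: int = 0

    def alphabet(self) -> Alphabet:
        from .msa import DEFAULT_ALPHABET
        return DEFAULT_ALPHABET if self.q == 21 else toy_alphabet(self.q)


def random_armodel(spec: FixtureSpec, shuffle_order: bool = False) -> ARModel:
    """A random autoregressive model with Gaussian fields and couplings.

    Couplings are nonzero only on ``spec.coupling_pairs`` (model-order
    position pairs (j, k), j < k); None means all pairs are coupled at
    ``coupling_scale`` (a scale of 0 gives an independent-site model).
    """
    rng = np.random.default_rng(spec.seed)
    L, q = spec.L, spec.q
    h = rng.normal(0.0, spec.field_scale, size=(L, q))
    J = [np.zeros((0, q, q))]
    pairs = (spec.coupling_pairs if spec.coupling_pairs is not None
             else [(j, k) for k in range(L) for j in range(k)])
    pairset = {(min(a, b), max(a, b)) for a, b in pairs}
    for k in range(1, L):
        Jk = np.zeros((k, q, q))
        for j in range(k):
            if (j, k) in pairset and spec.coupling_scale > 0:
                Jk[j] = rng.normal(0.0, spec.coupling_scale, size=(q, q))
        J.append(Jk)
    order = (random_order(L, spec.seed + 1) if shuffle_order
             else direct_order(L))
    return ARModel(h=h, J=J, order=order, alphabet=spec.alphabet(),
                   meta={"fixture": "random_armodel", "seed": spec.seed})


def _sample_coupled_pairs(rng, L: int, n_pick: int,
                          min_sep: int) -> list[tuple[int, int]]:
    """Random coupled pairs at separation >= min_sep, site-disjoint when
    possible (a random matching): each site then carries at most one
    coupling, so pair scores are not confounded by shared-site effects."""
    if n_pick == 0:
        return []
    if 2 * n_pick <= L:
        for _ in range(1000):
            perm = rng.permutation(L)
            pairs = sorted(
                (min(int(perm[2 * t]), int(perm[2 * t + 1])),
                 max(int(perm[2 * t]), int(perm[2 * t + 1])))
                for t in range(n_pick)
            )
            if all(j - i >= min_sep for i, j in pairs):
                return pairs
    all_pairs = [(i, j) for i in range(L) for j in range(i + 1, L)
                 if j - i >= min_sep]
    idx = rng.choice(len(all_pairs), size=n_pick, replace=False)
    return [all_pairs[t] for t in sorted(idx)]


@dataclass
class PottsFixture:
    """Exactly-sampled pairwise Potts family with known coupled pairs."""

    msa: EncodedMSA
    true_pairs: set[tuple[int, int]]
    fields: np.ndarray
    couplings: dict[tuple[int, int], np.ndarray]
    probabilities: np.ndarray | None = None

    def contact_matrix(self) -> np.ndarray:
        L = self.fields.shape[0]
        C = np.zeros((L, L), dtype=bool)
        for i, j in self.true_pairs:
            C[i, j] = C[j, i] = True
        return C


def random_potts_exact(
    spec: FixtureSpec,
    n_coupled_pairs: int | None = None,
    min_pair_sep: int = 1,
    cap: int = ENUMERATION_CAP,
    keep_probabilities: bool = False,
) -> PottsFixture:
    """Enumerate a pairwise Potts distribution and sample M sequences exactly.

    P(a) ~ exp( sum_i h_i(a_i) + sum_{(i,j) coupled} J_ij(a_i, a_j) ), with
    couplings only on randomly chosen pairs; the full q^L probability table
    is built by tensor broadcasting, so sampling is exact (no MCMC).
    """
    L, q = spec.L, spec.q
    n_states = q**L
    if n_states > cap:
        raise ValueError(f"q^L = {n_states} exceeds enumeration cap {cap}")
    rng = np.random.default_rng(spec.seed)
    h = rng.normal(0.0, spec.field_scale, size=(L, q))

    if spec.coupling_pairs is not None:
        chosen = [(min(i, j), max(i, j)) for i, j in spec.coupling_pairs]
    else:
        n_pick = n_coupled_pairs if n_coupled_pairs is not None else L // 2
        chosen = _sample_coupled_pairs(rng, L, n_pick, min_pair_sep)
    couplings = {
        (i, j): rng.normal(0.0, spec.coupling_scale, size=(q, q))
        for i, j in chosen
    }

    logits = np.zeros((q,) * L)
    for i in range(L):
        shape = [1] * L
        shape[i] = q
        logits += h[i].reshape(shape)
    for (i, j), Jij in couplings.items():
        shape = [1] * L
        shape[i] = q
        shape[j] = q
        logits += Jij.reshape(shape)
    flat = logits.reshape(-1)
    flat -= flat.max()
    p = np.exp(flat)
    p /= p.sum()

    u = rng.random(spec.M)
    states = np.searchsorted(np.cumsum(p), u).clip(max=n_states - 1)
    codes = np.column_stack(np.unravel_index(states, (q,) * L))
    msa = EncodedMSA(
        codes=codes,
        ids=[f"potts_{k}|seed={spec.seed}" for k in range(spec.M)],
        alphabet=spec.alphabet(),
    )
    return PottsFixture(
        msa=msa, true_pairs=set(chosen), fields=h, couplings=couplings,
        probabilities=p if keep_probabilities else None,
    )


@dataclass
class SubfamilyFixture:
    """Two related subfamilies with train / held-out splits."""

    train_1: EncodedMSA
    train_2: EncodedMSA
    held_out_1: EncodedMSA
    held_out_2: EncodedMSA
    model_1: ARModel
    model_2: ARModel
    divergent_sites: list[int]


def two_subfamily_msa(
    spec: FixtureSpec,
    n_divergent_sites: int = 4,
    divergence_scale: float = 2.0,
    n_held_out: int | None = None,
) -> SubfamilyFixture:
    """Two ground-truth families sharing a backbone, diverging at a few sites.

    Subfamily 2 is subfamily 1 with perturbations of the given scale at
    ``n_divergent_sites`` random sites: both the fields there and the
    couplings incident to them shift, so the subfamilies differ in their
    covariation structure and not only in column profiles (as real
    subfamilies do).  divergence_scale = 0 makes them identical
    (indistinguishable).  Each subfamily contributes ``spec.M`` training and
    ``n_held_out`` (default M // 4) held-out sequences, drawn i.i.d. with
    disjoint seeds.
    """
    rng = np.random.default_rng(spec.seed)
    base = random_armodel(spec)
    sites = sorted(rng.choice(spec.L, size=n_divergent_sites, replace=False).tolist())
    site_set = set(sites)
    h2 = base.h.copy()
    J2 = [Jk.copy() for Jk in base.J]
    for s in sites:
        h2[s] += rng.normal(0.0, divergence_scale, size=spec.q)
    for k in range(1, spec.L):
        for j in range(k):
            if j in site_set or k in site_set:
                J2[k][j] += rng.normal(0.0, divergence_scale,
                                       size=(spec.q, spec.q))
    model_2 = ARModel(h=h2, J=J2, order=base.order,
                      alphabet=base.alphabet,
                      meta={"fixture": "two_subfamily", "seed": spec.seed})
    n_out = n_held_out if n_held_out is not None else max(1, spec.M // 4)
    s0 = spec.seed
    return SubfamilyFixture(
        train_1=base.sample(spec.M, seed=s0 + 11),
        train_2=model_2.sample(spec.M, seed=s0 + 12),
        held_out_1=base.sample(n_out, seed=s0 + 13),
        held_out_2=model_2.sample(n_out, seed=s0 + 14),
        model_1=base, model_2=model_2, divergent_sites=sites,
    )


@dataclass
class ClusterFixture:
    msa: EncodedMSA
    labels: np.ndarray


def two_cluster_msa(spec: FixtureSpec, sharpness: float = 3.0) -> ClusterFixture:
    """One family drawn from a 50/50 mixture of two sharp profiles.

    Each cluster has its own random preferred state per column, favored by
    ``sharpness`` in log-weight; used to test that the leading principal
    component separates the clusters.
    """
    rng = np.random.default_rng(spec.seed)
    L, q = spec.L, spec.q
    profiles = []
    for _ in range(2):
        logw = rng.normal(0.0, 0.3, size=(L, q))
        logw[np.arange(L), rng.integers(0, q, size=L)] += sharpness
        p = np.exp(logw)
        profiles.append(p / p.sum(axis=1, keepdims=True))
    labels = rng.integers(0, 2, size=spec.M)
    u = rng.random((spec.M, L, 1))
    codes = np.empty((spec.M, L), dtype=np.int64)
    for c in (0, 1):
        mask = labels == c
        cum = profiles[c].cumsum(axis=1)[None, :, :]
        codes[mask] = (cum < u[mask]).sum(axis=2)
    msa = EncodedMSA(codes=codes,
                     ids=[f"cluster{labels[k]}_{k}" for k in range(spec.M)],
                     alphabet=spec.alphabet())
    return ClusterFixture(msa=msa, labels=labels)
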