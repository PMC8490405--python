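"""Mutational-effect prediction, epistasis and contact scoring.

Single-substitution effects are statistical-energy differences in a fixed
sequence background,

    dE(a_i -> b) = E(..., b at i, ...) - E(reference),

negative meaning the mutant is predicted more family-like.  Epistasis of a
double mutation is the deviation from additivity,

    ddE(b_i, b_j) = dE(double) - dE(b_i) - dE(b_j),

and the q x q matrix of ddE values over target states (i, j) acts as an
effective direct coupling between the two sites.  Contact scores follow the
standard coevolution pipeline: shift each effective-coupling block to the
zero-sum gauge, take its Frobenius norm, and apply the average-product
correction (APC) to suppress conservation/phylogeny bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .model import ARModel


@dataclass
class MutationalScan:
    """Full single-site substitution scan relative to one reference.

    delta_E[i, b] is dE(a_i -> b) at ORIGINAL column i; the wildtype entry
    delta_E[i, reference[i]] is exactly zero.
    """

    reference: np.ndarray
    delta_E: np.ndarray

    def to_frame(self, alphabet) -> pd.DataFrame:
        """Long-format table: position (1-based), wt_aa, mut_aa, delta_E."""
        L, q = self.delta_E.shape
        rows = []
        for i in range(L):
            wt = alphabet.symbols[self.reference[i]]
            for b in range(q):
                rows.append((i + 1, wt, alphabet.symbols[b], self.delta_E[i, b]))
        return pd.DataFrame(rows, columns=["position", "wt_aa", "mut_aa", "delta_E"])


@dataclass
class ContactScores:
    """Pairwise coupling-strength scores in original coordinates."""

    K: dict[tuple[int, int], np.ndarray]   # (i, j) i<j -> q x q ddE block
    F: np.ndarray                          # L x L Frobenius norms (symmetric)
    F_apc: np.ndarray                      # APC-corrected scores
    min_sep: int

    def ranked_pairs(self, min_sep: int | None = None) -> list[tuple[int, int, float]]:
        """(i, j, F_apc) sorted by descending score, |i-j| >= min_sep.

        Ties are broken by (i, j) lexicographic order.
        """
        sep = self.min_sep if min_sep is None else min_sep
        L = self.F_apc.shape[0]
        pairs = [(i, j, float(self.F_apc[i, j]))
                 for i in range(L) for j in range(i + 1, L) if j - i >= sep]
        return sorted(pairs, key=lambda t: (-t[2], t[0], t[1]))

    def to_frame(self, min_sep: int | None = None) -> pd.DataFrame:
        rows = [(i + 1, j + 1, s, float(self.F[i, j]))
                for i, j, s in self.ranked_pairs(min_sep)]
        return pd.DataFrame(rows, columns=["i", "j", "F_apc", "F"])


def _model_position_terms(model: ARModel, perm_ref: np.ndarray):
    """Reference logits at every model position, for incremental updates."""
    logits = []
    for k in range(model.L):
        lk = model.h[k].copy()
        if k:
            lk += model.J[k][np.arange(k), :, perm_ref[:k]].sum(axis=0)
        logits.append(lk)
    return logits


def dms_scan(model: ARModel, reference: np.ndarray) -> MutationalScan:
    """In-silico deep mutational scan: dE for all L x q single substitutions.

    Implemented incrementally: substituting original column c (model
    position p) leaves conditionals at positions < p untouched and leaves
    every local partition function z_k with k <= p unchanged, so only the
    chosen-state term at p and the (logit, z) pairs at positions k > p that
    are coupled to p need recomputation.  The result equals the naive
    difference of two full sequence energies.
    """
    reference = np.asarray(reference, dtype=np.int64)
    if reference.shape != (model.L,):
        raise ValueError(f"reference must have length L={model.L}")
    if reference.min() < 0 or reference.max() >= model.q:
        raise ValueError("invalid codes in reference")
    perm = np.asarray(model.order.perm)
    inv = model.order.inverse()
    perm_ref = reference[perm]
    base_logits = _model_position_terms(model, perm_ref)
    base_logz = np.array([logsumexp(lk) for lk in base_logits])
    # reference per-position log-factors
    base_logp = np.array(
        [base_logits[k][perm_ref[k]] - base_logz[k] for k in range(model.L)]
    )

    q = model.q
    delta_E = np.zeros((model.L, q))
    for p in range(model.L):          # p: model position being mutated
        a = perm_ref[p]
        # term at p: same logits and z, different chosen state (all targets b)
        dlogp = base_logits[p] - base_logits[p][a]
        # every position k > p reads p through its J[k][p] block: the logits
        # there shift by the coupling-column difference, and z_k changes
        for k in range(p + 1, model.L):
            shift = model.J[k][p] - model.J[k][p][:, [a]]     # (q_states, q_b)
            new_logits = base_logits[k][:, None] + shift
            new_logz = logsumexp(new_logits, axis=0)
            dlogp += new_logits[perm_ref[k]] - new_logz - base_logp[k]
        delta_E[p] = -dlogp
        delta_E[p, a] = 0.0
    # back to original column coordinates
    return MutationalScan(reference=reference, delta_E=delta_E[inv])


def dms_scan_naive(model: ARModel, reference: np.ndarray) -> MutationalScan:
    """Reference implementation: dE from full mutant energies (batched)."""
    reference = np.asarray(reference, dtype=np.int64)
    L, q = model.L, model.q
    mutants = np.repeat(reference[None, :], L * q, axis=0)
    idx = np.arange(L * q)
    mutants[idx, idx // q] = idx % q
    E = model.energy_many(mutants).reshape(L, q)
    E_ref = model.energy(reference)
    return MutationalScan(reference=reference, delta_E=E - E_ref)


def epistasis(
    model: ARModel,
    reference: np.ndarray,
    mutation_i: tuple[int, int],
    mutation_j: tuple[int, int],
) -> float:
    """ddE of a double mutation (i, b_i), (j, b_j) in the reference background."""
    (i, bi), (j, bj) = mutation_i, mutation_j
    if i == j:
        raise ValueError("epistasis requires two distinct sites")
    reference = np.asarray(reference, dtype=np.int64)
    single_i = reference.copy(); single_i[i] = bi
    single_j = reference.copy(); single_j[j] = bj
    double = reference.copy(); double[i] = bi; double[j] = bj
    E = model.energy_many(np.vstack([reference, single_i, single_j, double]))
    return float((E[3] - E[0]) - (E[1] - E[0]) - (E[2] - E[0]))


def effective_couplings(model: ARModel, reference: np.ndarray) -> dict[tuple[int, int], np.ndarray]:
    """ddE blocks K_ij(b_i, b_j) for every site pair i < j (original coords).

    The wildtype row and column of each block are identically zero.  Computed
    from batched exact energies; one background sequence only.
    """
    reference = np.asarray(reference, dtype=np.int64)
    L, q = model.L, model.q
    dE = dms_scan(model, reference).delta_E
    E_ref = model.energy(reference)
    K: dict[tuple[int, int], np.ndarray] = {}
    for i in range(L):
        for j in range(i + 1, L):
            doubles = np.repeat(reference[None, :], q * q, axis=0)
            pairs = np.arange(q * q)
            doubles[pairs, i] = pairs // q
            doubles[pairs, j] = pairs % q
            E_double = model.energy_many(doubles).reshape(q, q) - E_ref
            K[(i, j)] = E_double - dE[i][:, None] - dE[j][None, :]
    return K


def zero_sum_gauge(block: np.ndarray) -> np.ndarray:
    """Shift a q x q block so every row and column mean is zero."""
    return (block - block.mean(axis=0, keepdims=True)
            - block.mean(axis=1, keepdims=True) + block.mean())


def apc_correction(F: np.ndarray) -> np.ndarray:
    """Average-product correction of a symmetric score matrix.

    F_apc(i,j) = F(i,j) - mean_i(F) mean_j(F) / mean(F), means taken over
    off-diagonal entries; diagonal forced to zero.
    """
    L = F.shape[0]
    off = ~np.eye(L, dtype=bool)
    row_mean = (F * off).sum(axis=1) / (L - 1)
    grand = (F * off).sum() / (L * (L - 1))
    apc = F - np.outer(row_mean, row_mean) / grand
    np.fill_diagonal(apc, 0.0)
    return apc


def contact_scores(
    K: dict[tuple[int, int], np.ndarray],
    L: int,
    gap_code: int | None = None,
    min_sep: int = 5,
    exclude_gap: bool = True,
) -> ContactScores:
    """Frobenius + APC contact map from effective-coupling blocks.

    Each block is gauged to zero-sum over the retained states (the gap state
    dropped when ``exclude_gap`` and a gap code is given) before the norm.
    """
    F = np.zeros((L, L))
    keep = None
    if exclude_gap and gap_code is not None:
        keep = np.array([s for s in range(next(iter(K.values())).shape[0])
                         if s != gap_code])
    for (i, j), block in K.items():
        b = block if keep is None else block[np.ix_(keep, keep)]
        g = zero_sum_gauge(b)
        F[i, j] = F[j, i] = np.sqrt((g * g).sum())
    return ContactScores(K=K, F=F, F_apc=apc_correction(F), min_sep=min_sep)


def ppv_curve(
    scores: ContactScores,
    true_contacts: set[tuple[int, int]] | np.ndarray,
    min_sep: int | None = None,
) -> list[tuple[int, float]]:
    """Positive predictive value of the top-n ranked pairs, for each n.

    ``true_contacts`` is a symmetric relation, given as a set of (i, j)
    tuples or a boolean L x L matrix (0-based).
    """
    if isinstance(true_contacts, np.ndarray):
        truth = {(i, j) for i in range(true_contacts.shape[0])
                 for j in range(i + 1, true_contacts.shape[1])
                 if true_contacts[i, j]}
    else:
        truth = {(min(i, j), max(i, j)) for i, j in true_contacts}
    out = []
    hits = 0
    for n, (i, j, _) in enumerate(scores.ranked_pairs(min_sep), start=1):
        hits += (i, j) in truth
        out.append((n, hits / n))
    return out
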