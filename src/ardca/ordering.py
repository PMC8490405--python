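"""Positional orders for the autoregressive factorization.

The factorization P(a_1..a_L) = prod_i P(a_i | a_{i-1}..a_1) is valid for any
permutation of the columns, but the soft-max parameterization makes different
orders give different fitted models.  The entropic order — most conserved
(lowest column entropy) sites first — is the recommended heuristic; direct
(native), seeded random and user-supplied orders are also available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .msa import EncodedMSA


@dataclass(frozen=True)
class SiteOrder:
    """A permutation of alignment columns.

    ``perm[k]`` is the ORIGINAL column index placed at model position k.
    """

    perm: tuple[int, ...]
    label: str = "custom"

    def __post_init__(self) -> None:
        L = len(self.perm)
        if sorted(self.perm) != list(range(L)):
            raise ValueError("perm must be a permutation of 0..L-1")

    @property
    def L(self) -> int:
        return len(self.perm)

    def inverse(self) -> np.ndarray:
        """inverse()[original_column] = model position of that column."""
        inv = np.empty(self.L, dtype=np.int64)
        inv[np.asarray(self.perm)] = np.arange(self.L)
        return inv


def entropic_order(s: np.ndarray) -> SiteOrder:
    """Sites sorted by increasing column entropy; ties by column index."""
    s = np.asarray(s, dtype=np.float64)
    if not np.all(np.isfinite(s)):
        raise ValueError("entropies must be finite")
    perm = tuple(int(i) for i in np.argsort(s, kind="stable"))
    return SiteOrder(perm=perm, label="entropic")


def direct_order(L: int) -> SiteOrder:
    """The native left-to-right column order."""
    return SiteOrder(perm=tuple(range(L)), label="direct")


def random_order(L: int, seed: int) -> SiteOrder:
    """A seeded uniformly random permutation."""
    rng = np.random.default_rng(seed)
    return SiteOrder(perm=tuple(int(i) for i in rng.permutation(L)), label="random")


def custom_order(perm) -> SiteOrder:
    return SiteOrder(perm=tuple(int(i) for i in perm), label="custom")


def apply_order(msa: EncodedMSA, order: SiteOrder) -> EncodedMSA:
    """Permute MSA columns into model order."""
    if order.L != msa.L:
        raise ValueError("order length does not match alignment")
    return EncodedMSA(
        codes=msa.codes[:, list(order.perm)], ids=list(msa.ids), alphabet=msa.alphabet
    )


def invert_order(values: np.ndarray, order: SiteOrder) -> np.ndarray:
    """Map per-model-position values back to original column coordinates.

    ``invert_order(x, order)[c] == x[model position of column c]``, so
    ``invert_order`` undoes the column permutation of :func:`apply_order`
    along the first axis.
    """
    values = np.asarray(values)
    if values.shape[0] != order.L:
        raise ValueError("first axis must have length L")
    return values[order.inverse()]
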