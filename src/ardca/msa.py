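"""Alphabet, aligned-FASTA ingestion, integer encoding and sequence reweighting.

The model works on a fixed 21-letter alphabet: the 20 standard amino acids in
the order ``ACDEFGHIKLMNPQRSTVWY`` followed by the alignment gap ``-`` as the
21st state.  An alignment of M sequences of length L becomes an M x L integer
matrix with entries in [0, 20].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"


class FastaParseError(ValueError):
    """Raised when a FASTA file cannot be parsed."""


@dataclass(frozen=True)
class Alphabet:
    """Ordered symbol set mapping characters to integer codes.

    The default (and only alphabet used in practice) is the 20 amino acids
    plus gap, q = 21, with the gap as the last code.  Lowercase input is
    uppercased; ``.`` and any non-standard letter (X, B, Z, ...) map to the
    gap code, since the model has no other state for them.
    """

    symbols: str = AMINO_ACIDS + GAP

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be distinct")

    @property
    def q(self) -> int:
        return len(self.symbols)

    @property
    def gap_code(self) -> int:
        if GAP not in self.symbols:
            raise ValueError("alphabet has no gap symbol")
        return self.symbols.index(GAP)

    @property
    def char_to_code(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.symbols)}

    def encode(self, sequence: str) -> np.ndarray:
        """Encode one sequence string to integer codes (unknowns -> gap)."""
        table = self.char_to_code
        gap = self.gap_code if GAP in self.symbols else None
        out = []
        for c in sequence.upper():
            code = table.get(c, gap)
            if code is None:
                raise ValueError(f"character {c!r} not in alphabet")
            out.append(code)
        return np.array(out, dtype=np.int64)

    def decode(self, codes: np.ndarray) -> str:
        return "".join(self.symbols[c] for c in codes)


DEFAULT_ALPHABET = Alphabet()


def toy_alphabet(q: int) -> Alphabet:
    """A reduced q-letter alphabet (no gap) for small synthetic models."""
    if not (1 <= q <= 20):
        raise ValueError("toy alphabets support 1..20 symbols")
    return Alphabet(symbols=AMINO_ACIDS[:q])


@dataclass
class EncodedMSA:
    """Integer-coded multiple sequence alignment.

    Attributes
    ----------
    codes : (M, L) int array with entries in [0, q-1]
    ids : M record identifiers (headers, verbatim)
    alphabet : the Alphabet the codes refer to
    """

    codes: np.ndarray
    ids: list[str]
    alphabet: Alphabet = field(default_factory=lambda: DEFAULT_ALPHABET)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D matrix")
        if self.codes.shape[0] < 1 or self.codes.shape[1] < 1:
            raise ValueError("MSA must have at least one sequence and one column")
        if len(self.ids) != self.codes.shape[0]:
            raise ValueError("number of ids must match number of sequences")
        if self.codes.min() < 0 or self.codes.max() >= self.alphabet.q:
            raise ValueError("codes out of alphabet range")

    @property
    def M(self) -> int:
        return self.codes.shape[0]

    @property
    def L(self) -> int:
        return self.codes.shape[1]

    @property
    def q(self) -> int:
        return self.alphabet.q

    def sequences(self) -> list[str]:
        return [self.alphabet.decode(row) for row in self.codes]


@dataclass
class SequenceWeights:
    """Inverse-neighborhood sequence weights at an identity threshold.

    w_m = 1 / #{m' : identity(m, m') >= theta}, the count including m itself,
    so 0 < w_m <= 1 and Meff = sum(w) lies in [1, M].
    """

    w: np.ndarray
    theta: float

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=np.float64)
        if np.any(self.w <= 0) or np.any(self.w > 1):
            raise ValueError("weights must lie in (0, 1]")

    @property
    def Meff(self) -> float:
        return float(self.w.sum())


def read_fasta(path_or_handle) -> list[tuple[str, str]]:
    """Read FASTA records as (id, sequence) pairs, in file order.

    Headers are preserved verbatim (without the leading ``>``).  Raises
    :class:`FastaParseError` for an empty file or for sequence data appearing
    before the first header, naming the offending line.
    """
    if hasattr(path_or_handle, "read"):
        lines = path_or_handle.read().splitlines()
    else:
        with open(path_or_handle) as fh:
            lines = fh.read().splitlines()

    records: list[tuple[str, str]] = []
    header: str | None = None
    chunks: list[str] = []
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            if header is not None:
                records.append((header, "".join(chunks)))
            header = stripped[1:]
            chunks = []
        else:
            if header is None:
                raise FastaParseError(
                    f"line {lineno}: sequence data before first '>' header"
                )
            chunks.append(stripped)
    if header is not None:
        records.append((header, "".join(chunks)))
    if not records:
        raise FastaParseError("no sequences found in FASTA input")
    return records


def write_fasta(path_or_handle, records: Sequence[tuple[str, str]], width: int = 80) -> None:
    """Write (id, sequence) records as FASTA, wrapping sequences at `width`."""
    own = not hasattr(path_or_handle, "write")
    fh = open(path_or_handle, "w") if own else path_or_handle
    try:
        for name, seq in records:
            fh.write(f">{name}\n")
            for start in range(0, len(seq), width):
                fh.write(seq[start : start + width] + "\n")
    finally:
        if own:
            fh.close()


def encode_msa(
    records: Sequence[tuple[str, str]], alphabet: Alphabet = DEFAULT_ALPHABET
) -> EncodedMSA:
    """Encode aligned (id, sequence) records into an :class:`EncodedMSA`.

    All sequences must have the same length; a mismatch names the offending
    record.  Case is folded and unknown characters become gaps.
    """
    if not records:
        raise ValueError("no records to encode")
    L = len(records[0][1])
    rows = []
    ids = []
    for name, seq in records:
        if len(seq) != L:
            raise ValueError(
                f"record '{name}' has length {len(seq)}, expected {L} "
                f"(alignment must be rectangular)"
            )
        rows.append(alphabet.encode(seq))
        ids.append(name)
    return EncodedMSA(codes=np.vstack(rows), ids=ids, alphabet=alphabet)


def load_msa(path, alphabet: Alphabet = DEFAULT_ALPHABET) -> EncodedMSA:
    """Read an aligned FASTA file and encode it in one step."""
    return encode_msa(read_fasta(path), alphabet)


def compute_weights(msa: EncodedMSA, theta: float = 0.8) -> SequenceWeights:
    """Inverse-neighborhood reweighting at fractional identity `theta`.

    Identity between two rows is the fraction of equal codes over all L
    columns (the gap counts as an ordinary 21st symbol).  Each sequence gets
    weight 1 / (number of rows at identity >= theta, itself included).

    Computed blockwise via one-hot inner products, O(M^2 L q) but BLAS-bound.
    """
    if not (0 < theta <= 1):
        raise ValueError("theta must lie in (0, 1]")
    codes = msa.codes
    M, L = codes.shape
    # one-hot, float32: identity count between rows = dot of their one-hots
    onehot = np.zeros((M, L * msa.q), dtype=np.float32)
    flat_idx = np.arange(L) * msa.q + codes
    onehot[np.arange(M)[:, None], flat_idx] = 1.0
    min_matches = theta * L - 1e-9
    neighbors = np.zeros(M, dtype=np.int64)
    block = max(1, int(2**24 // max(M, 1)))
    for start in range(0, M, block):
        sim = onehot[start : start + block] @ onehot.T
        neighbors[start : start + block] = (sim >= min_matches).sum(axis=1)
    return SequenceWeights(w=1.0 / neighbors, theta=theta)


def uniform_weights(msa: EncodedMSA) -> SequenceWeights:
    """Unit weights (no reweighting); Meff = M."""
    return SequenceWeights(w=np.ones(msa.M), theta=1.0)


def weights_to_tsv(msa: EncodedMSA, weights: SequenceWeights, path) -> None:
    """Export per-sequence weights as a two-column (id, weight) TSV."""
    own = not hasattr(path, "write")
    fh = open(path, "w") if own else path
    try:
        for name, w in zip(msa.ids, weights.w):
            fh.write(f"{name}\t{w:.10g}\n")
    finally:
        if own:
            fh.close()


def msa_from_strings(sequences: Sequence[str], ids: Sequence[str] | None = None,
                     alphabet: Alphabet = DEFAULT_ALPHABET) -> EncodedMSA:
    """Convenience constructor from plain sequence strings."""
    if ids is None:
        ids = [f"seq{i}" for i in range(len(sequences))]
    return encode_msa(list(zip(ids, sequences)), alphabet)
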