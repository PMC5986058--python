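"""Core domain types, aligned-FASTA and annotation I/O, and pairwise measures.

The central object is the :class:`MultipleAlignment`, a rectangular matrix of
aligned residue rows over the 20 standard amino acids, the gap character
``-`` and the ambiguity symbols ``B``/``Z``/``X``.  Everything downstream
(filtering, merging, clustering, position statistics) consumes this object
together with a :class:`FamilyAnnotation` that assigns every sequence to a
functional family (specificity group).

Reference numbering maps alignment columns to residue labels of a chosen
representative protein (e.g. ``K199`` in the numbering of a PDB entry), the
convention used to report conserved and family-specific positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
AMBIGUOUS = "BZX"
ALPHABET = frozenset(AMINO_ACIDS) | {GAP} | frozenset(AMBIGUOUS)

#: integer codes used internally: 0..19 residues, -1 gap, -2 ambiguous
RESIDUE_CODES: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
RESIDUE_CODES[GAP] = -1
for _ch in AMBIGUOUS:
    RESIDUE_CODES[_ch] = -2

#: marker returned by :func:`bits_per_column` when two rows share no
#: mutually non-gap column; compares below any finite threshold.
UNDEFINED_BITS = float("-inf")


class AlignmentError(ValueError):
    """Raised on malformed alignments, annotations or numbering specs."""


def normalize_row(raw: str) -> str:
    """Upper-case a residue string and normalize the ``.`` gap alias to ``-``."""
    return raw.upper().replace(".", GAP)


@dataclass
class MultipleAlignment:
    """Rectangular multiple sequence alignment.

    Parameters
    ----------
    ids:
        Unique sequence identifiers, parallel to ``rows``.
    rows:
        Aligned residue strings of identical length over the declared
        alphabet (20 amino acids, ``-``, ``B``/``Z``/``X``).
    """

    ids: list[str]
    rows: list[str]
    _index: dict[str, int] = field(init=False, repr=False)
    _codes: np.ndarray | None = field(default=None, init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows must be parallel")
        if not self.rows:
            raise AlignmentError("no records")
        width = len(self.rows[0])
        if width < 1:
            raise AlignmentError("alignment has zero columns")
        self.rows = [normalize_row(r) for r in self.rows]
        for sid, row in zip(self.ids, self.rows):
            if len(row) != width:
                raise AlignmentError(f"ragged alignment at {sid}")
            bad = sorted(set(row) - ALPHABET)
            if bad:
                raise AlignmentError(
                    f"illegal characters in {sid}: {', '.join(bad)}"
                )
        self._index = {}
        for sid in self.ids:
            if sid in self._index:
                raise AlignmentError(f"duplicate id {sid}")
            self._index[sid] = len(self._index)

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self._index[seq_id]]
        except KeyError:
            raise AlignmentError(f"unknown sequence id {seq_id}") from None

    def index_of(self, seq_id: str) -> int:
        try:
            return self._index[seq_id]
        except KeyError:
            raise AlignmentError(f"unknown sequence id {seq_id}") from None

    def codes(self) -> np.ndarray:
        """Integer-coded matrix (n_sequences x n_columns), cached.

        Residues map to ``0..19``, gaps to ``-1``, ambiguity symbols to ``-2``.
        """
        if self._codes is None:
            lut = np.full(128, -3, dtype=np.int8)
            for ch, code in RESIDUE_CODES.items():
                lut[ord(ch)] = code
            buf = np.frombuffer(
                "".join(self.rows).encode("ascii"), dtype=np.uint8
            )
            self._codes = lut[buf].reshape(self.n_sequences, self.n_columns)
        return self._codes

    def subset(self, ids: list[str]) -> "MultipleAlignment":
        """Row subset in the given order (ids must exist)."""
        return MultipleAlignment(list(ids), [self.row(s) for s in ids])


@dataclass
class FamilyAnnotation:
    """Assignment of sequence ids to family (specificity-group) labels.

    ``families`` preserves the order of first appearance, which downstream
    code uses as the canonical family order.
    """

    labels: dict[str, str]
    families: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: list[str] = []
        for fam in self.labels.values():
            if fam not in seen:
                seen.append(fam)
        if self.families:
            if sorted(self.families) != sorted(seen):
                raise AlignmentError("families list inconsistent with labels")
        else:
            self.families = seen
        if not self.families:
            raise AlignmentError("annotation has no families")

    @property
    def n_families(self) -> int:
        return len(self.families)

    def members(self, family: str) -> list[str]:
        return [s for s, f in self.labels.items() if f == family]

    def family_codes(self, alignment: MultipleAlignment) -> np.ndarray:
        """Family index per alignment row, in ``families`` order."""
        fam_idx = {f: i for i, f in enumerate(self.families)}
        try:
            return np.array(
                [fam_idx[self.labels[s]] for s in alignment.ids], dtype=np.int64
            )
        except KeyError as exc:
            raise AlignmentError(f"sequence {exc.args[0]} not annotated") from None


@dataclass(frozen=True)
class ReferenceNumbering:
    """Residue numbering of a reference row.

    ``start_number`` is the residue number of the first non-gap character of
    the reference row; numbers increase by one per non-gap character.
    """

    seq_id: str
    start_number: int = 1


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the per-family sequence-set cleaning stage."""

    identity_threshold: float = 0.95
    min_bits_per_column: float = 0.5
    max_length_diff: float = 0.20
    max_seqs_per_family: int = 1000
    substitution_matrix_name: str = "BLOSUM62"

    def __post_init__(self) -> None:
        if not (0.0 < self.identity_threshold <= 1.0):
            raise ValueError("identity_threshold must be in (0, 1]")
        if self.min_bits_per_column <= 0:
            raise ValueError("min_bits_per_column must be positive")
        if self.max_length_diff <= 0:
            raise ValueError("max_length_diff must be positive")
        if self.max_seqs_per_family <= 0:
            raise ValueError("max_seqs_per_family must be positive")


# ---------------------------------------------------------------------------
# I/O


def read_alignment(path: str | Path) -> MultipleAlignment:
    """Read an aligned FASTA file into a :class:`MultipleAlignment`.

    Record order is preserved.  Ragged rows, duplicate ids and characters
    outside the alphabet are hard errors.
    """
    ids: list[str] = []
    rows: list[str] = []
    for record in SeqIO.parse(str(path), "fasta"):
        ids.append(record.id)
        rows.append(str(record.seq))
    if not ids:
        raise AlignmentError(f"no records in {path}")
    return MultipleAlignment(ids, rows)


def write_alignment(alignment: MultipleAlignment, path: str | Path) -> None:
    """Write an alignment as aligned FASTA (one record per row)."""
    records = [
        SeqRecord(Seq(row), id=sid, description="")
        for sid, row in zip(alignment.ids, alignment.rows)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_family_annotation(
    path: str | Path,
    alignment: MultipleAlignment,
    lenient: bool = False,
) -> FamilyAnnotation:
    """Read a two-column tab-separated ``seq_id<TAB>family`` file.

    Every alignment id must be annotated exactly once; family order is the
    order of first appearance in the file.  In lenient mode, unannotated
    alignment ids fall into a family named ``unassigned`` instead of raising.
    """
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise AlignmentError(
                    f"{path}:{lineno}: expected 'id<TAB>family', got {line!r}"
                )
            sid, fam = parts
            if sid in labels:
                raise AlignmentError(f"duplicate annotation for {sid}")
            if sid not in alignment._index:
                raise AlignmentError(
                    f"annotated id {sid} absent from alignment"
                )
            labels[sid] = fam
    missing = [s for s in alignment.ids if s not in labels]
    if missing:
        if lenient:
            for s in missing:
                labels[s] = "unassigned"
        else:
            raise AlignmentError(
                "alignment ids missing from annotation: " + ", ".join(missing)
            )
    return FamilyAnnotation(labels)


def write_family_annotation(
    annotation: FamilyAnnotation, path: str | Path
) -> None:
    with open(path, "w") as fh:
        for sid, fam in annotation.labels.items():
            fh.write(f"{sid}\t{fam}\n")


# ---------------------------------------------------------------------------
# Pairwise measures


def _check_equal_length(row_a: str, row_b: str) -> None:
    if len(row_a) != len(row_b):
        raise AlignmentError(
            f"rows differ in length ({len(row_a)} vs {len(row_b)})"
        )


def pairwise_identity(row_a: str, row_b: str) -> float:
    """Fraction of mutually non-gap columns at which two aligned rows agree.

    Ambiguity symbols (B/Z/X) are treated as missing observations: columns
    where either row is ambiguous contribute to neither numerator nor
    denominator.  Returns 0.0 when no mutually non-gap column exists.
    """
    _check_equal_length(row_a, row_b)
    shared = 0
    matches = 0
    for a, b in zip(row_a, row_b):
        if a == GAP or b == GAP or a in AMBIGUOUS or b in AMBIGUOUS:
            continue
        shared += 1
        if a == b:
            matches += 1
    return matches / shared if shared else 0.0


def identity_matrix(alignment: MultipleAlignment) -> np.ndarray:
    """Symmetric matrix of :func:`pairwise_identity` over all row pairs.

    Vectorized over the integer-coded alignment; semantics identical to the
    scalar function (gaps and ambiguity symbols are missing).
    """
    codes = alignment.codes()
    n = alignment.n_sequences
    valid = codes >= 0
    out = np.ones((n, n), dtype=float)
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        match = both & (codes[i] == codes[i + 1 :])
        shared = both.sum(axis=1)
        with np.errstate(invalid="ignore"):
            ident = np.where(shared > 0, match.sum(axis=1) / np.maximum(shared, 1), 0.0)
        out[i, i + 1 :] = ident
        out[i + 1 :, i] = ident
        codes_i_valid = valid[i]
        out[i, i] = 1.0 if codes_i_valid.any() else 0.0
    return out


def load_substitution_matrix(name: str = "BLOSUM62"):
    """Load a half-bit substitution matrix by name (delegates to biopython)."""
    return substitution_matrices.load(name)


def bits_per_column(row_a: str, row_b: str, matrix=None) -> float:
    """Average substitution score in bits over mutually non-gap columns.

    The matrix is in half-bit units (the BLOSUM convention), so summed scores
    are divided by two.  Returns :data:`UNDEFINED_BITS` (negative infinity)
    when the two rows share no non-gap column, which fails any finite
    threshold.
    """
    _check_equal_length(row_a, row_b)
    if matrix is None:
        matrix = load_substitution_matrix()
    total = 0.0
    shared = 0
    for a, b in zip(row_a, row_b):
        if a == GAP or b == GAP:
            continue
        try:
            total += matrix[a, b]
        except (KeyError, IndexError):
            raise AlignmentError(
                f"residue pair ({a}, {b}) absent from substitution matrix"
            ) from None
        shared += 1
    if shared == 0:
        return UNDEFINED_BITS
    return total / 2.0 / shared


# ---------------------------------------------------------------------------
# Reference numbering


def ungapped_length(row: str) -> int:
    return sum(1 for ch in row if ch != GAP)


def map_column_to_reference(
    alignment: MultipleAlignment,
    numbering: ReferenceNumbering,
    column: int,
) -> str:
    """Label a 1-based alignment column in reference-residue numbering.

    Returns e.g. ``"K199"`` if the reference row carries lysine at that
    column and it is the reference's 199th residue under ``start_number``;
    returns ``"N/A"`` where the reference row has a gap.
    """
    if not (1 <= column <= alignment.n_columns):
        raise AlignmentError(
            f"column {column} out of range 1..{alignment.n_columns}"
        )
    row = alignment.row(numbering.seq_id)
    ch = row[column - 1]
    if ch == GAP:
        return "N/A"
    nongaps = sum(1 for c in row[:column] if c != GAP)
    return f"{ch}{numbering.start_number + nongaps - 1}"
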