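"""Multiple sequence alignments: parsing, column filtering, redundancy
weighting, and mapping of alignment columns onto structure residues.

Alignments are held as an integer-encoded matrix over the 20 canonical
amino acids (codes ``0..19`` in :data:`AA_ALPHABET` order) plus a gap
code (:data:`GAP`). Non-standard letters (X, B, Z, U, O, J, ...) are
treated as gaps: they carry no usable identity for frequency counting.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import AlignIO
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import AlignmentFormatError, EmptyAlignmentError, InputError, MappingError

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
N_AA = 20
GAP = 20

_ENCODE = np.full(256, GAP, dtype=np.int8)
for _i, _aa in enumerate(AA_ALPHABET):
    _ENCODE[ord(_aa)] = _i
_DECODE = np.array(list(AA_ALPHABET + "-"))

#: Alignments with fewer distinct sequence clusters than this are
#: statistically thin for coevolution work; a warning is issued.
MIN_EFFECTIVE_SEQUENCES = 400


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an aligned row to integer codes (gap = 20)."""
    return _ENCODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def decode_row(codes: np.ndarray) -> str:
    return "".join(_DECODE[codes])


@dataclass
class MultipleAlignment:
    """An alignment as an (n_sequences, n_columns) integer matrix.

    ``column_index`` records the original (pre-filtering) column numbers,
    0-based and strictly increasing, so filtered alignments stay traceable
    to the source coordinates.
    """

    sequence_ids: list[str]
    matrix: np.ndarray
    column_index: np.ndarray
    reference_id: str | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        self.column_index = np.asarray(self.column_index, dtype=np.int64)
        if self.matrix.ndim != 2:
            raise AlignmentFormatError("alignment matrix must be 2-D")
        if len(self.sequence_ids) != self.matrix.shape[0]:
            raise AlignmentFormatError("sequence_ids/matrix row mismatch")
        if self.column_index.shape[0] != self.matrix.shape[1]:
            raise AlignmentFormatError("column_index/matrix column mismatch")
        if self.column_index.size and np.any(np.diff(self.column_index) <= 0):
            raise AlignmentFormatError("column_index must be strictly increasing")
        if self.reference_id is not None and self.reference_id not in self.sequence_ids:
            raise InputError(f"reference_id {self.reference_id!r} not in alignment")

    @property
    def n_sequences(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    @property
    def rows(self) -> list[str]:
        return [decode_row(r) for r in self.matrix]

    def reference_row(self) -> np.ndarray:
        if self.reference_id is None:
            raise InputError("alignment has no reference_id set")
        return self.matrix[self.sequence_ids.index(self.reference_id)]


@dataclass
class SequenceWeights:
    """Per-sequence redundancy weights: 1 / (size of own cluster).

    Members of one cluster sum to 1; the total weight equals the number
    of clusters (the effective sequence count).
    """

    weights: np.ndarray
    cluster_ids: np.ndarray
    cluster_count: int = field(init=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.cluster_ids = np.asarray(self.cluster_ids, dtype=np.int64)
        self.cluster_count = int(self.cluster_ids.max()) + 1 if self.cluster_ids.size else 0
        if np.any(self.weights < 0):
            raise InputError("sequence weights must be nonnegative")


_FORMATS = {"fasta": "fasta", "stockholm": "stockholm"}
_EXT_FORMATS = {
    ".fa": "fasta", ".fasta": "fasta", ".afa": "fasta", ".mfa": "fasta",
    ".sto": "stockholm", ".stk": "stockholm", ".stockholm": "stockholm",
}


def read_alignment(
    path: str | Path,
    format: str | None = None,
    reference_id: str | None = None,
) -> MultipleAlignment:
    """Read a FASTA or Stockholm alignment.

    Rows are uppercased; ``.`` gaps and non-standard residue letters are
    mapped to the gap code. Ragged inputs raise
    :class:`AlignmentFormatError`, empty files :class:`EmptyAlignmentError`.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"alignment file not found: {path}")
    if format is None:
        format = _EXT_FORMATS.get(path.suffix.lower(), "fasta")
    if format not in _FORMATS:
        raise InputError(f"unsupported alignment format {format!r}")
    text = path.read_text()
    if not text.strip():
        raise EmptyAlignmentError(f"empty alignment file: {path}")
    try:
        aln = AlignIO.read(_io.StringIO(text), _FORMATS[format])
    except ValueError as exc:
        raise AlignmentFormatError(f"cannot parse {path} as {format}: {exc}") from exc
    ids = [rec.id for rec in aln]
    if not ids:
        raise EmptyAlignmentError(f"no sequences in {path}")
    matrix = np.vstack([encode_sequence(str(rec.seq)) for rec in aln])
    return MultipleAlignment(
        sequence_ids=ids,
        matrix=matrix,
        column_index=np.arange(matrix.shape[1]),
        reference_id=reference_id,
    )


def filter_columns(aln: MultipleAlignment, min_coverage: float = 0.8) -> MultipleAlignment:
    """Keep columns whose non-gap fraction is at least ``min_coverage``.

    The 0.8 default is the usual column-inclusion threshold for family
    alignments used in coevolution scoring.
    """
    if not 0 < min_coverage <= 1:
        raise InputError("min_coverage must be in (0, 1]")
    coverage = (aln.matrix != GAP).mean(axis=0)
    keep = coverage >= min_coverage
    if not keep.any():
        raise EmptyAlignmentError("no columns survive the coverage filter")
    return MultipleAlignment(
        sequence_ids=list(aln.sequence_ids),
        matrix=aln.matrix[:, keep],
        column_index=aln.column_index[keep],
        reference_id=aln.reference_id,
    )


def pairwise_identity(matrix: np.ndarray) -> np.ndarray:
    """Fraction of matching residues over mutually ungapped positions.

    Pairs with no mutually ungapped position get identity 0.
    """
    n = matrix.shape[0]
    ungapped = matrix != GAP
    ident = np.zeros((n, n))
    for i in range(n):
        both = ungapped[i] & ungapped
        match = (matrix[i] == matrix) & both
        denom = both.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            row = np.where(denom > 0, match.sum(axis=1) / np.maximum(denom, 1), 0.0)
        ident[i] = row
    np.fill_diagonal(ident, 1.0)
    return ident


def cluster_weights(
    aln: MultipleAlignment, identity_threshold: float = 0.62
) -> SequenceWeights:
    """Single-linkage sequence clustering at a pairwise identity threshold.

    Clusters are the connected components of the >= ``identity_threshold``
    identity graph (the single-linkage closure, independent of input
    order); each sequence is weighted 1/|its cluster|. The 62% default is
    the usual redundancy threshold for MI-based coevolution scoring.
    """
    if not 0 < identity_threshold < 1:
        raise InputError("identity_threshold must be in (0, 1)")
    ident = pairwise_identity(aln.matrix)
    adj = csr_matrix(ident >= identity_threshold)
    n_comp, labels = connected_components(adj, directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    weights = 1.0 / sizes[labels]
    if n_comp < MIN_EFFECTIVE_SEQUENCES:
        import warnings

        warnings.warn(
            f"only {n_comp} sequence clusters at identity "
            f"{identity_threshold:.0%}; coevolution statistics are usually "
            f"considered reliable from {MIN_EFFECTIVE_SEQUENCES} clusters",
            stacklevel=2,
        )
    return SequenceWeights(weights=weights, cluster_ids=labels)


@dataclass
class ColumnResidueMap:
    """Bijection between surviving alignment columns and residue numbers.

    ``column_to_residue`` is keyed by original column index (as stored in
    ``MultipleAlignment.column_index``); residues of the structure not
    covered by any column are listed in ``unmapped_residues``.
    """

    column_to_residue: dict[int, int]
    residue_to_column: dict[int, int]
    unmapped_columns: list[int]
    unmapped_residues: list[int]
    n_mismatches: int


def map_alignment_to_structure(
    aln: MultipleAlignment,
    residue_numbers: list[int],
    residue_letters: str,
    mismatch_tolerance: float = 0.05,
) -> ColumnResidueMap:
    """Map alignment columns to structure residues via the reference row.

    The k-th ungapped reference position is paired with the k-th structure
    residue. A mismatch fraction above ``mismatch_tolerance`` raises
    :class:`MappingError` listing the offending positions.
    """
    ref = aln.reference_row()
    letters = encode_sequence(residue_letters)
    if len(residue_numbers) != len(letters):
        raise MappingError("residue_numbers and residue_letters length mismatch")
    ungapped_cols = np.nonzero(ref != GAP)[0]
    n_pair = min(len(ungapped_cols), len(letters))
    mism = [
        int(ungapped_cols[k])
        for k in range(n_pair)
        if ref[ungapped_cols[k]] != letters[k]
    ]
    if n_pair and len(mism) / n_pair > mismatch_tolerance:
        shown = ", ".join(str(aln.column_index[c]) for c in mism[:20])
        raise MappingError(
            f"{len(mism)}/{n_pair} reference/structure mismatches "
            f"(tolerance {mismatch_tolerance:.0%}); offending original "
            f"columns: {shown}"
        )
    col_to_res: dict[int, int] = {}
    res_to_col: dict[int, int] = {}
    for k in range(n_pair):
        col = int(aln.column_index[ungapped_cols[k]])
        res = int(residue_numbers[k])
        col_to_res[col] = res
        res_to_col[res] = col
    unmapped_cols = [
        int(aln.column_index[c]) for c in range(aln.n_columns)
        if int(aln.column_index[c]) not in col_to_res
    ]
    unmapped_res = [int(r) for r in residue_numbers if int(r) not in res_to_col]
    return ColumnResidueMap(
        column_to_residue=col_to_res,
        residue_to_column=res_to_col,
        unmapped_columns=unmapped_cols,
        unmapped_residues=unmapped_res,
        n_mismatches=len(mism),
    )
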