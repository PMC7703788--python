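"""Query-anchored multiple sequence alignments and effective sequence counts.

The central quantity here is Neff, the effective number of non-redundant
sequences in an alignment:

    Neff = sum_i 1 / weight_i

where ``weight_i`` counts the rows (including row i itself) whose pairwise
sequence identity with row i is at least 62%. An alignment of N mutually
dissimilar sequences has Neff = N; N copies of one sequence have Neff = 1.
Neff is the standard proxy for how much independent evolutionary signal an
alignment carries into coevolution-based contact prediction.

Alignments are query-anchored: columns correspond to query positions, the
query is row 0 and carries no gaps, and every row has the same length L.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP_CHARS = frozenset("-.")
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# integer codes: 0 = gap, 1..20 = amino acids, 21 = X / unknown (matches nothing)
_GAP_CODE = 0
_X_CODE = 21
_CODE_OF = {aa: i + 1 for i, aa in enumerate(AMINO_ACIDS)}

DenominatorMode = Literal["union", "full_length"]


class MsaError(ValueError):
    """Raised for malformed alignments or alignment files."""


@dataclass
class DomainSegment:
    """1-based inclusive interval [start, end] on the query sequence.

    ``kind`` distinguishes ab initio "hard" domains (under-covered regions
    detected from the alignment) from the "full"-length segment.
    """

    start: int
    end: int
    kind: Literal["hard", "full"] = "hard"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid segment [{self.start}, {self.end}]: need 1 <= start <= end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.start}-{self.end}({self.kind})"


@dataclass
class MSA:
    """A query-anchored alignment: the query plus aligned homolog rows.

    Row 0 is always the query itself, so N >= 1. All rows share length L and
    the query sequence carries no gap characters.
    """

    query_id: str
    query_seq: str
    rows: list[str]
    row_ids: list[str]
    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.rows:
            raise MsaError("alignment has no rows")
        L = len(self.rows[0])
        if L < 1:
            raise MsaError("alignment has zero columns")
        for rid, row in zip(self.row_ids, self.rows):
            if len(row) != L:
                raise MsaError(
                    f"row {rid!r} has length {len(row)}, expected {L}"
                )
        if len(self.row_ids) != len(self.rows):
            raise MsaError("row_ids and rows differ in length")
        if any(c in GAP_CHARS for c in self.query_seq):
            raise MsaError("query sequence must not contain gaps")
        if len(self.query_seq) != L:
            raise MsaError("query length differs from alignment width")
        if self.rows[0].upper() != self.query_seq.upper():
            raise MsaError("row 0 must be the query sequence")

    @property
    def L(self) -> int:
        """Alignment width == query length."""
        return len(self.query_seq)

    @property
    def N(self) -> int:
        """Number of rows, query included."""
        return len(self.rows)

    def codes(self) -> np.ndarray:
        """(N, L) int8 matrix of residue codes; cached."""
        if self._codes is None:
            self._codes = _encode_rows(self.rows)
        return self._codes


def _encode_rows(rows: Sequence[str]) -> np.ndarray:
    out = np.empty((len(rows), len(rows[0])), dtype=np.int8)
    for i, row in enumerate(rows):
        out[i] = [_encode_char(c) for c in row]
    return out


def _encode_char(c: str) -> int:
    if c in GAP_CHARS:
        return _GAP_CODE
    return _CODE_OF.get(c.upper(), _X_CODE)


# ---------------------------------------------------------------------------
# I/O


def read_msa(path: str | Path, dialect: Literal["aligned-fasta", "a3m"] = "aligned-fasta") -> MSA:
    """Read an alignment from FASTA-style text.

    ``aligned-fasta`` expects equal-length upper-case rows. ``a3m`` rows carry
    lowercase insertion states which are stripped to restore query-anchored
    columns. In either dialect, columns where the first (query) row holds a
    gap are insertion columns relative to the query and are removed, so the
    returned MSA is strictly query-anchored.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise MsaError(f"{path}: no sequences found")
    ids = [r.id for r in records]
    rows = [str(r.seq) for r in records]
    if dialect == "a3m":
        rows = ["".join(c for c in row if not c.islower()) for row in rows]
    elif dialect != "aligned-fasta":
        raise ValueError(f"unknown dialect {dialect!r}")
    rows = [row.upper() for row in rows]
    L0 = len(rows[0])
    for rid, row in zip(ids, rows):
        if len(row) != L0:
            raise MsaError(
                f"{path}: row {rid!r} has length {len(row)}, expected {L0}"
            )
    # drop columns where the query is gapped (insertions relative to query)
    keep = [i for i, c in enumerate(rows[0]) if c not in GAP_CHARS]
    if len(keep) != L0:
        rows = ["".join(row[i] for i in keep) for row in rows]
    return MSA(query_id=ids[0], query_seq=rows[0], rows=rows, row_ids=ids)


def write_msa(msa: MSA, path: str | Path) -> None:
    """Write the alignment as aligned FASTA."""
    records = [
        SeqRecord(Seq(row), id=rid, description="")
        for rid, row in zip(msa.row_ids, msa.rows)
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Identity, weights, Neff


def pairwise_identity(
    a: str, b: str, denominator: DenominatorMode = "union"
) -> float:
    """Sequence identity between two aligned rows, in [0, 1].

    Matches are counted over columns where both rows carry the same amino
    acid ('X' matches nothing, not even itself). With the default "union"
    denominator the count is divided by the number of columns where at least
    one row is non-gap, so coverage differences are penalized; gap-vs-gap
    columns are excluded. With "full_length" the denominator is the full
    alignment width.
    """
    if len(a) != len(b):
        raise ValueError("rows have different lengths")
    ca = np.array([_encode_char(c) for c in a], dtype=np.int8)
    cb = np.array([_encode_char(c) for c in b], dtype=np.int8)
    matchable = (ca >= 1) & (ca <= 20)
    matches = int(np.sum((ca == cb) & matchable))
    if denominator == "full_length":
        return matches / len(a)
    denom = int(np.sum((ca != _GAP_CODE) | (cb != _GAP_CODE)))
    if denom == 0:
        raise ValueError("identity undefined: both rows are entirely gaps")
    return matches / denom


@dataclass
class SequenceWeights:
    """Per-row redundancy weights: weight_i = number of rows (self included)
    whose identity with row i is >= identity_threshold."""

    per_row_weight: np.ndarray  # positive integers, length N
    identity_threshold: float = 0.62


def sequence_weights(
    msa: MSA,
    threshold: float = 0.62,
    denominator: DenominatorMode = "union",
) -> SequenceWeights:
    """Count, for each row, how many rows lie within the identity threshold.

    The pairwise weight is binary: 1 if identity >= threshold, else 0; a row
    always counts itself, so every weight is >= 1.
    """
    codes = msa.codes()
    N, L = codes.shape
    matchable = (codes >= 1) & (codes <= 20)
    nongap = codes != _GAP_CODE
    weights = np.ones(N, dtype=np.int64)
    for i in range(N):
        eq = (codes == codes[i]) & matchable & matchable[i]
        matches = eq.sum(axis=1)
        if denominator == "full_length":
            denom = np.full(N, L, dtype=np.int64)
        else:
            denom = (nongap | nongap[i]).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ident = np.where(denom > 0, matches / np.maximum(denom, 1), 0.0)
        similar = ident >= threshold
        similar[i] = False  # self counted unconditionally via the initial 1
        weights[i] += int(similar.sum())
    return SequenceWeights(per_row_weight=weights, identity_threshold=threshold)


def compute_neff(
    msa: MSA,
    threshold: float = 0.62,
    denominator: DenominatorMode = "union",
) -> float:
    """Effective sequence count: Neff = sum_i 1/weight_i, in [1, N]."""
    w = sequence_weights(msa, threshold=threshold, denominator=denominator)
    return float(np.sum(1.0 / w.per_row_weight))


def extract_domain_msa(msa: MSA, segment: DomainSegment) -> MSA:
    """Slice columns [start, end] (1-based inclusive) from every row.

    Rows that are entirely gaps within the segment carry no evolutionary
    signal there and are dropped; the query row is always retained.
    """
    if segment.end > msa.L:
        raise ValueError(
            f"segment [{segment.start}, {segment.end}] exceeds alignment width {msa.L}"
        )
    lo, hi = segment.start - 1, segment.end
    new_rows: list[str] = []
    new_ids: list[str] = []
    for idx, (rid, row) in enumerate(zip(msa.row_ids, msa.rows)):
        piece = row[lo:hi]
        if idx > 0 and all(c in GAP_CHARS for c in piece):
            continue
        new_rows.append(piece)
        new_ids.append(rid)
    return MSA(
        query_id=msa.query_id,
        query_seq=msa.query_seq[lo:hi],
        rows=new_rows,
        row_ids=new_ids,
    )


def domain_neff(
    msa: MSA,
    segment: DomainSegment,
    threshold: float = 0.62,
    denominator: DenominatorMode = "union",
) -> float:
    """Neff of the alignment restricted to a domain segment."""
    return compute_neff(
        extract_domain_msa(msa, segment), threshold=threshold, denominator=denominator
    )
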