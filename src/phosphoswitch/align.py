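"""Pairwise and group alignment primitives.

Alignments are consumed, never computed: pairwise query<->template
alignments and orthologue-group multiple alignments arrive as aligned
FASTA. Sequence positions are 1-based throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from Bio import AlignIO, SeqIO

GAP_CHARS = frozenset("-.")


def _is_gap(c: str) -> bool:
    return c in GAP_CHARS


@dataclass(frozen=True)
class PairwiseAlignment:
    """A pairwise alignment of a query sequence to a template chain."""

    query_id: str
    template_id: str
    query_aln: str
    template_aln: str

    def __post_init__(self) -> None:
        if len(self.query_aln) != len(self.template_aln):
            raise ValueError("aligned sequences differ in length")

    @property
    def query_length(self) -> int:
        return sum(1 for c in self.query_aln if not _is_gap(c))

    @property
    def template_length(self) -> int:
        return sum(1 for c in self.template_aln if not _is_gap(c))

    def aligned_columns(self) -> list[tuple[int, int, str, str]]:
        """Columns where neither sequence is gapped.

        Returns (query_pos, template_pos, query_aa, template_aa) tuples
        with 1-based positions.
        """
        out = []
        qp = tp = 0
        for qc, tc in zip(self.query_aln, self.template_aln):
            if not _is_gap(qc):
                qp += 1
            if not _is_gap(tc):
                tp += 1
            if not _is_gap(qc) and not _is_gap(tc):
                out.append((qp, tp, qc, tc))
        return out

    def identity(self) -> float:
        """Fraction of identical residues over aligned (non-gap-pair) columns."""
        cols = self.aligned_columns()
        if not cols:
            raise ValueError("alignment has no aligned columns")
        ident = sum(1 for _, _, q, t in cols if q.upper() == t.upper())
        return ident / len(cols)

    def coverage(self) -> float:
        """Fraction of the query sequence covered by aligned columns."""
        n = self.query_length
        if n == 0:
            raise ValueError("query sequence is empty")
        return len(self.aligned_columns()) / n

    def map_query_to_template(self, pos: int) -> Optional[tuple[int, str]]:
        """Template (position, residue) aligned to query position ``pos``.

        Returns None when the query position falls against a gap in the
        template. Raises if ``pos`` lies outside the query sequence.
        """
        if pos < 1 or pos > self.query_length:
            raise IndexError(
                f"position {pos} outside query {self.query_id!r} "
                f"(length {self.query_length})"
            )
        qp = tp = 0
        for qc, tc in zip(self.query_aln, self.template_aln):
            if not _is_gap(qc):
                qp += 1
            if not _is_gap(tc):
                tp += 1
            if qp == pos and not _is_gap(qc):
                if _is_gap(tc):
                    return None
                return tp, tc.upper()
        return None  # unreachable given the bounds check

    def map_template_to_query(self, pos: int) -> Optional[tuple[int, str]]:
        """Inverse mapping; see :meth:`map_query_to_template`."""
        return self.swapped().map_query_to_template(pos)

    def swapped(self) -> "PairwiseAlignment":
        return PairwiseAlignment(
            self.template_id, self.query_id, self.template_aln, self.query_aln
        )


def read_pairwise_fasta(path: str | Path) -> PairwiseAlignment:
    """Read a two-record aligned FASTA (query first, template second)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(f"{path}: expected exactly 2 aligned records, got {len(records)}")
    q, t = records
    return PairwiseAlignment(q.id, t.id, str(q.seq), str(t.seq))


def read_group_alignment(path: str | Path):
    """Read an orthologue-group multiple alignment (aligned FASTA)."""
    return AlignIO.read(str(path), "fasta")
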