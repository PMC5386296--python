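"""Per-site covariates: template mapping, f_ID, f_Cons, disorder, exposure,
and redundancy grouping.

f_ID is the minimum fraction of identical residues between each interacting
protein and its structural template chain. f_Cons is the fraction of
sequences in the site's orthologue-group alignment carrying the same amino
acid — or Asp/Glu, the phosphomimetic residues — at the site's column;
gapped sequences count in the denominator only. Sites in proteins covered
by no group alignment fall back to the species average over all S/T/Y
sites. Disorder and burial follow fixed thresholds: mean disorder >= 0.5
over an 11-residue window, side-chain ASA < 5 Å² buried.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .align import GAP_CHARS, PairwiseAlignment

logger = logging.getLogger(__name__)

THROUGHPUT_CLASSES = ("stp", "ltp", "mtp", "htp", "utp", "N/A")
CONSERVED_EXTRA = frozenset("DE")  # phosphomimetic residues count as conserved


@dataclass
class SiteRecord:
    """A phosphosite or background S/T/Y in a protein sequence."""

    protein_acc: str
    species: str
    pos: int
    wild_aa: str
    status: str = "phospho"  # phospho | background | ambiguous
    sources: tuple[str, ...] = ()
    throughput: str = "N/A"

    def __post_init__(self) -> None:
        if self.wild_aa not in "STY":
            raise ValueError(f"site residue must be S, T or Y, got {self.wild_aa!r}")
        if self.status not in ("phospho", "background", "ambiguous"):
            raise ValueError(f"unknown site status {self.status!r}")
        if self.throughput not in THROUGHPUT_CLASSES:
            raise ValueError(f"unknown throughput class {self.throughput!r}")

    @property
    def site_label(self) -> str:
        return f"{self.wild_aa}{self.pos}"


@dataclass
class TemplateMatch:
    """A site mapped onto a residue of a template interface chain."""

    site: SiteRecord
    interface_id: tuple
    template_chain: str
    template_pos: int
    template_icode: str
    template_aa: str
    f_id: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_id <= 1.0:
            raise ValueError("f_ID must lie in [0, 1]")


@dataclass
class OrthologyProfile:
    """Conservation of a site column across an orthologue group."""

    group_id: str
    n_sequences: int
    column_composition: dict[str, int]
    f_cons: float
    fallback_used: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_cons <= 1.0:
            raise ValueError("f_Cons must lie in [0, 1]")


@dataclass
class SiteAnnotation:
    site: SiteRecord
    disordered: Optional[bool] = None
    exposed: Optional[bool] = None
    nr_group_id: Optional[tuple] = None


def map_site_to_template(
    site: SiteRecord, pairwise_alignment: PairwiseAlignment
) -> Optional[tuple[int, str]]:
    """Template (position, amino acid) aligned to the site.

    Positional information transfers through the alignment even when the
    aligned amino acids differ. Returns None when the template is gapped
    at the site; raises when the site lies outside the alignment.
    """
    try:
        return pairwise_alignment.map_query_to_template(site.pos)
    except IndexError as exc:
        raise IndexError(f"site {site.site_label} of {site.protein_acc}: {exc}") from exc


def fraction_identity(
    aln_chain1: PairwiseAlignment, aln_chain2: Optional[PairwiseAlignment] = None
) -> float:
    """f_ID: minimum identity of the two query->template chain alignments.

    For homodimers the two alignments coincide and one may be given.
    """
    id1 = aln_chain1.identity()
    if aln_chain2 is None:
        return id1
    return min(id1, aln_chain2.identity())


def _column_of_position(row: str, pos: int) -> int:
    """Alignment column index (0-based) of the ``pos``-th residue of a row."""
    seen = 0
    for col, c in enumerate(row):
        if c not in GAP_CHARS:
            seen += 1
            if seen == pos:
                return col
    raise IndexError(f"position {pos} beyond ungapped length {seen}")


def conservation_fraction(
    group_alignment,
    protein_acc: str,
    pos: int,
    wild_aa: str,
    species_average: Optional[float] = None,
    group_id: str = "",
) -> OrthologyProfile:
    """f_Cons of a site from its orthologue-group alignment.

    Counts sequences whose residue at the site's column is the wild amino
    acid or Asp/Glu, over all sequences in the group (gapped sequences in
    the denominator only). When ``group_alignment`` is None the species
    average is used and flagged.
    """
    if group_alignment is None:
        if species_average is None:
            raise ValueError("no group alignment and no species-average fallback")
        return OrthologyProfile(
            group_id=group_id or "species-average",
            n_sequences=0,
            column_composition={},
            f_cons=species_average,
            fallback_used=True,
        )

    rows = {rec.id: str(rec.seq) for rec in group_alignment}
    if protein_acc not in rows:
        if species_average is None:
            raise KeyError(f"{protein_acc} not in group alignment and no fallback")
        return OrthologyProfile(
            group_id=group_id or "species-average",
            n_sequences=0,
            column_composition={},
            f_cons=species_average,
            fallback_used=True,
        )
    col = _column_of_position(rows[protein_acc], pos)

    composition: dict[str, int] = {}
    conserved = 0
    for seq in rows.values():
        c = seq[col].upper() if seq[col] not in GAP_CHARS else "-"
        composition[c] = composition.get(c, 0) + 1
        if c == wild_aa or c in CONSERVED_EXTRA:
            conserved += 1
    n = len(rows)
    return OrthologyProfile(
        group_id=group_id,
        n_sequences=n,
        column_composition=composition,
        f_cons=conserved / n,
        fallback_used=False,
    )


def classify_disorder(
    scores: Mapping[int, float] | Sequence[float],
    pos: int,
    window: int = 11,
    cutoff: float = 0.5,
) -> Optional[bool]:
    """Disorder flag: window mean of per-residue disorder >= cutoff (inclusive).

    ``scores`` maps 1-based positions to values in [0, 1] (a sequence is
    taken as positions 1..n). The window is centred on the site and
    truncated at the termini. Returns None when the site itself is not
    covered by the scores.
    """
    if not isinstance(scores, Mapping):
        scores = {i + 1: s for i, s in enumerate(scores)}
    if pos not in scores:
        return None
    half = window // 2
    vals = [scores[p] for p in range(pos - half, pos + half + 1) if p in scores]
    return (sum(vals) / len(vals)) >= cutoff


def classify_exposure(asa: Optional[float], buried_cutoff: float = 5.0) -> Optional[str]:
    """'buried' when side-chain ASA < cutoff (Å²), 'exposed' otherwise.

    Returns None when the ASA is unavailable.
    """
    if asa is None:
        return None
    return "buried" if asa < buried_cutoff else "exposed"


@dataclass
class RedundancyResult:
    annotations: list[SiteAnnotation]
    n_phospho_nr: int
    n_background_nr: int
    n_ambiguous: int
    excluded_members: list[tuple[str, str]] = field(default_factory=list)


def group_redundant_sites(
    sites: Sequence[SiteRecord],
    group_alignments: Mapping[str, object],
    max_gap_fraction: float = 0.09,
) -> RedundancyResult:
    """Collapse sites to non-redundant (group, column) keys.

    Group members whose gap fraction (gaps divided by the member's
    ungapped sequence length) reaches ``max_gap_fraction`` are dropped from
    grouping; their sites stand alone. Background sites sharing a column
    with any phosphosite become ambiguous and are excluded from the counts.
    Grouping is idempotent and ungrouped proteins form singleton groups.
    """
    member_of: dict[str, tuple[str, str]] = {}  # protein -> (group_id, row)
    excluded: list[tuple[str, str]] = []
    for group_id in sorted(group_alignments):
        for rec in group_alignments[group_id]:
            row = str(rec.seq)
            length = sum(1 for c in row if c not in GAP_CHARS)
            gaps = sum(1 for c in row if c in GAP_CHARS)
            if length == 0 or gaps / length >= max_gap_fraction:
                excluded.append((group_id, rec.id))
                logger.info(
                    "member %s of group %s excluded (gap fraction %.3f)",
                    rec.id, group_id, gaps / max(length, 1),
                )
                continue
            member_of.setdefault(rec.id, (group_id, row))

    annotations = []
    key_status: dict[tuple, set[str]] = {}
    for site in sites:
        membership = member_of.get(site.protein_acc)
        if membership is None:
            key: tuple = ("singleton", site.protein_acc, site.pos)
        else:
            group_id, row = membership
            try:
                col = _column_of_position(row, site.pos)
            except IndexError:
                key = ("singleton", site.protein_acc, site.pos)
            else:
                key = ("group", group_id, col)
        annotations.append(SiteAnnotation(site=site, nr_group_id=key))
        key_status.setdefault(key, set()).add(site.status)

    phospho_keys = set()
    background_keys = set()
    n_ambiguous = 0
    for ann in annotations:
        statuses = key_status[ann.nr_group_id]
        if ann.site.status == "background" and "phospho" in statuses:
            ann.site.status = "ambiguous"
        if ann.site.status == "ambiguous":
            n_ambiguous += 1
        elif ann.site.status == "phospho":
            phospho_keys.add(ann.nr_group_id)
        else:
            background_keys.add(ann.nr_group_id)

    return RedundancyResult(
        annotations=annotations,
        n_phospho_nr=len(phospho_keys),
        n_background_nr=len(background_keys),
        n_ambiguous=n_ambiguous,
        excluded_members=excluded,
    )
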