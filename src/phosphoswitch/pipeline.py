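"""End-to-end site scoring: annotate -> map -> IE -> S_switch -> classify.

Input layout
------------
sites TSV        columns: protein, species, site (e.g. "T879"), optional
                 source, pubmed, throughput.
structures dir   ``<struct_id>.pdb`` / ``.cif`` template complexes.
alignments dir   pairwise files ``<protein>__<struct_id>__<chain>.fasta``
                 (query first, template chain second), plus an optional
                 ``groups/`` subdirectory of orthologue-group alignments.
disorder TSV     columns: protein, pos, score (per-residue, in [0, 1]).
matrix TSV       labelled pair-potential matrix.

Every input site appears in the output with a status: ``scored``,
``unmapped`` (no alignment or gapped at the site), ``buried-only``
(mapped, but the template residue is buried) or ``no-interface`` (mapped
and exposed, but no inter-chain contact). Scores are aggregated over
templates per site x interactor by largest |S_switch|.
"""

from __future__ import annotations

import logging
from collections import Counter
from pathlib import Path
from typing import Optional

import pandas as pd

from . import annotate, scoring, structures
from .align import read_group_alignment, read_pairwise_fasta
from .config import Config
from .potentials import read_matrix

logger = logging.getLogger(__name__)

OUTPUT_COLUMNS = [
    "protein", "species", "site", "interactor", "template", "pdbres",
    "IE", "f_ID", "f_Cons", "S_switch", "label", "status", "throughput",
]


def _parse_site(text: str) -> tuple[str, int]:
    aa = text[0].upper()
    digits = "".join(ch for ch in text[1:] if ch.isdigit())
    if aa not in "STY" or not digits:
        raise ValueError(f"cannot parse site {text!r} (expected e.g. 'T879')")
    return aa, int(digits)


def _load_disorder(path: Optional[str | Path]) -> dict[str, dict[int, float]]:
    if path is None:
        return {}
    frame = pd.read_csv(path, sep="\t")
    out: dict[str, dict[int, float]] = {}
    for _, row in frame.iterrows():
        out.setdefault(str(row["protein"]), {})[int(row["pos"])] = float(row["score"])
    return out


def score_sites_pipeline(
    sites_tsv: str | Path,
    structures_dir: str | Path,
    alignments_dir: str | Path,
    matrix_tsv: str | Path,
    disorder_tsv: Optional[str | Path] = None,
    config: Optional[Config] = None,
    out_tsv: Optional[str | Path] = None,
) -> pd.DataFrame:
    """Score every site x interface x template and aggregate per interactor.

    Deterministic given identical inputs and configuration. Per-site
    mapping failures are logged, never fatal; a missing matrix is fatal.
    Returns the aggregated table (and writes it when ``out_tsv`` given),
    with scores rounded to 4 decimals.
    """
    cfg = config or Config()
    matrix = read_matrix(matrix_tsv)
    sites = pd.read_csv(sites_tsv, sep="\t", dtype=str)
    alignments_dir = Path(alignments_dir)
    structures_dir = Path(structures_dir)
    disorder = _load_disorder(disorder_tsv)

    group_dir = alignments_dir / "groups"
    groups = {}
    if group_dir.is_dir():
        for p in sorted(group_dir.glob("*.fasta")):
            groups[p.stem] = read_group_alignment(p)

    struct_cache: dict[str, structures.StructureModel] = {}
    asa_cache: dict[str, dict] = {}
    counters: Counter = Counter()
    rows = []

    for _, srow in sites.iterrows():
        protein = str(srow["protein"])
        species = str(srow.get("species", "") or "")
        throughput = str(srow.get("throughput", "N/A") or "N/A")
        try:
            wild_aa, pos = _parse_site(str(srow["site"]))
        except ValueError as exc:
            logger.warning("%s", exc)
            continue
        site = annotate.SiteRecord(
            protein_acc=protein, species=species, pos=pos, wild_aa=wild_aa,
            throughput=throughput if throughput in annotate.THROUGHPUT_CLASSES else "N/A",
        )
        counters["sites"] += 1

        dscores = disorder.get(protein)
        disordered = (
            annotate.classify_disorder(dscores, pos, cfg.disorder_window, cfg.disorder_cutoff)
            if dscores else None
        )
        if disordered:
            counters["disordered"] += 1
        else:
            counters["ordered"] += 1

        # f_Cons: first group containing the protein, in sorted order
        f_cons = cfg.species_fcons_fallback
        for gid in sorted(groups):
            ids = {rec.id for rec in groups[gid]}
            if protein in ids:
                profile = annotate.conservation_fraction(
                    groups[gid], protein, pos, wild_aa, group_id=gid
                )
                f_cons = profile.f_cons
                break

        aln_files = sorted(alignments_dir.glob(f"{protein}__*.fasta"))
        if not aln_files:
            rows.append(_row(site, species, "", "", "", None, None, f_cons, None,
                             "", "unmapped", throughput))
            counters["unmapped"] += 1
            continue

        per_interactor: dict[str, list[scoring.SwitchScore]] = {}
        statuses = []
        for aln_path in aln_files:
            parts = aln_path.stem.split("__")
            if len(parts) != 3:
                logger.warning("ignoring alignment file %s (bad name)", aln_path.name)
                continue
            _, struct_id, chain_id = parts
            aln = read_pairwise_fasta(aln_path)
            try:
                mapped = annotate.map_site_to_template(site, aln)
            except IndexError as exc:
                logger.warning("%s", exc)
                statuses.append("unmapped")
                continue
            if mapped is None:
                statuses.append("unmapped")
                continue
            tpos, taa = mapped

            if struct_id not in struct_cache:
                spath = next(
                    (structures_dir / f"{struct_id}{ext}" for ext in (".pdb", ".cif")
                     if (structures_dir / f"{struct_id}{ext}").exists()),
                    None,
                )
                if spath is None:
                    logger.warning("structure %s not found; template skipped", struct_id)
                    continue
                struct_cache[struct_id] = structures.read_structure(spath)
                asa_cache[struct_id] = structures.sidechain_asa(struct_cache[struct_id])
            model = struct_cache[struct_id]

            chain_res = [model.residues[i] for i in model.chain_residue_indices(chain_id)]
            if tpos < 1 or tpos > len(chain_res):
                logger.warning("mapped position %d outside chain %s of %s",
                               tpos, chain_id, struct_id)
                statuses.append("unmapped")
                continue
            tres = chain_res[tpos - 1]
            exposure = annotate.classify_exposure(
                asa_cache[struct_id].get(tres.key), cfg.asa_buried_cutoff
            )

            found_interface = False
            for other in model.chains:
                if other == chain_id:
                    continue
                iface = structures.find_interface_contacts(
                    model, chain_id, other, cfg.contact_cutoff
                )
                if not iface.edges_for(tres.chain_id, tres.seq_pos, tres.icode):
                    continue
                found_interface = True
                ie = scoring.site_interaction_effect(
                    iface, tres.chain_id, tres.seq_pos, matrix, tres.icode
                )
                # partner chain alignment, if any protein aligns to it
                partner_alns = sorted(alignments_dir.glob(f"*__{struct_id}__{other}.fasta"))
                f_id = aln.identity()
                interactor = f"{struct_id}:{other}"
                if partner_alns:
                    paln = read_pairwise_fasta(partner_alns[0])
                    f_id = annotate.fraction_identity(aln, paln)
                    interactor = paln.query_id
                sc = scoring.make_switch_score(
                    site_label=site.site_label,
                    protein_acc=protein,
                    interactor_acc=interactor,
                    interface_id=iface.interface_id,
                    ie=ie,
                    f_id=f_id,
                    f_cons=f_cons,
                    threshold=cfg.switch_threshold,
                )
                sc.template_residue = f"{chain_id}{tres.seq_pos}{tres.icode}{tres.aa}"
                per_interactor.setdefault(interactor, []).append(sc)
            statuses.append("scored" if found_interface else
                            ("buried-only" if exposure == "buried" else "no-interface"))
            if exposure == "exposed":
                counters["exposed"] += 1
            elif exposure == "buried":
                counters["buried"] += 1

        if per_interactor:
            counters["interface"] += 1
            for interactor, scs in sorted(per_interactor.items()):
                best = scoring.aggregate_templates(scs)
                counters[best.label] += 1
                rows.append(_row(site, species, interactor,
                                 "|".join(str(x) for x in best.interface_id),
                                 best.template_residue, best.ie, best.f_id,
                                 best.f_cons, best.s_switch, best.label,
                                 "scored", throughput))
        else:
            status = "unmapped"
            for cand in ("no-interface", "buried-only"):
                if cand in statuses:
                    status = cand
            counters[status] += 1
            rows.append(_row(site, species, "", "", "", None, None, f_cons, None,
                             "", status, throughput))

    for key in ("sites", "ordered", "disordered", "exposed", "buried",
                "interface", "enabling", "disabling", "neutral", "unmapped"):
        logger.info("pipeline counter %-12s %d", key, counters[key])

    frame = pd.DataFrame(rows, columns=OUTPUT_COLUMNS)
    if out_tsv is not None:
        frame.to_csv(out_tsv, sep="\t", index=False)
    return frame


def _row(site, species, interactor, template, pdbres, ie, f_id, f_cons, s,
         label, status, throughput):
    rnd = lambda v: None if v is None else round(v, 4)
    return {
        "protein": site.protein_acc, "species": species, "site": site.site_label,
        "interactor": interactor, "template": template, "pdbres": pdbres,
        "IE": rnd(ie), "f_ID": rnd(f_id), "f_Cons": rnd(f_cons),
        "S_switch": rnd(s), "label": label, "status": status,
        "throughput": throughput,
    }
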