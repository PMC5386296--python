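"""Structure parsing, interface contacts, side-chain ASA and interface matching.

Structures are read with gemmi (PDB or mmCIF). Only the 20 standard amino
acids and the phosphorylated residues SEP/TPO/PTR are retained; hydrogens
are dropped and, for alternate conformations, only the highest-occupancy
conformer of each atom is kept. Residue numbering is author numbering with
insertion codes preserved.

An interface is an ordered pair of chains; a contact is a residue pair from
different chains whose minimum heavy-atom distance does not exceed the
cutoff (default 5.0 Å). Side-chain accessible surface area is computed in
the context of the full complex by the Shrake-Rupley method.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .align import PairwiseAlignment
from .residues import AA3_TO_1, PHOSPHO_RESNAMES, residue_class

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: van der Waals radii (Å) by element for ASA; NACCESS-style values
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
DEFAULT_VDW = 1.70


class EmptyStructureError(ValueError):
    """Raised when a structure file contains no polymer residues."""


@dataclass
class ResidueRecord:
    """One standard or phosphorylated residue of a parsed structure."""

    struct_id: str
    chain_id: str
    seq_pos: int
    icode: str
    aa: str
    phospho: bool = False
    sidechain_asa: Optional[float] = None

    def __post_init__(self) -> None:
        if self.phospho and self.aa not in "STY":
            raise ValueError("phospho residues must be S, T or Y")
        if self.sidechain_asa is not None and self.sidechain_asa < 0:
            raise ValueError("sidechain_asa must be non-negative")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_pos, self.icode)

    @property
    def residue_class(self) -> str:
        return residue_class(self.aa, self.phospho)


@dataclass(frozen=True)
class ContactEdge:
    """An inter-chain residue-residue contact within one interface."""

    res_a: ResidueRecord
    res_b: ResidueRecord
    interface_id: tuple
    min_dist: float


@dataclass
class InterfaceModel:
    """All contacts between an ordered pair of chains."""

    interface_id: tuple
    contacts: list[ContactEdge]
    residues_a: list[ResidueRecord]
    residues_b: list[ResidueRecord]
    homodimer: bool = False

    @property
    def chain_a(self) -> str:
        return self.interface_id[1]

    @property
    def chain_b(self) -> str:
        return self.interface_id[2]

    def contact_positions(self, side: str) -> set[tuple[int, str]]:
        """Interface residue (seq_pos, icode) keys on one side ('a' or 'b')."""
        if side == "a":
            return {(e.res_a.seq_pos, e.res_a.icode) for e in self.contacts}
        if side == "b":
            return {(e.res_b.seq_pos, e.res_b.icode) for e in self.contacts}
        raise ValueError("side must be 'a' or 'b'")

    def edges_for(self, chain_id: str, seq_pos: int, icode: str = "") -> list[ContactEdge]:
        """Contacts incident to one residue, oriented with that residue first."""
        key = (chain_id, seq_pos, icode)
        out = []
        for e in self.contacts:
            if e.res_a.key == key:
                out.append(e)
            elif e.res_b.key == key:
                out.append(ContactEdge(e.res_b, e.res_a, e.interface_id, e.min_dist))
        return out


@dataclass
class StructureModel:
    """Residues plus heavy-atom coordinates of one structure (single model)."""

    struct_id: str
    residues: list[ResidueRecord]
    # parallel to residues: per-residue atom names and Nx3 coordinates
    atom_names: list[list[str]] = field(repr=False, default_factory=list)
    atom_elements: list[list[str]] = field(repr=False, default_factory=list)
    atom_coords: list[np.ndarray] = field(repr=False, default_factory=list)
    assembly: str = ""
    model: int = 1

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.chain_id, None)
        return list(seen)

    def chain_residue_indices(self, chain_id: str) -> list[int]:
        idx = [i for i, r in enumerate(self.residues) if r.chain_id == chain_id]
        if not idx:
            raise KeyError(f"chain {chain_id!r} not in structure {self.struct_id!r}")
        return idx

    def chain_sequence(self, chain_id: str) -> str:
        """One-letter sequence of a chain (phospho residues as base aa)."""
        return "".join(self.residues[i].aa for i in self.chain_residue_indices(chain_id))

    def residue(self, chain_id: str, seq_pos: int, icode: str = "") -> ResidueRecord:
        for r in self.residues:
            if r.key == (chain_id, seq_pos, icode):
                return r
        raise KeyError(f"residue {chain_id}{seq_pos}{icode} not found")


def _highest_occupancy_atoms(residue) -> list:
    """Keep one conformer per atom name: the highest-occupancy altloc."""
    best: dict[str, object] = {}
    for atom in residue:
        if atom.is_hydrogen():
            continue
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            best[atom.name] = atom
    return list(best.values())


def read_structure(path: str | Path, fmt: Optional[str] = None) -> StructureModel:
    """Parse a PDB or mmCIF file into a :class:`StructureModel`.

    Non-standard residues other than SEP/TPO/PTR are skipped with a
    warning; waters and ligands are ignored. Raises
    :class:`EmptyStructureError` when no usable polymer residue is found.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise IOError(f"no such structure file: {path}")
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt in ("mmcif", "cif"):
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path)).sole_block())
        else:
            st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise IOError(f"cannot parse structure file {path}: {exc}") from exc

    st.remove_waters()
    model = StructureModel(struct_id=path.stem, residues=[])
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no model in structure")
    gmodel = st[0]
    for chain in gmodel:
        for res in chain:
            name = res.name.upper()
            if name in PHOSPHO_RESNAMES:
                aa, phospho = PHOSPHO_RESNAMES[name], True
            elif name in AA3_TO_1:
                aa, phospho = AA3_TO_1[name], False
            elif name == "HOH":
                continue
            else:
                warnings.warn(
                    f"{path.name}: skipping non-standard residue "
                    f"{name} {chain.name}{res.seqid.num}"
                )
                continue
            atoms = _highest_occupancy_atoms(res)
            if not atoms:
                continue
            icode = res.seqid.icode.strip()
            model.residues.append(
                ResidueRecord(
                    struct_id=model.struct_id,
                    chain_id=chain.name,
                    seq_pos=res.seqid.num,
                    icode=icode,
                    aa=aa,
                    phospho=phospho,
                )
            )
            model.atom_names.append([a.name for a in atoms])
            model.atom_elements.append([a.element.name.upper() for a in atoms])
            model.atom_coords.append(
                np.array([[a.pos.x, a.pos.y, a.pos.z] for a in atoms], dtype=float)
            )
    if not model.residues:
        raise EmptyStructureError(f"{path}: no standard or phospho polymer residues")
    return model


def detect_phospho_residues(residues: Iterable[ResidueRecord]) -> list[ResidueRecord]:
    """Return the SEP/TPO/PTR-derived residues."""
    return [r for r in residues if r.phospho]


def find_interface_contacts(
    structure: StructureModel,
    chain_a: str,
    chain_b: str,
    cutoff_angstrom: float = 5.0,
) -> InterfaceModel:
    """Enumerate inter-chain residue contacts between two chains.

    A contact is recorded when any heavy-atom pair lies within the cutoff
    (inclusive). The homodimer flag is set when both chains have identical
    base-amino-acid sequences.
    """
    idx_a = structure.chain_residue_indices(chain_a)
    idx_b = structure.chain_residue_indices(chain_b)

    coords_a = np.vstack([structure.atom_coords[i] for i in idx_a])
    owner_a = np.concatenate(
        [np.full(len(structure.atom_coords[i]), k) for k, i in enumerate(idx_a)]
    )
    coords_b = np.vstack([structure.atom_coords[i] for i in idx_b])
    owner_b = np.concatenate(
        [np.full(len(structure.atom_coords[i]), k) for k, i in enumerate(idx_b)]
    )

    tree_a, tree_b = cKDTree(coords_a), cKDTree(coords_b)
    pairs = tree_a.sparse_distance_matrix(tree_b, cutoff_angstrom, output_type="coo_matrix")

    min_dist: dict[tuple[int, int], float] = {}
    for ai, bi, d in zip(pairs.row, pairs.col, pairs.data):
        k = (int(owner_a[ai]), int(owner_b[bi]))
        if d < min_dist.get(k, np.inf):
            min_dist[k] = float(d)

    interface_id = (structure.struct_id, chain_a, chain_b, structure.assembly, structure.model)
    residues_a = [structure.residues[i] for i in idx_a]
    residues_b = [structure.residues[i] for i in idx_b]
    edges = [
        ContactEdge(residues_a[ka], residues_b[kb], interface_id, d)
        for (ka, kb), d in min_dist.items()
    ]
    edges.sort(key=lambda e: (e.res_a.seq_pos, e.res_a.icode, e.res_b.seq_pos, e.res_b.icode))

    seq_a = "".join(r.aa for r in residues_a)
    seq_b = "".join(r.aa for r in residues_b)
    return InterfaceModel(
        interface_id=interface_id,
        contacts=edges,
        residues_a=residues_a,
        residues_b=residues_b,
        homodimer=(seq_a == seq_b),
    )


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def sidechain_asa(
    structure: StructureModel,
    probe_radius: float = 1.4,
    n_points: int = 960,
    chains: Optional[Sequence[str]] = None,
) -> dict[tuple[str, int, str], Optional[float]]:
    """Side-chain accessible surface area (Å²) per residue, Shrake-Rupley.

    Computed in the context of the whole complex (or of ``chains`` when
    given, e.g. to measure a chain in isolation). Side-chain atoms are all
    heavy atoms beyond the backbone, CB included. Glycine has no side
    chain and is assigned 0. A non-glycine residue with no side-chain
    atoms present is flagged unset (None) rather than 0.

    Results are also written onto ``ResidueRecord.sidechain_asa`` (only
    for the residues measured).
    """
    if chains is None:
        sel = list(range(len(structure.residues)))
    else:
        sel = [i for i, r in enumerate(structure.residues) if r.chain_id in chains]
        if not sel:
            raise KeyError(f"no residues in chains {chains!r}")

    coords = np.vstack([structure.atom_coords[i] for i in sel])
    elements = [e for i in sel for e in structure.atom_elements[i]]
    names = [n for i in sel for n in structure.atom_names[i]]
    owner = np.concatenate(
        [np.full(len(structure.atom_coords[i]), i) for i in sel]
    )
    radii = np.array([VDW_RADII.get(e, DEFAULT_VDW) for e in elements]) + probe_radius

    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    atom_asa = np.zeros(len(coords))
    max_r = radii.max()
    for i in range(len(coords)):
        pts = coords[i] + radii[i] * unit
        neigh = tree.query_ball_point(coords[i], radii[i] + max_r)
        neigh = [j for j in neigh if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neigh:
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            accessible &= d2 > radii[j] ** 2
        atom_asa[i] = accessible.sum() / n_points * 4.0 * np.pi * radii[i] ** 2

    out: dict[tuple[str, int, str], Optional[float]] = {}
    for i in sel:
        res = structure.residues[i]
        mask = owner == i
        side = [
            k
            for k, (n, m) in enumerate(zip(names, mask))
            if m and n not in BACKBONE_ATOMS
        ]
        if res.aa == "G":
            value: Optional[float] = 0.0
        elif not side:
            value = None
            logger.warning(
                "residue %s%s%s has no side-chain atoms; ASA unset",
                res.chain_id, res.seq_pos, res.icode,
            )
        else:
            value = float(atom_asa[side].sum())
        res.sidechain_asa = value
        out[res.key] = value
    return out


def find_homologous_interfaces(
    query: InterfaceModel,
    candidates: Sequence[InterfaceModel],
    alignments: Mapping[tuple[str, str], PairwiseAlignment],
    min_identity: float = 0.5,
    min_coverage: float = 0.5,
    min_shared_interface: float = 0.5,
) -> list[InterfaceModel]:
    """Candidates homologous to ``query`` by the three >=50% criteria.

    A candidate matches when, for some pairing of its chains with the
    query's, each chain pair shows at least ``min_identity`` sequence
    identity over at least ``min_coverage`` of the query chain, and at
    least ``min_shared_interface`` of the query's interface residues map
    (through the alignments) onto interface residues of the candidate.

    ``alignments`` maps ("struct/chain", "struct/chain") keys — query
    chain first — to pairwise alignments of the chain sequences.
    Candidates lacking an alignment are skipped with a warning.
    """

    def chain_tag(iface: InterfaceModel, side: str) -> str:
        cid = iface.chain_a if side == "a" else iface.chain_b
        return f"{iface.interface_id[0]}/{cid}"

    def get_aln(qtag: str, ctag: str) -> Optional[PairwiseAlignment]:
        aln = alignments.get((qtag, ctag))
        if aln is None:
            aln = alignments.get((ctag, qtag))
            if aln is not None:
                aln = aln.swapped()
        return aln

    def shared_fraction(q_side: str, c_side: str, aln: PairwiseAlignment,
                        cand: InterfaceModel) -> float:
        q_iface = query.contact_positions(q_side)
        if not q_iface:
            return 0.0
        q_residues = query.residues_a if q_side == "a" else query.residues_b
        index_of = {r.key[1:]: i + 1 for i, r in enumerate(q_residues)}
        c_residues = cand.residues_a if c_side == "a" else cand.residues_b
        c_iface_seq = {
            i + 1
            for i, r in enumerate(c_residues)
            if r.key[1:] in cand.contact_positions(c_side)
        }
        shared = 0
        for pos_key in q_iface:
            seq_i = index_of.get(pos_key)
            if seq_i is None:
                continue
            mapped = aln.map_query_to_template(seq_i) if seq_i <= aln.query_length else None
            if mapped is not None and mapped[0] in c_iface_seq:
                shared += 1
        return shared / len(q_iface)

    matches = []
    for cand in candidates:
        matched = False
        for (qa, qb), (ca, cb) in (
            (("a", "b"), ("a", "b")),
            (("a", "b"), ("b", "a")),
        ):
            aln1 = get_aln(chain_tag(query, qa), chain_tag(cand, ca))
            aln2 = get_aln(chain_tag(query, qb), chain_tag(cand, cb))
            if aln1 is None or aln2 is None:
                continue
            ok = True
            for aln in (aln1, aln2):
                if aln.identity() < min_identity or aln.coverage() < min_coverage:
                    ok = False
                    break
            if not ok:
                continue
            shared = (
                shared_fraction(qa, ca, aln1, cand)
                + shared_fraction(qb, cb, aln2, cand)
            ) / 2.0
            if shared >= min_shared_interface:
                matched = True
                break
        if matched:
            matches.append(cand)
        elif all(
            get_aln(chain_tag(query, s), chain_tag(cand, c)) is None
            for s in ("a", "b")
            for c in ("a", "b")
        ):
            warnings.warn(
                f"no alignment for candidate interface {cand.interface_id}; skipped"
            )
    return matches


def contacts_to_frame(interfaces: Iterable[InterfaceModel]):
    """Contacts of one or more interfaces as a tidy DataFrame (TSV dialect)."""
    import pandas as pd

    rows = []
    for iface in interfaces:
        sid, ca, cb, assembly, model = iface.interface_id
        for e in iface.contacts:
            rows.append(
                {
                    "struct_id": sid,
                    "assembly": assembly,
                    "chain_a": ca,
                    "pos_a": e.res_a.seq_pos,
                    "aa_a": e.res_a.aa,
                    "phospho_a": int(e.res_a.phospho),
                    "chain_b": cb,
                    "pos_b": e.res_b.seq_pos,
                    "aa_b": e.res_b.aa,
                    "phospho_b": int(e.res_b.phospho),
                    "min_dist": round(e.min_dist, 3),
                }
            )
    columns = [
        "struct_id", "assembly", "chain_a", "pos_a", "aa_a", "phospho_a",
        "chain_b", "pos_b", "aa_b", "phospho_b", "min_dist",
    ]
    return pd.DataFrame(rows, columns=columns)
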