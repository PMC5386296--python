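"""Synthetic fixtures: contact samples from a planted potential, toy
two-chain complexes with known geometry, orthologue alignments with
tunable conservation, and labelled benchmark sets with tunable effect size.

All generators are deterministic under a fixed seed. The contact sampler
draws unordered class pairs from the distribution whose quasi-chemical
log-odds equal a planted matrix; because an estimated matrix always
satisfies a closure condition (sum of expected-frequency-weighted
exponentiated scores equals one), planted matrices are first calibrated
onto that family (see :func:`phosphoswitch.potentials.calibrate_matrix`),
which amounts to a uniform additive offset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .benchmark import BenchmarkEntry
from .potentials import PairPotentialMatrix, calibrate_matrix, implied_pair_distribution
from .residues import AA1_TO_3, ALPHABET, PHOSPHO_RESNAMES, base_aa
from .structures import ContactEdge, ResidueRecord


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study conditions."""

    planted_matrix: Optional[PairPotentialMatrix] = None
    n_pairs: int = 100_000
    conservation: float = 0.5
    de_fraction: float = 0.1
    gap_fraction: float = 0.1
    effect_size: float = 3.0
    n_pos: int = 200
    n_neg: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.conservation + self.de_fraction + self.gap_fraction > 1.0 + 1e-12:
            raise ValueError("conservation + de_fraction + gap_fraction must be <= 1")
        for name in ("n_pairs", "n_pos", "n_neg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")


def make_planted_matrix(
    alphabet: Sequence[str] = ALPHABET,
    perturbations: Optional[dict[tuple[str, str], float]] = None,
    calibrate: bool = True,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> PairPotentialMatrix:
    """A symmetric planted matrix: zeros plus the given pair scores.

    With ``calibrate`` (default) the matrix is projected onto the family
    the estimator can return, and the tilt is iteratively adjusted so that
    the perturbed entries keep exactly their requested values; sampling
    followed by re-estimation then recovers them without systematic
    offset. Unperturbed entries pick up the (small) compensating
    marginal corrections. Raises when the requested values cannot be
    realised on the given alphabet.
    """
    alphabet = tuple(alphabet)
    n = len(alphabet)
    idx = {c: i for i, c in enumerate(alphabet)}
    targets = {}
    for (a, b), s in (perturbations or {}).items():
        targets[(idx[a], idx[b])] = s
        targets[(idx[b], idx[a])] = s

    def tilt_to_matrix(tilt: np.ndarray) -> PairPotentialMatrix:
        m = PairPotentialMatrix(alphabet, tilt, provenance="planted")
        return calibrate_matrix(m)[0] if calibrate else m

    tilt = np.zeros((n, n))
    for (i, j), s in targets.items():
        tilt[i, j] = s
    matrix = tilt_to_matrix(tilt)
    if not calibrate or not targets:
        return matrix
    for _ in range(max_iter):
        err = max(abs(matrix.scores[i, j] - s) for (i, j), s in targets.items())
        if err < tol:
            return matrix
        for (i, j), s in targets.items():  # damped to avoid overshooting
            tilt[i, j] += 0.5 * (s - matrix.scores[i, j])
        matrix = tilt_to_matrix(tilt)
    raise ValueError(
        "planted scores not realisable on this alphabet "
        "(log-odds this large need a bigger alphabet or rarer classes)"
    )


def contact_pair_distribution(
    matrix: PairPotentialMatrix,
) -> tuple[np.ndarray, np.ndarray]:
    """(unordered pair probabilities, marginals) induced by a planted matrix.

    The matrix must be estimator-consistent (build it with
    :func:`make_planted_matrix`). The returned square array holds
    unordered probabilities: off-diagonal cells carry the full
    2 g_a g_b e^s mass on the upper triangle.
    """
    p_ord, g = implied_pair_distribution(matrix)
    p_unord = np.triu(p_ord * 2.0, k=1) + np.diag(np.diag(p_ord))
    return p_unord, g


def _edge_for_classes(cls_a: str, cls_b: str, index: int) -> ContactEdge:
    aa_a, aa_b = base_aa(cls_a), base_aa(cls_b)
    res_a = ResidueRecord("synthetic", "A", index + 1, "", aa_a, phospho=cls_a.startswith("p"))
    res_b = ResidueRecord("synthetic", "B", index + 1, "", aa_b, phospho=cls_b.startswith("p"))
    return ContactEdge(res_a, res_b, ("synthetic", "A", "B", "", 1), 4.0)


def sample_contact_graph(spec: SyntheticSpec) -> list[ContactEdge]:
    """Draw ``spec.n_pairs`` contacts i.i.d. from the planted distribution."""
    matrix = spec.planted_matrix
    if matrix is None:
        matrix = make_planted_matrix()
    if not np.isfinite(matrix.scores).all():
        raise ValueError("planted matrix must be finite")
    p_unord, _ = contact_pair_distribution(matrix)
    alphabet = matrix.alphabet
    n = len(alphabet)
    iu = np.triu_indices(n)
    probs = p_unord[iu]
    rng = np.random.default_rng(spec.seed)
    counts = rng.multinomial(spec.n_pairs, probs / probs.sum())
    edges: list[ContactEdge] = []
    k = 0
    for (i, j), c in zip(zip(*iu), counts):
        for _ in range(int(c)):
            edges.append(_edge_for_classes(alphabet[i], alphabet[j], k))
            k += 1
    return edges


# --- toy complexes ---------------------------------------------------------

_RES_ATOM_OFFSETS = {
    "N": (-1.46, 0.0, 0.0),
    "CA": (0.0, 0.0, 0.0),
    "C": (1.52, 0.0, 0.0),
    "O": (2.15, 1.06, 0.0),
    "CB": (0.0, 1.53, 0.0),
}
_CHAIN_SPACING = 10.0  # Å between residue centres along a chain
_CB_OFFSET = 1.53  # CB distance from the residue centre along y
_FAR_GAP = 40.0


def _pdb_atom_line(serial, name, resname, chain, resseq, x, y, z, element):
    return (
        f"ATOM  {serial:5d} {name:^4s}{resname:>4s} {chain}{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {element:>2s}\n"
    )


def _residue_atoms(center, flip_y: bool):
    for name, (dx, dy, dz) in _RES_ATOM_OFFSETS.items():
        dy = -dy if flip_y else dy
        yield name, (center[0] + dx, center[1] + dy, center[2] + dz), name[0]


def make_toy_complex(
    n_per_chain: int,
    contact_pairs: Sequence[tuple[int, int]] = (),
    seed: int = 0,
    sequence_a: Optional[str] = None,
    sequence_b: Optional[str] = None,
    phospho: Optional[dict[tuple[str, int], str]] = None,
    homodimer: bool = False,
    contact_distance: float = 4.5,
) -> str:
    """PDB text for a toy two-chain complex with the requested contacts.

    Chains A and B carry ``n_per_chain`` five-atom pseudo-residues spaced
    10 Å apart. Each requested (pos_a, pos_b) pair — 1-based — is realised
    as a CB-CB contact at ``contact_distance`` Å and no other inter-chain
    residue pair comes within 5 Å (for the default distance). ``phospho``
    maps (chain, pos) to SEP/TPO/PTR, renaming the residue (the sequence
    letter must agree). With ``homodimer`` chain B copies chain A's
    sequence.
    """
    if n_per_chain <= 0:
        raise ValueError("n_per_chain must be positive")
    if contact_distance <= 0:
        raise ValueError("contact_distance must be positive")
    contact_gap = 2 * _CB_OFFSET + contact_distance
    seq_a = (sequence_a or "A" * n_per_chain).upper()
    seq_b = (seq_a if homodimer else (sequence_b or "A" * n_per_chain)).upper()
    if len(seq_a) != n_per_chain or len(seq_b) != n_per_chain:
        raise ValueError("sequence length must equal n_per_chain")

    contact_of_b: dict[int, int] = {}
    for pa, pb in contact_pairs:
        if not (1 <= pa <= n_per_chain and 1 <= pb <= n_per_chain):
            raise ValueError(f"contact pair ({pa},{pb}) outside chain length")
        if pb in contact_of_b:
            raise ValueError(f"chain B residue {pb} requested in two contacts")
        contact_of_b[pb] = pa

    # offset duplicate chain-B placements that target the same chain-A residue
    used_x: dict[float, int] = {}
    centers_a = [((i - 1) * _CHAIN_SPACING, 0.0, 0.0) for i in range(1, n_per_chain + 1)]
    centers_b = []
    for j in range(1, n_per_chain + 1):
        if j in contact_of_b:
            x = (contact_of_b[j] - 1) * _CHAIN_SPACING
            n_used = used_x.get(x, 0)
            used_x[x] = n_used + 1
            centers_b.append((x + 0.5 * n_used, contact_gap, 0.0))
        else:
            centers_b.append(((j - 1) * _CHAIN_SPACING, _FAR_GAP, 0.0))

    phospho = phospho or {}
    for (chain, pos), resname in phospho.items():
        seq = seq_a if chain == "A" else seq_b
        if resname not in PHOSPHO_RESNAMES:
            raise ValueError(f"phospho residue name must be SEP/TPO/PTR, got {resname}")
        if seq[pos - 1] != PHOSPHO_RESNAMES[resname]:
            raise ValueError(
                f"{resname} at {chain}{pos} conflicts with sequence letter {seq[pos - 1]}"
            )

    lines = []
    serial = 1
    for chain, seq, centers, flip in (
        ("A", seq_a, centers_a, False),
        ("B", seq_b, centers_b, True),
    ):
        for pos, (letter, center) in enumerate(zip(seq, centers), start=1):
            resname = phospho.get((chain, pos)) or AA1_TO_3[letter]
            for name, xyz, element in _residue_atoms(center, flip_y=flip):
                lines.append(
                    _pdb_atom_line(serial, name, resname, chain, pos, *xyz, element)
                )
                serial += 1
        lines.append("TER\n")
    lines.append("END\n")
    return "".join(lines)


def make_buried_cluster(n_shell: int = 32, shell_radius: float = 4.5) -> str:
    """PDB text with a central residue fully occluded by a shell of residues.

    The central residue's CB is surrounded by ``n_shell`` pseudo-residues
    whose atoms sit on a sphere of ``shell_radius`` Å around it, driving
    its side-chain ASA to (near) zero.
    """
    from .structures import _sphere_points

    lines = []
    serial = 1
    center_cb = np.array(_RES_ATOM_OFFSETS["CB"])
    for name, (dx, dy, dz) in _RES_ATOM_OFFSETS.items():
        lines.append(
            _pdb_atom_line(serial, name, "SER", "A", 1, dx, dy, dz, name[0])
        )
        serial += 1
    directions = _sphere_points(n_shell)
    for k, d in enumerate(directions, start=2):
        base = center_cb + shell_radius * d
        for i, name in enumerate(("N", "CA", "C", "O", "CB")):
            off = 0.25 * _sphere_points(5)[i]
            x, y, z = base + off
            lines.append(_pdb_atom_line(serial, name, "ALA", "A", k, x, y, z, name[0]))
            serial += 1
    lines.append("TER\nEND\n")
    return "".join(lines)


# --- orthologue alignments -------------------------------------------------

_OTHER_RESIDUES = "GLVIFMKRH"  # never wild S/T/Y nor D/E


def make_ortholog_alignment(
    wild_aa: str,
    n_seq: int,
    c: float,
    de_fraction: float,
    gap_fraction: float,
    seed: int = 0,
    length: int = 21,
    site_col: int = 10,
    query_id: str = "query",
) -> str:
    """Aligned FASTA of an orthologue group with a planted site column.

    At the site column (0-based ``site_col``) each non-query sequence
    carries ``wild_aa`` with probability ``c``, Asp/Glu with probability
    ``de_fraction``, a gap with probability ``gap_fraction``, and another
    residue otherwise; expected f_Cons is c + de_fraction (the query row
    always carries the wild residue). Other columns are weakly conserved
    alanine background with random substitutions.
    """
    if wild_aa not in "STY":
        raise ValueError("wild_aa must be S, T or Y")
    for frac in (c, de_fraction, gap_fraction):
        if not 0.0 <= frac <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
    if c + de_fraction + gap_fraction > 1.0 + 1e-12:
        raise ValueError("c + de_fraction + gap_fraction must be <= 1")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_seq):
        row = []
        for col in range(length):
            if col == site_col:
                if i == 0:
                    row.append(wild_aa)
                    continue
                u = rng.random()
                if u < c:
                    row.append(wild_aa)
                elif u < c + de_fraction:
                    row.append(rng.choice(list("DE")))
                elif u < c + de_fraction + gap_fraction:
                    row.append("-")
                else:
                    row.append(rng.choice(list(_OTHER_RESIDUES)))
            else:
                row.append("A" if rng.random() < 0.8 else rng.choice(list(_OTHER_RESIDUES)))
        rid = query_id if i == 0 else f"ortholog{i}"
        records.append(f">{rid}\n{''.join(row)}\n")
    return "".join(records)


# --- labelled benchmarks ---------------------------------------------------

def make_synthetic_benchmark(spec: SyntheticSpec) -> tuple[list[BenchmarkEntry], list[int]]:
    """Labelled site-interactor pairs with a planted interaction effect.

    Positives draw IE from N(+effect_size, 1) (enabling) or
    N(-effect_size, 1) (disabling); negatives draw IE from N(0, 1) and
    inherit the effect label of their source positive. f_ID ~ U(0.8, 1)
    mimics the high-identity templates that dominate real mappings;
    f_Cons ~ U(0.3, 1). Returns entries plus ground-truth labels
    (1 positive, 0 negative).
    """
    rng = np.random.default_rng(spec.seed)
    entries: list[BenchmarkEntry] = []
    labels: list[int] = []

    def one_entry(i: int, which: str, effect: str, protein: str) -> BenchmarkEntry:
        if which == "positive":
            mu = spec.effect_size if effect == "enabling" else -spec.effect_size
        else:
            mu = 0.0
        ie = rng.normal(mu, 1.0)
        f_id = rng.uniform(0.8, 1.0)
        f_cons = rng.uniform(0.3, 1.0)
        aa = rng.choice(list("STY"))
        return BenchmarkEntry(
            set=which,
            protein=protein,
            site=f"{aa}{int(rng.integers(2, 400))}",
            interactor=f"I{i:05d}",
            effect=effect,
            template=f"tmpl{i % 7}",
            pdbres="",
            ie=float(ie),
            f_id=float(f_id),
            f_cons=float(f_cons),
            s_switch=float(ie * f_id * f_cons),
            ddg=None,
            is_kinase=bool(rng.random() < 0.15),
        )

    for i in range(spec.n_pos):
        effect = "enabling" if i % 2 == 0 else "disabling"
        entries.append(one_entry(i, "positive", effect, f"P{i:05d}"))
        labels.append(1)
    for j in range(spec.n_neg):
        src = j % spec.n_pos
        effect = "enabling" if src % 2 == 0 else "disabling"
        entries.append(one_entry(spec.n_pos + j, "negative", effect, f"P{src:05d}"))
        labels.append(0)
    return entries, labels
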