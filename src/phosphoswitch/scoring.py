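"""The Interaction Effect, the switch score, and per-site aggregation.

IE sums, over the mapped site residue's inter-chain contacts, the change in
pair-potential when the site is phosphorylated. At homodimeric interfaces
the site is phosphorylated in both copies of the protein: both symmetric
copies are scored and summed, which doubles the effect for a perfectly
symmetric interface, and a contact between the two copies of the site
itself is compared as s(p,p) - s(u,u).

S_switch = IE * f_ID * f_Cons down-weights remote templates and poorly
conserved sites; |S_switch| >= 1.7 calls a switch (enabling when positive,
disabling when negative).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .potentials import PairPotentialMatrix, delta_on_phosphorylation
from .structures import ContactEdge, InterfaceModel

DEFAULT_SWITCH_THRESHOLD = 1.7


@dataclass
class SwitchScore:
    """Scores for one site x interactor x template."""

    site_label: str
    protein_acc: str
    interactor_acc: str
    interface_id: tuple
    ie: float
    f_id: float
    f_cons: float
    s_switch: float
    label: str
    template_residue: str = ""

    def __post_init__(self) -> None:
        if abs(self.s_switch) > abs(self.ie) + 1e-9:
            raise ValueError("|S_switch| cannot exceed |IE|")


def interaction_effect(
    site_contacts: Sequence[ContactEdge],
    matrix: PairPotentialMatrix,
    homodimer: bool = False,
) -> float:
    """Sum of pair-potential changes over the site's inter-chain contacts.

    Edges must be oriented with the site residue first (``res_a``); see
    :func:`InterfaceModel.edges_for`. With ``homodimer`` the mirrored copy
    of the site is phosphorylated too: a partner at the site's own
    position on the other chain is treated as phosphorylated, and when
    only one copy's contacts are supplied the symmetric copy's identical
    contribution is added (doubling the sum).
    """
    if not site_contacts:
        return 0.0
    site_keys = {e.res_a.key for e in site_contacts}
    total = 0.0
    for e in site_contacts:
        mirrored = (
            homodimer
            and e.res_b.chain_id != e.res_a.chain_id
            and (e.res_b.seq_pos, e.res_b.icode) == (e.res_a.seq_pos, e.res_a.icode)
            and e.res_b.aa == e.res_a.aa
        )
        total += delta_on_phosphorylation(
            matrix, e.res_a.aa, e.res_b.residue_class, partner_is_mirrored_site=mirrored
        )
    if homodimer and len({k[0] for k in site_keys}) == 1:
        # only one copy's contacts supplied: add the symmetric copy's sum
        total *= 2.0
    return total


def site_interaction_effect(
    interface: InterfaceModel,
    chain_id: str,
    seq_pos: int,
    matrix: PairPotentialMatrix,
    icode: str = "",
) -> float:
    """IE of a site residue within one interface.

    Collects the residue's contacts (and, for homodimers, the contacts of
    the equivalent residue on the partner chain) and sums the
    phosphorylation deltas.
    """
    edges = interface.edges_for(chain_id, seq_pos, icode)
    if interface.homodimer:
        other = interface.chain_b if chain_id == interface.chain_a else interface.chain_a
        edges = edges + interface.edges_for(other, seq_pos, icode)
    return interaction_effect(edges, matrix, homodimer=interface.homodimer)


def s_switch(ie: float, f_id: float, f_cons: float) -> float:
    """S_switch = IE * f_ID * f_Cons (no clamping or rounding)."""
    if not 0.0 <= f_id <= 1.0:
        raise ValueError(f"f_ID must lie in [0, 1], got {f_id}")
    if not 0.0 <= f_cons <= 1.0:
        raise ValueError(f"f_Cons must lie in [0, 1], got {f_cons}")
    return ie * f_id * f_cons


def classify_switch(s: float, threshold: float = DEFAULT_SWITCH_THRESHOLD) -> str:
    """enabling when S >= threshold, disabling when S <= -threshold, else neutral."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if s >= threshold:
        return "enabling"
    if s <= -threshold:
        return "disabling"
    return "neutral"


def make_switch_score(
    site_label: str,
    protein_acc: str,
    interactor_acc: str,
    interface_id: tuple,
    ie: float,
    f_id: float,
    f_cons: float,
    threshold: float = DEFAULT_SWITCH_THRESHOLD,
    template_residue: str = "",
) -> SwitchScore:
    s = s_switch(ie, f_id, f_cons)
    return SwitchScore(
        site_label=site_label,
        protein_acc=protein_acc,
        interactor_acc=interactor_acc,
        interface_id=interface_id,
        ie=ie,
        f_id=f_id,
        f_cons=f_cons,
        s_switch=s,
        label=classify_switch(s, threshold),
    )


def aggregate_templates(scores: Sequence[SwitchScore]) -> SwitchScore:
    """Most significant score over a site's templates at one interface.

    The score of largest |S_switch| wins; ties break by larger |IE|, then
    enabling over disabling, then lexicographically smallest template id —
    a deterministic cascade, since the original rule does not specify one.
    """
    if not scores:
        raise ValueError("no scores to aggregate")

    def key(sc: SwitchScore):
        return (
            abs(sc.s_switch),
            abs(sc.ie),
            sc.s_switch >= 0,  # enabling over disabling
            tuple(-ord(c) for c in str(sc.interface_id)),  # smaller id wins
        )

    return max(scores, key=key)
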