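"""Structure parsing, contacts, ASA and interface homology matching."""

from __future__ import annotations

import numpy as np
import pytest

from phosphoswitch import simulate, structures
from phosphoswitch.align import PairwiseAlignment
from phosphoswitch.structures import (
    ContactEdge,
    EmptyStructureError,
    InterfaceModel,
    ResidueRecord,
    detect_phospho_residues,
    find_homologous_interfaces,
    find_interface_contacts,
    read_structure,
    sidechain_asa,
)


class TestReadStructure:
    def test_toy_complex_round_trip(self, toy_structure):
        model = toy_structure(n_per_chain=3, contact_pairs=[(1, 2)])
        assert len(model.residues) == 6
        assert model.chains == ["A", "B"]

    def test_sep_residue_parsed_as_phospho_serine(self, toy_structure):
        model = toy_structure(
            n_per_chain=3, sequence_a="ASA", sequence_b="AKA",
            phospho={("A", 2): "SEP"},
        )
        ph = detect_phospho_residues(model.residues)
        assert [(r.chain_id, r.seq_pos, r.aa, r.phospho) for r in ph] == [("A", 2, "S", True)]
        assert ph[0].residue_class == "pS"

    def test_tpo_on_chain_b(self, toy_structure):
        model = toy_structure(
            n_per_chain=3, sequence_a="AAA", sequence_b="ATA",
            phospho={("B", 2): "TPO"},
        )
        ph = detect_phospho_residues(model.residues)
        assert [(r.chain_id, r.seq_pos, r.aa) for r in ph] == [("B", 2, "T")]

    def test_no_phospho_residues_gives_empty_list(self, toy_structure):
        model = toy_structure(n_per_chain=2)
        assert detect_phospho_residues(model.residues) == []

    def test_empty_file_raises(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("")
        with pytest.raises((EmptyStructureError, IOError)):
            read_structure(p)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(IOError):
            read_structure(tmp_path / "nope.pdb")

    def test_nonstandard_residue_skipped_with_warning(self, tmp_path, toy_structure):
        text = simulate.make_toy_complex(2, sequence_a="AA", sequence_b="AA")
        text = text.replace(" ALA A   1", " XYZ A   1")
        p = tmp_path / "odd.pdb"
        p.write_text(text)
        with pytest.warns(UserWarning, match="XYZ"):
            model = read_structure(p)
        assert len(model.residues) == 3


class TestContacts:
    def test_requested_contact_found_at_cutoff(self, toy_structure):
        model = toy_structure(n_per_chain=3, contact_pairs=[(1, 2)])
        iface = find_interface_contacts(model, "A", "B", 5.0)
        assert [(e.res_a.seq_pos, e.res_b.seq_pos) for e in iface.contacts] == [(1, 2)]
        assert iface.contacts[0].min_dist == pytest.approx(4.5, abs=1e-3)

    def test_threshold_between_4_and_5(self, tmp_path):
        # closest heavy atoms at 4.9 Å: included at 5.0, excluded at 4.0
        p = tmp_path / "t.pdb"
        p.write_text(simulate.make_toy_complex(1, [(1, 1)], contact_distance=4.9))
        model = read_structure(p)
        assert len(find_interface_contacts(model, "A", "B", 5.0).contacts) == 1
        assert len(find_interface_contacts(model, "A", "B", 4.0).contacts) == 0

    def test_contact_count_monotone_in_cutoff(self, toy_structure):
        model = toy_structure(n_per_chain=4, contact_pairs=[(1, 1), (3, 4)])
        counts = [
            len(find_interface_contacts(model, "A", "B", c).contacts)
            for c in (2.0, 4.0, 5.0, 8.0, 12.0)
        ]
        assert counts == sorted(counts)

    def test_homodimer_flag_and_mirrored_site_contact(self, toy_structure):
        model = toy_structure(n_per_chain=3, contact_pairs=[(2, 2)],
                              sequence_a="ASA", homodimer=True)
        iface = find_interface_contacts(model, "A", "B")
        assert iface.homodimer
        assert [(e.res_a.seq_pos, e.res_b.seq_pos) for e in iface.contacts] == [(2, 2)]
        # flag invariant under swapping chain labels
        assert find_interface_contacts(model, "B", "A").homodimer

    def test_heterodimer_not_flagged(self, toy_structure):
        model = toy_structure(n_per_chain=3, contact_pairs=[(2, 2)],
                              sequence_a="ASA", sequence_b="AKA")
        assert not find_interface_contacts(model, "A", "B").homodimer

    def test_missing_chain_raises(self, toy_structure):
        model = toy_structure(n_per_chain=2)
        with pytest.raises(KeyError):
            find_interface_contacts(model, "A", "Z")

    def test_contacts_frame_columns(self, toy_structure):
        model = toy_structure(n_per_chain=3, contact_pairs=[(1, 2)])
        frame = structures.contacts_to_frame([find_interface_contacts(model, "A", "B")])
        assert list(frame.columns) == [
            "struct_id", "assembly", "chain_a", "pos_a", "aa_a", "phospho_a",
            "chain_b", "pos_b", "aa_b", "phospho_b", "min_dist",
        ]
        assert len(frame) == 1


class TestSidechainAsa:
    def test_buried_core_residue_below_5(self, tmp_path):
        p = tmp_path / "buried.pdb"
        p.write_text(simulate.make_buried_cluster())
        model = read_structure(p)
        asa = sidechain_asa(model)
        assert asa[("A", 1, "")] < 5.0

    def test_isolated_residue_above_5(self, tmp_path):
        p = tmp_path / "iso.pdb"
        p.write_text(simulate.make_toy_complex(1, sequence_a="S", sequence_b="A"))
        model = read_structure(p)
        assert sidechain_asa(model)[("A", 1, "")] > 5.0

    def test_glycine_sidechain_asa_is_zero(self, toy_structure):
        model = toy_structure(n_per_chain=2, sequence_a="GA", sequence_b="AA")
        assert sidechain_asa(model)[("A", 1, "")] == 0.0

    def test_complex_asa_not_above_monomer_asa(self, toy_structure):
        model = toy_structure(n_per_chain=3, contact_pairs=[(1, 1), (2, 2)],
                              sequence_a="SKE", sequence_b="EKS")
        complex_asa = sidechain_asa(model)
        monomer_asa = sidechain_asa(model, chains=["A"])
        for key, mono in monomer_asa.items():
            assert complex_asa[key] <= mono + 1e-6

    def test_matches_independent_implementation(self, tmp_path):
        biotite_struc = pytest.importorskip("biotite.structure")
        import biotite.structure.io.pdb as bpdb

        p = tmp_path / "cmp.pdb"
        p.write_text(simulate.make_toy_complex(
            3, contact_pairs=[(2, 2)], sequence_a="SKE", sequence_b="EKS"))
        model = read_structure(p)
        ours = sidechain_asa(model)

        arr = bpdb.PDBFile.read(str(p)).get_structure(model=1)
        radii = np.array(
            [structures.VDW_RADII.get(e.upper(), structures.DEFAULT_VDW)
             for e in arr.element]
        )
        per_atom = biotite_struc.sasa(
            arr, probe_radius=1.4, point_number=1000, vdw_radii=radii
        )
        for res in model.residues:
            mask = (
                (arr.chain_id == res.chain_id)
                & (arr.res_id == res.seq_pos)
                & ~np.isin(arr.atom_name, ["N", "CA", "C", "O", "OXT"])
            )
            ref = float(per_atom[mask].sum())
            assert ours[res.key] == pytest.approx(ref, abs=1.5)


def _fake_interface(struct_id, seq_a, seq_b, contact_pairs):
    res_a = [ResidueRecord(struct_id, "A", i + 1, "", aa) for i, aa in enumerate(seq_a)]
    res_b = [ResidueRecord(struct_id, "B", i + 1, "", aa) for i, aa in enumerate(seq_b)]
    iface_id = (struct_id, "A", "B", "", 1)
    edges = [
        ContactEdge(res_a[i - 1], res_b[j - 1], iface_id, 4.5) for i, j in contact_pairs
    ]
    return InterfaceModel(iface_id, edges, res_a, res_b, homodimer=(seq_a == seq_b))


class TestHomologousInterfaces:
    def _aln(self, qtag, ttag, qseq, tseq):
        return {(qtag, ttag): PairwiseAlignment(qtag, ttag, qseq, tseq)}

    def test_identical_duplicate_matches(self):
        q = _fake_interface("q", "SKEYL", "AKEDL", [(1, 2), (3, 4)])
        c = _fake_interface("c", "SKEYL", "AKEDL", [(1, 2), (3, 4)])
        alns = {}
        alns.update(self._aln("q/A", "c/A", "SKEYL", "SKEYL"))
        alns.update(self._aln("q/B", "c/B", "AKEDL", "AKEDL"))
        assert find_homologous_interfaces(q, [c], alns) == [c]

    def test_low_identity_candidate_rejected(self):
        # 40% identity fails the >= 50% sequence-identity criterion
        q = _fake_interface("q", "SKEYL", "AKEDL", [(1, 2), (3, 4)])
        c = _fake_interface("c", "SPRYG", "AKEDL", [(1, 2), (3, 4)])
        alns = {}
        alns.update(self._aln("q/A", "c/A", "SKEYL", "SPRYG"))  # 2/5 identical
        alns.update(self._aln("q/B", "c/B", "AKEDL", "AKEDL"))
        assert find_homologous_interfaces(q, [c], alns) == []

    def test_low_shared_interface_rejected(self):
        # identity/coverage fine but interface residues do not coincide
        q = _fake_interface("q", "SKEYL", "AKEDL", [(1, 2), (3, 4)])
        c = _fake_interface("c", "SKEYL", "AKEDL", [(5, 5)])
        alns = {}
        alns.update(self._aln("q/A", "c/A", "SKEYL", "SKEYL"))
        alns.update(self._aln("q/B", "c/B", "AKEDL", "AKEDL"))
        assert find_homologous_interfaces(q, [c], alns) == []

    def test_candidate_without_alignment_skipped_with_warning(self):
        q = _fake_interface("q", "SKEYL", "AKEDL", [(1, 2)])
        c = _fake_interface("c", "SKEYL", "AKEDL", [(1, 2)])
        with pytest.warns(UserWarning, match="no alignment"):
            assert find_homologous_interfaces(q, [c], {}) == []
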