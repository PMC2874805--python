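"""PDB parsing, annotations, SASA and contact counting."""

import numpy as np
import pytest

from bbscore import fixtures as fx
from bbscore.structure import (
    BackboneResidue,
    EmptyStructureError,
    MAX_SASA,
    ProteinStructure,
    assign_secondary_structure,
    contact_count,
    interhelix_contacts,
    load_max_sasa_table,
    read_backbone,
    relative_sasa,
    structure_summary,
    write_pdb,
)

from conftest import MINIMAL_PDB, random_rotation


class TestReadBackbone:
    def test_minimal_parse_with_virtual_cb(self, minimal_pdb):
        s = read_backbone(minimal_pdb)
        assert len(s) == 3
        assert s.sequence == "AGL"
        flags = [r.cb_is_virtual for r in s.residues]
        assert flags == [False, True, False]  # glycine lacks a CB in the file
        assert np.linalg.norm(s.residues[1].CB - s.residues[1].CA) == pytest.approx(1.53)

    def test_write_read_round_trip(self, tmp_path):
        helix = fx.make_ideal_helix(5)
        p = tmp_path / "helix.pdb"
        write_pdb(helix, p)
        back = read_backbone(p)
        assert len(back) == 5
        for a, b in zip(helix.residues, back.residues):
            assert np.allclose(a.CA, b.CA, atol=1.5e-3)  # PDB has 3 decimals
            assert np.allclose(a.CB, b.CB, atol=1.5e-3)

    def test_first_model_only(self, tmp_path, minimal_pdb):
        body = minimal_pdb.read_text().replace("END\n", "")
        two_models = (
            "MODEL        1\n" + body + "ENDMDL\n"
            "MODEL        2\n" + body + "ENDMDL\nEND\n"
        )
        p = tmp_path / "nmr.pdb"
        p.write_text(two_models)
        s = read_backbone(p)
        assert len(s) == 3  # residues from model 1 only

    def test_unreadable_file_raises(self, tmp_path):
        with pytest.raises(OSError):
            read_backbone(tmp_path / "missing.pdb")

    def test_no_residues_raises(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("REMARK nothing here\nEND\n")
        with pytest.raises(EmptyStructureError):
            read_backbone(p)


class TestProteinStructure:
    def test_minimum_length(self):
        res = fx.make_ideal_helix(3).residues
        with pytest.raises(ValueError):
            ProteinStructure(residues=res[:1])

    def test_monotone_indices_enforced(self):
        res = fx.make_ideal_helix(3).residues
        res[2].residue_index = 0
        with pytest.raises(ValueError):
            ProteinStructure(residues=res)


class TestSecondaryStructure:
    def test_ideal_helix_interior_is_H(self):
        s = fx.make_ideal_helix(12)
        classes = assign_secondary_structure(s)
        interior = classes[1:-1]
        assert interior.count("H") / len(interior) >= 0.9

    def test_ideal_strand_interior_is_E(self):
        s = fx.make_ideal_helix(12, -135.0, 135.0)
        classes = assign_secondary_structure(s)
        assert set(classes[1:-1]) == {"E"}

    def test_two_residue_structure_all_C(self):
        s = fx.make_ideal_helix(2)
        assert assign_secondary_structure(s) == ["C", "C"]

    def test_override_classes(self):
        s = fx.make_ideal_helix(4)
        assert assign_secondary_structure(s, override=list("HHEC")) == list("HHEC")
        with pytest.raises(ValueError):
            assign_secondary_structure(s, override=list("HX"))


def _spread_pair(distance=50.0):
    """Two residues far apart: each effectively isolated."""
    template = fx.make_ideal_helix(2).residues
    far = BackboneResidue(
        chain_id="A", residue_index=1, aa_type=template[1].aa_type,
        N=template[1].N + distance, CA=template[1].CA + distance,
        C=template[1].C + distance, CB=template[1].CB + distance,
    )
    return ProteinStructure(residues=[template[0], far], id="pair")


class TestRelativeSasa:
    def test_isolated_residue_is_exposed(self):
        s = _spread_pair()
        rsa = relative_sasa(s)
        assert all(v > 0.5 for v in rsa)

    def test_center_of_dense_cluster_is_buried(self, rng):
        # A central residue surrounded by 30 copies within 6 Angstrom.
        base = fx.make_ideal_helix(2).residues[0]
        residues = [
            BackboneResidue(
                chain_id="A", residue_index=0, aa_type="A",
                N=base.N, CA=base.CA, C=base.C, CB=base.CB,
            )
        ]
        for k in range(30):
            v = rng.standard_normal(3)
            v *= rng.uniform(3.0, 5.0) / np.linalg.norm(v)
            residues.append(
                BackboneResidue(
                    chain_id="A", residue_index=k + 1, aa_type="A",
                    N=base.N + v, CA=base.CA + v, C=base.C + v, CB=base.CB + v,
                )
            )
        s = ProteinStructure(residues=residues, id="cluster")
        rsa = relative_sasa(s)
        assert rsa[0] < 0.01

    def test_occlusion_monotonicity(self):
        sparse = _spread_pair(50.0)
        dense = _spread_pair(4.0)
        assert relative_sasa(dense)[0] <= relative_sasa(sparse)[0]


class TestContactCount:
    def test_extended_chain_has_none(self):
        s = fx.make_ideal_helix(7, -135.0, 135.0)
        assert contact_count(s) == 0

    def test_short_chain_separation_filter(self):
        s = fx.make_toy_protein(16, "hairpin", 0)
        sub = ProteinStructure(residues=s.residues[:6], id="short")
        assert contact_count(sub) == 0

    def test_matches_brute_force(self):
        s = fx.make_toy_protein(60, "helix-bundle", 3)
        cb = s.cb_coordinates()
        expected = 0
        for i in range(len(s)):
            for j in range(i + 1, len(s)):
                if (
                    s.residues[j].residue_index - s.residues[i].residue_index >= 6
                    and np.linalg.norm(cb[j] - cb[i]) <= 10.0
                ):
                    expected += 1
        assert contact_count(s) == expected

    def test_rigid_motion_invariance(self, rng):
        s = fx.make_toy_protein(40, "globule", 5)
        n0 = contact_count(s)
        R = random_rotation(rng)
        t = rng.normal(size=3) * 30
        moved = ProteinStructure(
            residues=[
                BackboneResidue(
                    chain_id=r.chain_id, residue_index=r.residue_index,
                    aa_type=r.aa_type, N=R @ r.N + t, CA=R @ r.CA + t,
                    C=R @ r.C + t, CB=R @ r.CB + t,
                )
                for r in s.residues
            ],
            id="moved",
        )
        assert contact_count(moved) == n0


class TestInterhelixContacts:
    def test_distant_helices_have_none(self):
        h1, h2, _, _ = fx.make_membrane_helix_pair(0, contact_rich=False)
        far = ProteinStructure(
            residues=[
                BackboneResidue(
                    chain_id=r.chain_id, residue_index=r.residue_index,
                    aa_type=r.aa_type, N=r.N + 50, CA=r.CA + 50, C=r.C + 50,
                    CB=r.CB + 50,
                )
                for r in h2.residues
            ],
            id="far",
        )
        assert interhelix_contacts(h1, far) == 0

    def test_threshold_rule_single_pair(self):
        a = fx.make_ideal_helix(2)
        shift = np.zeros(3)
        # Place copy so that exactly the CB-CB distance of residue 0 is 3.9.
        b_res = []
        for k, r in enumerate(a.residues):
            offset = np.array([60.0, 0, 0]) if k else (r.CB + np.array([3.9, 0, 0])) - r.CB
            b_res.append(
                BackboneResidue(
                    chain_id="B", residue_index=k, aa_type=r.aa_type,
                    N=r.N + 60, CA=r.CA + 60, C=r.C + 60, CB=r.CB + offset if k == 0 else r.CB + 60,
                )
            )
        # simpler: direct pairwise check against brute force
        b = ProteinStructure(residues=b_res, id="b")
        brute = 0
        for r1 in a.residues:
            for r2 in b.residues:
                d = np.linalg.norm(r1.atoms()[:, None, :] - r2.atoms()[None, :, :], axis=-1)
                brute += bool((d < 4.0).any())
        assert interhelix_contacts(a, b) == brute

    def test_packed_dimer_matches_brute_force(self):
        h1, h2, _, _ = fx.make_membrane_helix_pair(1)
        brute = 0
        for r1 in h1.residues:
            for r2 in h2.residues:
                d = np.linalg.norm(r1.atoms()[:, None, :] - r2.atoms()[None, :, :], axis=-1)
                brute += bool((d < 4.0).any())
        assert interhelix_contacts(h1, h2) == brute
        assert interhelix_contacts(h1, h2) >= 15


class TestConfigAndSummary:
    def test_max_sasa_table_round_trip(self, tmp_path):
        p = tmp_path / "sasa.txt"
        p.write_text("".join(f"{k} {v}\n" for k, v in MAX_SASA.items()))
        assert load_max_sasa_table(p) == MAX_SASA

    def test_max_sasa_table_missing_entry(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("A 100.0\n")
        with pytest.raises(ValueError):
            load_max_sasa_table(p)

    def test_summary_is_tab_separated(self):
        s = fx.make_ideal_helix(8)
        text = structure_summary(s)
        lines = text.strip().splitlines()
        assert lines[0].split("\t") == ["index", "aa", "ss", "relative_sasa", "acc_class"]
        assert len(lines) == 9
        assert all(len(line.split("\t")) == 5 for line in lines[1:])
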