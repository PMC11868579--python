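"""Geometry: PDB parsing, proximity sites, contact shells, superposition."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from fragkit import synthetic as syn
from fragkit.errors import (
    EmptyStructureError,
    InsufficientPairsError,
    LigandNotFoundError,
    ParseError,
)
from fragkit.structures import (
    LigandSelection,
    StructureModel,
    common_residue_pairing,
    contact_residues,
    define_site_by_proximity,
    parse_structure,
    superpose_backbone,
    write_pdb,
)

from conftest import THREE_ATOM_PDB


class TestParsing:
    def test_hand_written_block(self, three_atom_model):
        m = three_atom_model
        assert len(m) == 3
        assert {a.chain_id for a in m.atoms} == {"A"}
        assert m.atoms[0].name == "N" and m.atoms[0].element == "N"
        assert m.atoms[1].xyz == pytest.approx((11.639, 6.071, -5.147))
        assert not any(a.is_hetero for a in m.atoms)

    def test_altloc_resolved_to_highest_occupancy(self):
        text = (
            "ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.60  0.00           C\n"
            "ATOM      2  CA BALA A   1       2.000   0.000   0.000  0.40  0.00           C\n"
        )
        m = parse_structure(text)
        assert len(m) == 1
        assert m.atoms[0].altloc == "A"
        assert m.atoms[0].xyz[0] == pytest.approx(1.0)

    def test_altloc_tie_prefers_a(self):
        text = (
            "ATOM      1  CA BALA A   1       2.000   0.000   0.000  0.50  0.00           C\n"
            "ATOM      2  CA AALA A   1       1.000   0.000   0.000  0.50  0.00           C\n"
        )
        m = parse_structure(text)
        assert m.atoms[0].altloc == "A"

    def test_empty_input_raises(self):
        with pytest.raises(EmptyStructureError):
            parse_structure("")

    def test_malformed_coordinate_names_line(self):
        bad = THREE_ATOM_PDB.replace("11.639", "x1.639")
        with pytest.raises(ParseError, match="line 2"):
            parse_structure(bad)

    def test_waters_retained_and_flagged(self):
        text = (
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "HETATM    2  O   HOH A  99       5.000   0.000   0.000  1.00  0.00           O\n"
        )
        m = parse_structure(text)
        assert len(m) == 2
        assert m.atoms[1].is_water

    def test_roundtrip_through_writer(self, helix_toy):
        reparsed = parse_structure(write_pdb(helix_toy.model))
        assert len(reparsed) == len(helix_toy.model)
        np.testing.assert_allclose(
            reparsed.coordinates(), helix_toy.model.coordinates(), atol=1e-3
        )

    def test_biotite_agrees_on_generated_pdb(self, helix_toy):
        """Independent parser cross-check on a generated fixture."""
        import io

        import biotite.structure.io.pdb as bpdb

        arr = bpdb.PDBFile.read(io.StringIO(helix_toy.pdb_text)).get_structure(model=1)
        assert arr.array_length() == len(helix_toy.model)
        np.testing.assert_allclose(
            arr.coord, helix_toy.model.coordinates(), atol=1e-3
        )


class TestSiteDefinition:
    def test_line_toy_k3(self, line_toy):
        site = define_site_by_proximity(line_toy.model, line_toy.ligand, k=3)
        assert [r.residue_number for r in site.residues] == [1, 2, 3]
        assert [r.min_distance for r in site.residues] == pytest.approx([1, 2, 3])

    def test_k_exceeding_residue_count_returns_all(self, line_toy):
        site = define_site_by_proximity(line_toy.model, line_toy.ligand, k=99)
        assert len(site.residues) == 5

    def test_k_nonpositive_rejected(self, line_toy):
        with pytest.raises(ValueError):
            define_site_by_proximity(line_toy.model, line_toy.ligand, k=0)

    def test_hydrogens_ignored_in_distances(self):
        # residue 1: H at 0.5 A but nearest heavy at 6 A; residue 2: heavy at 2 A
        text = (
            "ATOM      1  H   GLY A   1       0.500   0.000   0.000  1.00  0.00           H\n"
            "ATOM      2  CA  GLY A   1       6.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      3  CA  GLY A   2       2.000   0.000   0.000  1.00  0.00           C\n"
            "HETATM    4  C1  LIG A   9       0.000   0.000   0.000  1.00  0.00           C\n"
        )
        m = parse_structure(text)
        lig = LigandSelection("A", "LIG", 9)
        site = define_site_by_proximity(m, lig, k=1)
        assert site.residues[0].residue_number == 2
        assert site.residues[0].min_distance == pytest.approx(2.0)

    def test_missing_ligand_raises(self, line_toy):
        with pytest.raises(LigandNotFoundError):
            define_site_by_proximity(
                line_toy.model, LigandSelection("A", "XYZ", 77), k=3
            )

    def test_output_sorted_ascending(self, line_toy):
        site = define_site_by_proximity(line_toy.model, line_toy.ligand, k=5)
        d = [r.min_distance for r in site.residues]
        assert d == sorted(d)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_on_random_toys(self, seed):
        """Site equals a brute-force sort of the full distance table."""
        toy = syn.generate_toy_structure(
            syn.ToyStructureSpec(n_residues=25, geometry="random-sphere", seed=seed)
        )
        site = define_site_by_proximity(toy.model, toy.ligand, k=10)
        truth = sorted(toy.distance_table.items(), key=lambda kv: (kv[1], kv[0]))
        assert [r.residue_number for r in site.residues] == [n for n, _ in truth[:10]]
        assert [r.min_distance for r in site.residues] == pytest.approx(
            [d for _, d in truth[:10]]
        )


class TestContacts:
    def test_threshold_inclusion(self):
        text = (
            "ATOM      1  CA  GLY A   1       3.900   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CA  GLY A   2       4.100   0.000   0.000  1.00  0.00           C\n"
            "HETATM    3  C1  LIG A   9       0.000   0.000   0.000  1.00  0.00           C\n"
        )
        m = parse_structure(text)
        res = contact_residues(m, LigandSelection("A", "LIG", 9), cutoff=4.0)
        assert [r.residue_number for r in res] == [1]

    def test_tiny_cutoff_empty(self, line_toy):
        assert contact_residues(line_toy.model, line_toy.ligand, cutoff=0.1) == []

    def test_known_pocket(self):
        toy = syn.generate_toy_structure(
            syn.ToyStructureSpec(n_residues=7, geometry="line", spacing=1.0)
        )
        res = contact_residues(toy.model, toy.ligand, cutoff=4.0)
        assert [r.residue_number for r in res] == [1, 2, 3, 4]

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_in_cutoff(self, seed):
        toy = syn.generate_toy_structure(
            syn.ToyStructureSpec(n_residues=30, geometry="random-sphere", seed=seed)
        )
        inner = {r.residue_number for r in contact_residues(toy.model, toy.ligand, 4.0)}
        outer = {r.residue_number for r in contact_residues(toy.model, toy.ligand, 8.0)}
        assert inner <= outer


def _brute_force_rmsd(mob, ref):
    """Independent oracle: numerical optimisation over rotations+translations."""

    def cost(p):
        R = Rotation.from_rotvec(p[:3]).as_matrix()
        moved = mob @ R.T + p[3:]
        return np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1)))

    best = np.inf
    for trial in range(4):
        x0 = np.concatenate([np.random.default_rng(trial).uniform(-1, 1, 3), [0, 0, 0]])
        res = minimize(cost, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        best = min(best, res.fun)
    return best


class TestSuperposition:
    def _identity_pairing(self, model):
        nums = sorted({a.residue_number for a in model.protein_heavy_atoms()})
        return [(("A", n), ("A", n)) for n in nums]

    def test_self_superposition_zero(self, helix_toy):
        sup = superpose_backbone(
            helix_toy.model, helix_toy.model, self._identity_pairing(helix_toy.model)
        )
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_rigid_motion_invariance(self, helix_toy):
        copy, _, _ = syn.rigid_copy(helix_toy.model, seed=42)
        sup = superpose_backbone(
            copy, helix_toy.model, self._identity_pairing(helix_toy.model)
        )
        assert sup.rmsd == pytest.approx(0.0, abs=1e-6)

    def test_rmsd_invariant_to_pre_transformation(self, helix_toy):
        """RMSD between deformed copy and reference unchanged by rigid pre-move."""
        rng = np.random.default_rng(7)
        disp = rng.normal(0, 0.4, size=(len(helix_toy.model.atoms), 3))
        deformed = syn.displace_atoms(helix_toy.model, disp)
        pairing = self._identity_pairing(helix_toy.model)
        base = superpose_backbone(deformed, helix_toy.model, pairing).rmsd
        premoved, _, _ = syn.rigid_copy(deformed, seed=99)
        moved = superpose_backbone(premoved, helix_toy.model, pairing).rmsd
        assert moved == pytest.approx(base, abs=1e-6)
        assert np.linalg.det(
            superpose_backbone(premoved, helix_toy.model, pairing).rotation
        ) == pytest.approx(1.0, abs=1e-8)

    def test_symmetry(self, helix_toy):
        rng = np.random.default_rng(3)
        disp = rng.normal(0, 0.5, size=(len(helix_toy.model.atoms), 3))
        other = syn.displace_atoms(helix_toy.model, disp)
        pairing = self._identity_pairing(helix_toy.model)
        ab = superpose_backbone(helix_toy.model, other, pairing).rmsd
        ba = superpose_backbone(other, helix_toy.model, pairing).rmsd
        assert ab == pytest.approx(ba, abs=1e-9)

    def test_uniform_shift_refits_to_zero(self, helix_toy):
        disp = np.tile([0.7, 0.0, 0.0], (len(helix_toy.model.atoms), 1))
        shifted = syn.displace_atoms(helix_toy.model, disp)
        sup = superpose_backbone(
            shifted, helix_toy.model, self._identity_pairing(helix_toy.model)
        )
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_agrees_with_numerical_optimiser(self, helix_toy):
        """Kabsch result matches a brute-force rigid-fit optimiser."""
        rng = np.random.default_rng(12)
        disp = rng.normal(0, 0.6, size=(len(helix_toy.model.atoms), 3))
        deformed = syn.displace_atoms(helix_toy.model, disp)
        pairing = self._identity_pairing(helix_toy.model)
        sup = superpose_backbone(deformed, helix_toy.model, pairing)

        # collect the same backbone coordinate pairs the implementation used
        from fragkit.structures import BACKBONE_ATOMS, _backbone_coords

        mob = np.concatenate([_backbone_coords(deformed, ("A", n)) for n in
                              sorted({a.residue_number for a in deformed.protein_heavy_atoms()})])
        ref = np.concatenate([_backbone_coords(helix_toy.model, ("A", n)) for n in
                              sorted({a.residue_number for a in helix_toy.model.protein_heavy_atoms()})])
        oracle = _brute_force_rmsd(mob, ref)
        assert sup.rmsd == pytest.approx(oracle, rel=1e-4)

    def test_insufficient_pairs(self, helix_toy):
        with pytest.raises(InsufficientPairsError):
            superpose_backbone(
                helix_toy.model, helix_toy.model, [(("A", 1), ("A", 1))]
            )

    def test_common_residue_pairing(self, helix_toy):
        copy, _, _ = syn.rigid_copy(helix_toy.model, seed=1)
        pairing = common_residue_pairing(copy, helix_toy.model, "A", "A")
        assert len(pairing) == 15
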