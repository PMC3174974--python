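import numpy as np
import pytest

from cisd import io, struct
from cisd import synthetic_data as syn
from conftest import random_rotation
from oracles import (brute_force_contacts, quaternion_rmsd,
                     two_sphere_accessible_area)


def single_atom_model(*atoms):
    # non-adjacent residue numbers so peptide through-bond exclusions never fire
    residues = [io.Residue("A", 2 * i + 1, "", "ALA", [io.Atom(n, el, xyz)])
                for i, (n, el, xyz) in enumerate(atoms)]
    return io.StructureModel("synthetic", residues, [], [])


class TestSuperpose:
    def test_identity(self, rng):
        A = rng.normal(size=(17, 3))
        R, t, rmsd = struct.superpose(A, A)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(R, np.eye(3), atol=1e-9)

    def test_rigid_motion_recovered(self, rng):
        A = rng.normal(size=(17, 3)) * 5
        Rot = random_rotation(rng)
        B = A @ Rot.T + np.array([3.0, -2.0, 7.0])
        R, t, rmsd = struct.superpose(A, B)
        assert rmsd < 1e-9
        assert np.linalg.det(R) == pytest.approx(1.0)
        assert np.allclose(struct.apply_transform(A, R, t), B, atol=1e-8)

    def test_matches_quaternion_oracle(self, rng):
        for _ in range(200):
            A = rng.normal(size=(17, 3)) * 4
            B = rng.normal(size=(17, 3)) * 4
            _, _, rmsd = struct.superpose(A, B)
            assert rmsd == pytest.approx(quaternion_rmsd(A, B), abs=1e-9)

    def test_optimality_against_random_rigid_transforms(self, rng):
        A = rng.normal(size=(17, 3)) * 4
        B = rng.normal(size=(17, 3)) * 4
        _, _, best = struct.superpose(A, B)
        for _ in range(50):
            Rot = random_rotation(rng)
            t = rng.normal(size=3) * 5
            trial = np.sqrt((((A @ Rot.T + t) - B) ** 2).sum() / len(A))
            assert best <= trial + 1e-9

    def test_reflection_not_allowed(self, rng):
        A = rng.normal(size=(10, 3))
        B = A.copy()
        B[:, 0] *= -1  # mirrored set
        R, _, _ = struct.superpose(A, B)
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_length_mismatch(self, rng):
        with pytest.raises(struct.StructError):
            struct.superpose(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))


class TestClustersAndModules:
    def test_find_clusters_in_synthetic_dimer(self, symmetric_dimer):
        clusters = struct.find_clusters(symmetric_dimer)
        assert len(clusters) == 2
        for c in clusters:
            assert len(c.fe_atoms) == 2 and len(c.s_atoms) == 2

    def test_apo_model_has_no_clusters(self):
        model = single_atom_model(("CA", "C", (0, 0, 0)))
        assert struct.find_clusters(model) == []

    def test_lone_iron_warns_and_is_excluded(self):
        fes = io.Residue("A", 101, "", "FE", [io.Atom("FE", "FE", (0, 0, 0))])
        model = io.StructureModel("m", [], [fes], [])
        with pytest.warns(UserWarning, match="lone Fe"):
            assert struct.find_clusters(model) == []

    def test_ligand_assignment_canonical_3cys1his(self, symmetric_dimer):
        clusters = struct.find_clusters(symmetric_dimer)
        ligands = struct.assign_ligands(symmetric_dimer, clusters[0])
        assert [(r.seqnum, r.name) for r, _ in ligands] == \
            [(2, "CYS"), (4, "CYS"), (13, "CYS"), (17, "HIS")]
        assert struct.coordination_class(ligands) == "3Cys1His"

    def test_isolated_cluster_has_no_ligands(self):
        fes = io.Residue("A", 101, "", "FES", [
            io.Atom("FE1", "FE", (50, 0, 0)), io.Atom("FE2", "FE", (52.7, 0, 0)),
            io.Atom("S1", "S", (51.35, 1.7, 0)), io.Atom("S2", "S", (51.35, -1.7, 0))])
        ca = single_atom_model(("CA", "C", (0, 0, 0)))
        model = io.StructureModel("m", ca.polymer, [fes], [])
        cluster = struct.find_clusters(model)[0]
        with pytest.warns(UserWarning, match="no protein ligand"):
            assert struct.assign_ligands(model, cluster) == []

    def test_module_extraction_returns_template_exactly(self, template):
        ca, cluster = template
        model = syn.gen_dimer(syn.DimerParams(center_distance=15.0, symmetric=True))
        mods = struct.extract_all_modules(model)
        assert len(mods) == 2
        chain_a = [m for m in mods if m.chain == "A"][0]
        assert np.allclose(chain_a.ca_segment, ca, atol=1e-9)
        assert [r.seqnum for r in chain_a.ca_residues] == list(range(1, 18))

    def test_chain_break_inside_window_raises(self, symmetric_dimer):
        broken = io.StructureModel(
            "broken",
            [r for r in symmetric_dimer.polymer if not (r.chain == "A" and r.seqnum == 9)],
            symmetric_dimer.het_groups, [])
        cluster = [c for c in struct.find_clusters(broken) if c.chain == "A"][0]
        with pytest.raises(struct.StructError, match="9"):
            struct.extract_module(broken, cluster)


class TestInterModuleGeometry:
    def test_cluster_distance_by_construction(self):
        for d in (10.0, 14.2, 15.9):
            model = syn.gen_dimer(syn.DimerParams(center_distance=d))
            c1, c2 = struct.find_clusters(model)
            assert struct.cluster_distance(c1, c2) == pytest.approx(d, abs=1e-9)

    def test_distance_to_self_is_zero(self, symmetric_dimer):
        c = struct.find_clusters(symmetric_dimer)[0]
        assert struct.cluster_distance(c, c) == 0.0

    def test_intermodule_angle_self_is_zero(self, symmetric_dimer):
        assert struct.intermodule_angle(symmetric_dimer, symmetric_dimer) == \
            pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("angle", [5.0, 15.0, 26.0])
    def test_constructed_shift_angle_recovered(self, angle):
        ref = syn.gen_dimer(syn.DimerParams(center_distance=15.0))
        tgt = syn.gen_dimer(syn.DimerParams(center_distance=15.0, shift_angle=angle))
        assert struct.intermodule_angle(ref, tgt) == pytest.approx(angle, abs=1e-6)

    def test_angle_invariant_under_rigid_motion(self, rng):
        ref = syn.gen_dimer(syn.DimerParams(center_distance=15.0))
        tgt = syn.gen_dimer(syn.DimerParams(center_distance=15.0, shift_angle=20.0))
        Rot, t = random_rotation(rng), rng.normal(size=3) * 20
        moved = io.StructureModel(
            "moved",
            [_move_res(r, Rot, t) for r in tgt.polymer],
            [_move_res(r, Rot, t) for r in tgt.het_groups], [])
        assert struct.intermodule_angle(ref, moved) == pytest.approx(20.0, abs=1e-6)

    def test_pseudo_dyad_symmetric(self, symmetric_dimer):
        rmsd, rotation = struct.pseudo_dyad(symmetric_dimer)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert rotation == pytest.approx(180.0, abs=1e-9)

    def test_pseudo_dyad_noise_scales(self):
        sigma = 0.3
        noisy = syn.gen_dimer(syn.DimerParams(center_distance=15.0, symmetric=True,
                                              noise_sigma=sigma, seed=5))
        rmsd, rotation = struct.pseudo_dyad(noisy)
        # two independently perturbed copies: rmsd ~ sqrt(2)*sigma
        assert 0.5 * sigma < rmsd < 3 * sigma
        assert rotation == pytest.approx(180.0, abs=15.0)


def _move_res(r, Rot, t):
    return io.Residue(r.chain, r.seqnum, r.icode, r.name, [
        io.Atom(a.name, a.element, tuple(Rot @ a.coord + t), a.occupancy)
        for a in r.atoms])


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        model = single_atom_model(("CA", "C", (0, 0, 0)))
        area = sum(struct.sasa(model).values())
        exact = 4 * np.pi * (1.70 + 1.4) ** 2
        assert abs(area - exact) / exact < 0.01

    def test_two_overlapping_spheres_vs_analytic(self):
        d = 2.5
        model = single_atom_model(("CA", "C", (0, 0, 0)), ("CA", "C", (d, 0, 0)))
        areas = list(struct.sasa(model).values())
        r = 1.70 + 1.4
        exact1, exact2 = two_sphere_accessible_area(r, r, d)
        assert abs(areas[0] - exact1) / exact1 < 0.01
        assert abs(areas[1] - exact2) / exact2 < 0.01

    def test_fully_enclosed_atom_has_zero_area(self):
        # central atom caged by a dense shell
        shell = []
        golden = np.pi * (1 + 5 ** 0.5)
        for i in range(60):
            phi = np.arccos(1 - 2 * (i + 0.5) / 60)
            theta = golden * i
            p = 2.2 * np.array([np.sin(phi) * np.cos(theta),
                                np.sin(phi) * np.sin(theta), np.cos(phi)])
            shell.append(("CA", "C", tuple(p)))
        model = single_atom_model(("CA", "C", (0.0, 0.0, 0.0)), *shell)
        areas = struct.sasa(model)
        assert areas[("A", 1, "", "CA")] == 0.0

    def test_waters_excluded(self, symmetric_dimer):
        wet = io.StructureModel(
            "wet", symmetric_dimer.polymer, symmetric_dimer.het_groups,
            [io.Residue("A", 201, "", "HOH", [io.Atom("O", "O", (0, 0, 0))])])
        assert struct.sasa(wet).keys() == struct.sasa(symmetric_dimer).keys()

    def test_unknown_element_needs_default_radius(self):
        model = single_atom_model(("X1", "XX", (0, 0, 0)))
        with pytest.raises(struct.StructError):
            struct.sasa(model)
        assert sum(struct.sasa(model, default_radius=1.5).values()) > 0

    def test_rigid_motion_invariance(self, rng, symmetric_dimer):
        base = sum(struct.sasa(symmetric_dimer, n_points=240).values())
        Rot, t = random_rotation(rng), rng.normal(size=3) * 30
        moved = io.StructureModel(
            "mv", [_move_res(r, Rot, t) for r in symmetric_dimer.polymer],
            [_move_res(r, Rot, t) for r in symmetric_dimer.het_groups], [])
        other = sum(struct.sasa(moved, n_points=240).values())
        assert abs(base - other) / base < 0.02  # quadrature reorientation only


class TestBuriedArea:
    def test_symmetric_dimer_buries_equally(self, symmetric_dimer):
        a, b = struct.buried_area(symmetric_dimer, "A", "B", n_points=240)
        assert a > 0 and b > 0
        assert abs(a - b) / a < 0.05

    def test_distant_chains_bury_nothing(self):
        far = syn.gen_dimer(syn.DimerParams(center_distance=100.0))
        a, b = struct.buried_area(far, "A", "B", n_points=240)
        assert a == pytest.approx(0.0, abs=1e-6)
        assert b == pytest.approx(0.0, abs=1e-6)

    def test_missing_chain_raises(self, symmetric_dimer):
        with pytest.raises(struct.StructError):
            struct.buried_area(symmetric_dimer, "A", "Z")


class TestHbondsAndContacts:
    def test_ideal_pair_detected(self):
        model = single_atom_model(("N", "N", (0, 0, 0)), ("O", "O", (2.9, 0, 0)))
        bonds = struct.detect_hbonds(model)
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(2.9)

    def test_far_pair_not_detected(self):
        model = single_atom_model(("N", "N", (0, 0, 0)), ("O", "O", (9, 0, 0)))
        assert struct.detect_hbonds(model) == []

    def test_same_residue_excluded(self):
        res = io.Residue("A", 1, "", "ASN", [io.Atom("N", "N", (0, 0, 0)),
                                             io.Atom("OD1", "O", (2.8, 0, 0))])
        model = io.StructureModel("m", [res], [], [])
        assert struct.detect_hbonds(model) == []

    def test_adjacent_backbone_excluded(self):
        r1 = io.Residue("A", 1, "", "ALA", [io.Atom("O", "O", (0, 0, 0))])
        r2 = io.Residue("A", 2, "", "ALA", [io.Atom("N", "N", (2.3, 0, 0))])
        model = io.StructureModel("m", [r1, r2], [], [])
        assert struct.detect_hbonds(model) == []

    def test_contacts_match_brute_force(self, rng):
        coords = rng.normal(size=(250, 3)) * 8
        resA = [io.Residue("A", i + 1, "", "ALA", [io.Atom("CA", "C", tuple(c))])
                for i, c in enumerate(coords[:125])]
        resB = [io.Residue("B", i + 1, "", "ALA", [io.Atom("CA", "C", tuple(c))])
                for i, c in enumerate(coords[125:])]
        model = io.StructureModel("m", resA + resB, [], [])
        got = {(c.res1[1], c.res2[1]) for c in struct.close_contacts(model, "A", "B", 4.0)}
        want = {(i + 1, j + 1)
                for i, j in brute_force_contacts(coords[:125], coords[125:], 4.0)}
        assert got == want

    def test_disjoint_chains_no_contacts(self):
        far = syn.gen_dimer(syn.DimerParams(center_distance=100.0))
        assert struct.close_contacts(far, "A", "B", 3.8) == []

    def test_atom_filter_restricts(self, symmetric_dimer):
        all_pairs = struct.close_contacts(symmetric_dimer, "A", "B", 8.0)
        ca_only = struct.close_contacts(
            symmetric_dimer, "A", "B", 8.0,
            atom_filter=lambda r, a: a.name == "CA")
        assert len(ca_only) <= len(all_pairs)
        assert all(c.atom1 == "CA" and c.atom2 == "CA" for c in ca_only)


class TestWaters:
    def test_count(self, symmetric_dimer):
        assert struct.count_waters(symmetric_dimer) == 0
        wet = io.StructureModel(
            "wet", symmetric_dimer.polymer, symmetric_dimer.het_groups,
            [io.Residue("A", 200 + i, "", "HOH", [io.Atom("O", "O", (i, 0, 0))])
             for i in range(7)])
        assert struct.count_waters(wet) == 7
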