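"""Dihedrals, ABEGO bins, Kabsch superposition and the backbone builder."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from ploopkit.errors import GeometryError, SpecError
from ploopkit.fixtures import FixtureSpec, make_motif_fixture
from ploopkit.geometry import (
    CHAIN_BREAK_CN,
    ResidueTorsions,
    abego_bin,
    abego_classify,
    backbone_torsions,
    build_backbone,
    compare_models,
    dihedral_angle,
    kabsch_superpose,
    random_rotation,
    transform_model,
)


class TestDihedral:
    @pytest.mark.parametrize(
        "points,expected",
        [
            ([(0, 0, 0), (1, 0, 0), (1, 1, 0), (2, 1, 0)], 180.0),
            ([(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)], 0.0),
            ([(0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1)], 90.0),
            ([(0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, -1)], -90.0),
        ],
    )
    def test_reference_angles(self, points, expected):
        assert dihedral_angle(*points) == pytest.approx(expected, abs=1e-9)

    def test_invariant_under_rigid_transforms(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            pts = rng.normal(scale=3.0, size=(4, 3))
            try:
                ref = dihedral_angle(*pts)
            except GeometryError:
                continue
            rot = random_rotation(rng)
            shift = rng.normal(scale=10.0, size=3)
            moved = [rot @ p + shift for p in pts]
            assert dihedral_angle(*moved) == pytest.approx(ref, abs=1e-9)

    def test_degenerate_geometry_raises(self):
        with pytest.raises(GeometryError):
            dihedral_angle((0, 0, 0), (0, 0, 0), (1, 0, 0), (2, 0, 0))
        with pytest.raises(GeometryError):
            dihedral_angle((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))


class TestAbego:
    @pytest.mark.parametrize(
        "phi,psi,omega,expected",
        [
            (-57, -47, 180, "A"),
            (60, 40, 180, "G"),
            (-120, 130, 180, "B"),
            (60, 170, 180, "E"),
            (-57, -47, 0, "O"),
            (-57, -47, 89.9, "O"),
            (-1e-9, -47, 180, "A"),  # phi < 0 boundary
            (0.0, -47, 180, "G"),  # phi >= 0 inclusive
            (-57, 50.0, 180, "B"),  # psi upper bound exclusive for A
            (-57, -75.0, 180, "A"),  # psi lower bound inclusive for A
        ],
    )
    def test_bin_table(self, phi, psi, omega, expected):
        assert abego_bin(phi, psi, omega) == expected

    def test_undefined_torsions_get_dash(self):
        assert abego_classify([ResidueTorsions(None, -47.0, 180.0)]) == "-"
        assert abego_classify([ResidueTorsions(-57.0, None, None)]) == "-"

    def test_partition_on_degree_grid(self):
        """Every defined (phi, psi) maps to exactly one of A/B/G/E."""
        grid = np.arange(-179.5, 180.5, 1.0)
        for phi in grid:
            row = [abego_bin(float(phi), float(psi), 180.0) for psi in grid]
            assert set(row) <= set("ABGE")
            # phi determines the A/B vs G/E family
            family = set("AB") if phi < 0 else set("GE")
            assert set(row) <= family


class TestKabsch:
    def test_identity(self):
        pts = np.random.default_rng(1).normal(size=(6, 3))
        res = kabsch_superpose(pts, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-9)
        assert res.n_pairs == 6

    def test_congruent_sets_rmsd_zero(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(8, 3))
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = pts @ rot.T + np.array([5.0, 0.0, 0.0])
        res = kabsch_superpose(pts, moved)
        assert res.rmsd == pytest.approx(0.0, abs=1e-6)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-6)

    def test_rotation_is_proper_never_reflection(self):
        # mirror-image point sets must be fit with a proper rotation only
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(5, 3))
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        res = kabsch_superpose(pts, mirrored)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-6)
        assert res.rmsd > 0.1

    @staticmethod
    def _oracle_rmsd(mobile, reference):
        """Numerical minimization over rotation vectors (independent of SVD)."""
        x = mobile - mobile.mean(axis=0)
        y = reference - reference.mean(axis=0)

        def cost(rotvec):
            rot = Rotation.from_rotvec(rotvec).as_matrix()
            return float(np.mean(np.sum((x @ rot.T - y) ** 2, axis=1)))

        best = math.inf
        rng = np.random.default_rng(0)
        for _ in range(8):
            res = minimize(cost, rng.uniform(-math.pi, math.pi, 3), method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000})
            best = min(best, res.fun)
        return math.sqrt(best)

    def test_matches_numerical_minimization_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(15):
            n = int(rng.integers(3, 12))
            mobile = rng.normal(scale=2.0, size=(n, 3))
            reference = rng.normal(scale=2.0, size=(n, 3))
            try:
                res = kabsch_superpose(mobile, reference)
            except GeometryError:
                continue
            assert res.rmsd == pytest.approx(self._oracle_rmsd(mobile, reference), abs=1e-5)

    def test_scaled_triangle_matches_oracle(self):
        mobile = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        reference = 2.0 * mobile
        res = kabsch_superpose(mobile, reference)
        assert res.rmsd == pytest.approx(self._oracle_rmsd(mobile, reference), abs=1e-6)

    def test_superposed_rmsd_never_exceeds_raw(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = rng.normal(size=(7, 3))
            b = rng.normal(size=(7, 3))
            raw = math.sqrt(float(np.mean(np.sum((a - b) ** 2, axis=1))))
            assert kabsch_superpose(a, b).rmsd <= raw + 1e-12

    def test_too_few_or_collinear_points_raise(self):
        with pytest.raises(GeometryError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(GeometryError):
            kabsch_superpose(line, line + 1.0)


class TestBackboneBuilder:
    def test_round_trip_all_helix(self):
        torsions = [(-57.0, -47.0, 180.0)] * 8
        model = build_backbone("AAAAAAAA", torsions)
        recovered = backbone_torsions(model.chain("A"))
        assert abego_classify(recovered) == "-AAAAAA-"
        for i, t in enumerate(recovered):
            if t.phi is not None:
                assert t.phi == pytest.approx(-57.0, abs=1e-3)
            if t.psi is not None:
                assert t.psi == pytest.approx(-47.0, abs=1e-3)

    def test_round_trip_random_specs(self):
        """Internal-coordinate build followed by torsion extraction recovers
        the spec within 1e-3 degrees (1,000 seeded draws)."""
        rng = np.random.default_rng(2024)
        worst = 0.0
        for _ in range(1000):
            n = int(rng.integers(3, 10))
            torsions = [
                (
                    float(rng.uniform(-179.9, 180.0)),
                    float(rng.uniform(-179.9, 180.0)),
                    float(rng.uniform(120.0, 180.0)) * (1 if rng.random() < 0.5 else -1),
                )
                for _ in range(n)
            ]
            model = build_backbone("A" * n, torsions)
            recovered = backbone_torsions(model.chain("A"))
            for i in range(n):
                if recovered[i].phi is not None:
                    worst = max(worst, abs(recovered[i].phi - torsions[i][0]))
                if recovered[i].psi is not None:
                    worst = max(worst, abs(recovered[i].psi - torsions[i][1]))
                if recovered[i].omega is not None:
                    delta = abs(recovered[i].omega - torsions[i][2])
                    worst = max(worst, min(delta, 360.0 - delta))
        assert worst < 1e-3

    def test_atom_counts(self):
        model = build_backbone("GAVG", [(-57.0, -47.0, 180.0)] * 4)
        residues = model.chain("A")
        backbone = sum(1 for r in residues for a in r.atoms if a.atom_name in {"N", "CA", "C", "O"})
        cb = sum(1 for r in residues for a in r.atoms if a.atom_name == "CB")
        assert backbone == 16
        assert cb == 2  # non-Gly only

    def test_cis_omega_round_trips_to_o_bin(self):
        torsions = [(-57.0, -47.0, 180.0)] * 5
        torsions[2] = (-57.0, -47.0, 5.0)
        model = build_backbone("AAAAA", torsions)
        assert abego_classify(backbone_torsions(model.chain("A")))[2] == "O"

    def test_single_residue_torsions_undefined(self):
        model = build_backbone("A", [(-57.0, -47.0, 180.0)])
        t = backbone_torsions(model.chain("A"))[0]
        assert t.phi is None and t.psi is None and t.omega is None

    def test_invalid_angle_rejected(self):
        with pytest.raises(SpecError):
            build_backbone("AA", [(-57.0, -47.0, 180.0), (-200.0, 0.0, 180.0)])

    def test_chain_break_masks_torsions(self):
        model = build_backbone("AAAAAA", [(-57.0, -47.0, 180.0)] * 6)
        residues = model.chain("A")
        # translate the C-terminal half far away: creates a >2 Å C-N gap
        for res in residues[3:]:
            for atom in res.atoms:
                atom.coords = atom.coords + np.array([10.0, 0.0, 0.0])
        torsions = backbone_torsions(residues)
        assert torsions[2].psi is None  # before the gap
        assert torsions[3].phi is None and torsions[3].omega is None  # after the gap
        assert CHAIN_BREAK_CN == pytest.approx(2.0)


class TestCompareModels:
    def test_self_and_translated_copy_rmsd_zero(self):
        model, _ = make_motif_fixture(FixtureSpec(seed=9))
        assert compare_models(model, model, "A", "A").rmsd == pytest.approx(0.0, abs=1e-9)
        shifted = transform_model(model, np.eye(3), np.array([3.0, -2.0, 7.0]))
        assert compare_models(model, shifted, "A", "A").rmsd == pytest.approx(0.0, abs=1e-6)

    def test_symmetric_in_model_order(self):
        rng = np.random.default_rng(12)
        model, _ = make_motif_fixture(FixtureSpec(seed=9))
        noisy = transform_model(model, random_rotation(rng), rng.normal(size=3))
        for res in noisy.chain("A"):
            for atom in res.atoms:
                atom.coords = atom.coords + rng.normal(scale=0.4, size=3)
        forward = compare_models(model, noisy, "A", "A").rmsd
        backward = compare_models(noisy, model, "A", "A").rmsd
        assert forward == pytest.approx(backward, abs=1e-9)
        assert forward > 0.1

    def test_sequence_align_pairing_matches_auth_pairing_on_renumbered_copy(self):
        model, _ = make_motif_fixture(FixtureSpec(seed=9))
        shifted_numbering, _ = make_motif_fixture(FixtureSpec(seed=9, start_auth=501))
        by_align = compare_models(model, shifted_numbering, "A", "A", pairing="sequence_align")
        assert by_align.rmsd == pytest.approx(0.0, abs=1e-6)
        assert by_align.n_pairs == len(model.chain("A"))
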