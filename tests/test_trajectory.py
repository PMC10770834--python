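"""Trajectory observables: superposition, RMSD/RMSF, Rg, SASA, covariance."""

import math

import numpy as np
import pytest
from scipy.stats import spearmanr

from bindscope import (
    AtomRadii,
    FluctuationDesign,
    Trajectory,
    count_hbonds_series,
    covariance_analysis,
    generate_trajectory,
    kabsch_superpose,
    make_toy_protein,
    radius_of_gyration,
    rg_series,
    rmsd_series,
    rmsf,
    sasa,
    summarize,
)
from bindscope.structure import Atom, Structure
from bindscope.trajectory import read_xyz, select_atoms


def random_rotation(rng):
    q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def static_trajectory(n_frames=6, n_residues=8):
    base = make_toy_protein(n_residues)
    frames = np.repeat(base.coords[None], n_frames, axis=0)
    return Trajectory(topology=base, frames=frames)


def rigid_moved_trajectory(seed=0, n_frames=6, n_residues=8):
    base = make_toy_protein(n_residues)
    rng = np.random.default_rng(seed)
    frames = np.array(
        [base.coords @ random_rotation(rng).T + rng.uniform(-10, 10, 3)
         for _ in range(n_frames)]
    )
    return Trajectory(topology=base, frames=frames)


class TestKabsch:
    def test_identity_and_rigid_motion(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=(7, 3))
        rot, trans, r = kabsch_superpose(ref, ref)
        assert r == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-10)
        rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        moved = ref @ rz.T + np.array([5.0, 5.0, 5.0])
        _, _, r2 = kabsch_superpose(ref, moved)
        assert r2 == pytest.approx(0.0, abs=1e-10)

    def test_analytic_stretch(self):
        """A pair stretched to double its centred offsets, with symmetric
        anchors pinning the optimal rotation to the identity, gives a
        pair rmsd of exactly 1.0 A after superposition."""
        ref = np.array([[-1.0, 0, 0], [1.0, 0, 0], [0, 3.0, 0], [0, -3.0, 0]])
        mob = np.array([[-2.0, 0, 0], [2.0, 0, 0], [0, 3.0, 0], [0, -3.0, 0]])
        rot, trans, r_all = kabsch_superpose(ref, mob)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-9)
        moved = mob @ rot.T + trans
        pair_rmsd = math.sqrt(np.mean(np.sum((moved[:2] - ref[:2]) ** 2, axis=1)))
        assert pair_rmsd == pytest.approx(1.0, abs=1e-10)
        # over all four atoms: only the stretched pair deviates
        assert r_all == pytest.approx(math.sqrt(2.0 / 4.0), abs=1e-10)

    def test_brute_force_rotation_grid_oracle(self):
        """Kabsch attains the minimum a 2-degree rotation-grid search finds,
        within grid resolution, on small toys."""
        from conftest import brute_force_min_rmsd

        rng = np.random.default_rng(4)
        for trial in range(2):
            ref = rng.normal(scale=1.5, size=(5, 3))
            mob = ref + rng.normal(scale=0.4, size=(5, 3))
            _, _, r_kabsch = kabsch_superpose(ref, mob)
            r_grid = brute_force_min_rmsd(ref, mob, step_deg=2.0)
            assert r_kabsch <= r_grid + 1e-9
            tol = float(np.abs(mob - mob.mean(0)).max()) * math.radians(2.0) * math.sqrt(3)
            assert r_grid - r_kabsch <= tol

    def test_degenerate_selection_rejected(self):
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        with pytest.raises(ValueError, match="degenerate"):
            kabsch_superpose(line, line + 1.0)
        with pytest.raises(ValueError, match="degenerate"):
            kabsch_superpose(line[:2], line[:2])


class TestRMSD:
    def test_static_and_rigid_motion_zero(self):
        assert rmsd_series(static_trajectory()).max() == pytest.approx(0.0, abs=1e-12)
        assert rmsd_series(rigid_moved_trajectory()).max() <= 1e-9

    def test_bad_reference_index(self):
        with pytest.raises(ValueError, match="out of range"):
            rmsd_series(static_trajectory(), reference=99)

    def test_known_displacement(self):
        """Uniform +1 A x-shift of half the atoms vs an anchored rest."""
        base = make_toy_protein(10)
        coords = base.coords
        moved = coords.copy()
        moved[:2] += np.array([1.0, 0, 0])
        traj = Trajectory(topology=base, frames=np.stack([coords, moved]))
        r = rmsd_series(traj, reference=0, selection="all")
        assert r[0] == pytest.approx(0.0, abs=1e-12)
        # superposition redistributes part of the shift; rmsd stays below
        # the naive sqrt(2/40)*1 A and above zero
        assert 0 < r[1] <= math.sqrt(2 / 40) / 10


class TestRMSF:
    def test_static_zero_and_single_frame_error(self):
        per_res, arr = rmsf(static_trajectory())
        assert arr.max() == pytest.approx(0.0, abs=1e-12)
        single = Trajectory(
            topology=make_toy_protein(4),
            frames=make_toy_protein(4).coords[None],
        )
        with pytest.raises(ValueError, match=">= 2 frames"):
            rmsf(single)

    def test_oscillating_atom_amplitude(self):
        """One CA oscillating +-a along x among many static atoms has
        RMSF ~= a (superposition anchored by the static majority)."""
        base = make_toy_protein(20)
        ca = select_atoms(base, "ca")
        coords = base.coords
        a = 0.8  # A
        frames = np.repeat(coords[None], 40, axis=0)
        target = int(ca[10])
        frames[:20, target, 0] += a
        frames[20:, target, 0] -= a
        traj = Trajectory(topology=base, frames=frames)
        anchors = [int(i) for i in ca if i != target]
        per_res, arr = rmsf(traj, "ca", fit_selection=anchors)
        key = base.atoms[target].residue_key
        assert per_res[key] == pytest.approx(a / 10.0, rel=1e-9)
        # without a separate fit group the superposition absorbs a bit
        per_res_coupled, _ = rmsf(traj, "ca")
        assert 0.8 * a / 10.0 < per_res_coupled[key] < a / 10.0

    def test_planted_amplitude_rank_recovery(self):
        """Per-residue planted amplitudes are recovered in rank order."""
        base = make_toy_protein(12)
        amps = {("A", i): 0.08 * i for i in range(1, 13)}
        traj, planted = generate_trajectory(
            FluctuationDesign(base_structure=base, per_residue_amplitude=amps,
                              rigid_jitter=(8.0, 2.0), n_frames=150, seed=5)
        )
        per_res, _ = rmsf(traj, "ca")
        keys = sorted(per_res)
        rho = spearmanr([planted[k] for k in keys], [per_res[k] for k in keys]).statistic
        assert rho >= 0.95

    def test_anchored_magnitude_matches_closed_form(self):
        """With static anchor residues, RMSF of the one fluctuating
        residue approaches sqrt(3)*amplitude."""
        base = make_toy_protein(20)
        amps = {("A", 10): 0.5}
        traj, _ = generate_trajectory(
            FluctuationDesign(base_structure=base, per_residue_amplitude=amps,
                              rigid_jitter=(5.0, 1.0), n_frames=400, seed=2)
        )
        per_res, _ = rmsf(traj, "ca")
        expected = math.sqrt(3) * 0.5 / 10.0  # nm
        assert per_res[("A", 10)] == pytest.approx(expected, rel=0.10)


class TestRg:
    def test_analytic_values(self):
        assert radius_of_gyration(np.zeros((1, 3)), np.array([12.0])) == 0.0
        two = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert radius_of_gyration(two, np.ones(2)) == pytest.approx(0.1)  # nm

    def test_homogeneity_and_mass_weighting(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(30, 3))
        masses = rng.uniform(1, 16, 30)
        rg1 = radius_of_gyration(coords, masses)
        assert radius_of_gyration(2.5 * coords, masses) == pytest.approx(2.5 * rg1)
        heavy = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        # all mass on one atom -> Rg ~ 0
        assert radius_of_gyration(heavy, np.array([1e9, 1e-9])) < 1e-4

    def test_series_rigid_invariance(self):
        t1 = static_trajectory()
        t2 = rigid_moved_trajectory()
        np.testing.assert_allclose(rg_series(t1), rg_series(t2), atol=1e-9)


class TestSASA:
    def test_single_atom_closed_form(self):
        total, per_atom = sasa(np.zeros((1, 3)), ["C"], n_sphere_points=960)
        expected = 4 * math.pi * 3.1**2 / 100.0  # nm^2
        quantum = expected / 960
        assert abs(total - expected) <= quantum + 1e-12

    def test_disjoint_additivity(self):
        coords = np.array([[0.0, 0, 0], [50.0, 0, 0]])
        total, _ = sasa(coords, ["C", "C"])
        single, _ = sasa(np.zeros((1, 3)), ["C"])
        assert total == pytest.approx(2 * single, rel=1e-12)

    def test_two_sphere_spherical_cap(self):
        r = 1.70 + 1.4
        for d in (2.0, 3.0, 4.5):
            total, _ = sasa(np.array([[0.0, 0, 0], [d, 0, 0]]), ["C", "C"],
                            n_sphere_points=960)
            expected = 4 * math.pi * r * (r + d / 2) / 100.0
            assert total == pytest.approx(expected, rel=0.02)

    def test_convergence_with_point_count(self):
        rng = np.random.default_rng(6)
        coords = rng.normal(scale=3.0, size=(50, 3))
        elements = ["C"] * 50
        s960, _ = sasa(coords, elements, n_sphere_points=960)
        s3840, _ = sasa(coords, elements, n_sphere_points=3840)
        assert abs(s960 - s3840) / s3840 <= 0.01

    def test_missing_radius_names_element(self):
        with pytest.raises(ValueError, match="'Xe'"):
            sasa(np.zeros((1, 3)), ["Xe"])

    def test_biotite_cross_check(self):
        """Independent Shrake-Rupley implementation agrees on a toy."""
        import biotite.structure as bst

        rng = np.random.default_rng(12)
        coords = rng.normal(scale=2.5, size=(12, 3))
        total, _ = sasa(coords, ["C"] * 12, n_sphere_points=3840)
        arr = bst.AtomArray(12)
        arr.coord = coords.astype(np.float32)
        arr.element = np.array(["C"] * 12)
        arr.atom_name = np.array(["C"] * 12)
        arr.res_name = np.array(["UNK"] * 12)
        arr.res_id = np.arange(1, 13)
        arr.chain_id = np.array(["A"] * 12)
        ref = bst.sasa(arr, probe_radius=1.4, point_number=1000,
                       vdw_radii="Single").sum() / 100.0
        assert total == pytest.approx(ref, rel=0.03)


class TestHbondSeries:
    def drifting_pair(self, distances):
        atoms = [
            Atom(1, "N", "N", "ASN", 1, "A", np.zeros(3)),
            Atom(2, "CA", "C", "ASN", 1, "A", np.array([1.5, 0, 0.0])),
            Atom(3, "O1", "O", "LIG", 900, "L", np.array([0, 3.0, 0.0]), is_ligand=True),
        ]
        top = Structure(atoms)
        frames = np.array([
            [[0, 0, 0], [1.5, 0, 0], [0, d, 0]] for d in distances
        ], dtype=float)
        return Trajectory(topology=top, frames=frames)

    def test_planted_pair_counted_every_frame(self):
        traj = self.drifting_pair([2.9] * 4)
        counts = count_hbonds_series(traj, [0, 1], [2])
        assert counts.tolist() == [1, 1, 1, 1]

    def test_drift_crosses_cutoff(self):
        distances = np.linspace(3.0, 4.0, 6)  # 3.0,3.2,...,4.0
        counts = count_hbonds_series(self.drifting_pair(distances), [0, 1], [2])
        expected = [1 if d <= 3.5 else 0 for d in distances]
        assert counts.tolist() == expected

    def test_group_validation(self):
        traj = self.drifting_pair([2.9, 2.9])
        with pytest.raises(ValueError, match="non-empty"):
            count_hbonds_series(traj, [0, 1], [])
        with pytest.raises(ValueError, match="overlapping"):
            count_hbonds_series(traj, [0, 1], [1, 2])


class TestCovariance:
    def test_static_trace_zero(self):
        assert covariance_analysis(static_trajectory()).trace == pytest.approx(0.0, abs=1e-15)

    def test_trace_equals_sum_of_variances_and_eigenvalues(self):
        traj, _ = generate_trajectory(
            FluctuationDesign(base_structure=make_toy_protein(8),
                              per_residue_amplitude=0.4, rigid_jitter=(0.0, 0.0),
                              n_frames=60, seed=7)
        )
        res = covariance_analysis(traj, "ca")
        sel = select_atoms(traj.topology, "ca")
        x = traj.frames[:, sel, :].reshape(60, -1) / 10.0
        # identical superposition path not required: with zero jitter and a
        # centred fluctuation, variances dominate any alignment correction
        assert res.trace == pytest.approx(res.eigenvalues.sum(), rel=1e-10)
        assert res.projections.shape == (60, 2)

    def test_planted_isotropic_variance(self):
        """One residue fluctuating with sigma per axis among static anchors
        contributes ~3*sigma^2 to the trace."""
        base = make_toy_protein(24)
        sigma = 0.6  # A
        traj, _ = generate_trajectory(
            FluctuationDesign(base_structure=base,
                              per_residue_amplitude={("A", 12): sigma},
                              rigid_jitter=(0.0, 0.0), n_frames=600, seed=9)
        )
        res = covariance_analysis(traj, "ca")
        expected = 3 * sigma**2 / 100.0  # nm^2
        assert res.trace == pytest.approx(expected, rel=0.15)

    def test_rigid_motion_invariance(self):
        base = make_toy_protein(8)
        traj, _ = generate_trajectory(
            FluctuationDesign(base_structure=base, per_residue_amplitude=0.3,
                              rigid_jitter=(0.0, 0.0), n_frames=30, seed=3)
        )
        rng = np.random.default_rng(0)
        frames2 = np.array([
            f @ random_rotation(rng).T + rng.uniform(-5, 5, 3) for f in traj.frames
        ])
        t2 = Trajectory(topology=base, frames=frames2)
        a = covariance_analysis(traj, "ca")
        b = covariance_analysis(t2, "ca")
        assert b.trace == pytest.approx(a.trace, abs=1e-8)


class TestSummaryAndIO:
    def test_static_summary_row(self):
        traj = static_trajectory(n_frames=4)
        s = summarize(traj, n_sphere_points=240)
        assert s.mean_rmsd == pytest.approx(0.0, abs=1e-10)
        assert s.mean_rmsf == pytest.approx(0.0, abs=1e-10)
        assert s.covariance_trace == pytest.approx(0.0, abs=1e-12)
        assert s.mean_rg > 0 and s.mean_sasa > 0

    def test_xyz_reader(self, tmp_path):
        path = tmp_path / "t.xyz"
        path.write_text(
            "2\nframe 0\nC 0.0 0.0 0.0\nO 1.2 0.0 0.0\n"
            "2\nframe 1\nC 0.0 0.0 0.1\nO 1.2 0.0 0.1\n"
        )
        elements, frames = read_xyz(path)
        assert elements == ["C", "O"]
        assert frames.shape == (2, 2, 3)
        traj = Trajectory.from_xyz(path)
        assert traj.n_atoms == 2 and traj.n_frames == 2
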