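"""Gyration-based shape descriptors, iMSD, distance distributions, t-test."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from oracles import gyration_descriptors_oracle
from ringtop import (
    SystemConfig,
    Trajectory,
    distance_distributions,
    gyration_radius,
    gyration_tensor,
    imsd,
    welch_t_test,
)
from ringtop.static_metrics import ensemble_rg


class TestGyrationRadius:
    def test_coincident_beads_zero(self, make_frame):
        assert gyration_radius(make_frame([[1, 2, 3]] * 5)) == 0.0

    def test_two_beads_half_separation(self, make_frame):
        d = 1.7
        frame = make_frame([[0, 0, 0], [d, 0, 0]])
        assert gyration_radius(frame) == pytest.approx(d / 2)

    def test_square_side_over_sqrt2(self, make_frame):
        s = 0.8
        frame = make_frame([[0, 0, 0], [s, 0, 0], [s, s, 0], [0, s, 0]])
        assert gyration_radius(frame) == pytest.approx(s / np.sqrt(2))


class TestGyrationTensor:
    def test_matches_double_loop_oracle(self, rng, make_frame):
        beads = rng.normal(size=(10, 3))
        got = gyration_tensor(make_frame(beads))
        want = gyration_descriptors_oracle(beads)
        assert got.rg == pytest.approx(want["rg"], rel=1e-12)
        np.testing.assert_allclose(got.eigenvalues, want["eigenvalues"], rtol=1e-10)
        assert got.asphericity == pytest.approx(want["asphericity"], rel=1e-9)
        assert got.acylindricity == pytest.approx(want["acylindricity"], rel=1e-9)
        assert got.anisotropy == pytest.approx(want["anisotropy"], rel=1e-9)

    def test_rg_squared_is_eigenvalue_sum(self, rng, make_frame):
        for _ in range(20):
            g = gyration_tensor(make_frame(rng.normal(size=(8, 3))))
            assert g.rg**2 == pytest.approx(g.eigenvalues.sum(), rel=1e-10)

    def test_spherical_shell_nearly_isotropic(self, rng, make_frame):
        x = rng.normal(size=(4000, 3))
        shell = x / np.linalg.norm(x, axis=1, keepdims=True)
        g = gyration_tensor(make_frame(shell))
        # b and c carry units of length^2 and shrink like 1/sqrt(n); kappa^2
        # is the dimensionless criterion and must be < 0.01
        assert abs(g.asphericity) < 0.05 * g.rg**2
        assert abs(g.acylindricity) < 0.05 * g.rg**2
        assert 0 <= g.anisotropy < 0.01

    def test_collinear_cloud_anisotropy_one(self, make_frame):
        beads = np.outer(np.linspace(0, 1, 7), [1.0, 2.0, -0.5])
        g = gyration_tensor(make_frame(beads))
        assert g.anisotropy == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_cloud_flagged(self, make_frame):
        g = gyration_tensor(make_frame([[0.5, 0.5, 0.5]] * 4))
        assert g.degenerate and g.anisotropy == 0.0

    def test_rotation_translation_invariance(self, rng, make_frame):
        beads = rng.normal(size=(12, 3))
        rot = Rotation.random(random_state=7).as_matrix()
        moved = beads @ rot.T + np.array([5.0, -2.0, 9.0])
        g0, g1 = gyration_tensor(make_frame(beads)), gyration_tensor(make_frame(moved))
        assert g1.rg == pytest.approx(g0.rg, abs=1e-9)
        np.testing.assert_allclose(g1.eigenvalues, g0.eigenvalues, atol=1e-9)
        assert g1.anisotropy == pytest.approx(g0.anisotropy, abs=1e-9)


def _single_atom_traj(beads_by_time, timestep=1.0):
    p = np.asarray(beads_by_time[0]).shape[0]
    cfg = SystemConfig(n_beads=p, timestep=timestep, length_unit="angstrom")
    from ringtop import RingPolymerFrame

    frames = {
        0: [
            RingPolymerFrame(0, "A", t, np.asarray(b, float))
            for t, b in enumerate(beads_by_time)
        ]
    }
    return Trajectory(config=cfg, frames=frames)


class TestIMSD:
    def test_lag_zero_is_zero(self, rng):
        traj = _single_atom_traj([rng.normal(size=(8, 3))])
        curve = imsd(traj)
        assert curve.values[0] == 0.0
        assert curve.values[-1] == 0.0  # lag P wraps to lag 0

    def test_two_bead_ring(self):
        d = 1.3
        traj = _single_atom_traj([[[0, 0, 0], [d, 0, 0]]])
        curve = imsd(traj)
        assert curve.values[1] == pytest.approx(d**2)

    def test_symmetric_about_half_p(self, rng):
        traj = _single_atom_traj([rng.normal(size=(10, 3)) for _ in range(3)])
        curve = imsd(traj)
        np.testing.assert_allclose(curve.values, curve.values[::-1], rtol=1e-10)

    def test_tau_axis_uses_beta_hbar_over_p(self, rng):
        cfg = SystemConfig(
            n_beads=4, timestep=1.0, length_unit="bohr",
            inverse_temperature=8.0, hbar=2.0,
        )
        from ringtop import RingPolymerFrame

        traj = Trajectory(
            config=cfg,
            frames={0: [RingPolymerFrame(0, "A", 0, np.zeros((4, 3)))]},
        )
        curve = imsd(traj)
        np.testing.assert_allclose(curve.taus, np.arange(5) * 8.0 * 2.0 / 4)

    def test_empty_subset_rejected(self, rng):
        traj = _single_atom_traj([rng.normal(size=(4, 3))])
        with pytest.raises(ValueError):
            imsd(traj, atom_subset=[])


class TestDistanceDistributions:
    def test_two_beads_single_pair(self, make_frame):
        dist = distance_distributions(
            [make_frame([[0, 0, 0], [1.1, 0, 0]])], "bead_bead_pairwise"
        )
        np.testing.assert_allclose(dist.samples, [1.1])

    def test_equilateral_triangle(self, make_frame):
        s = 0.9
        frame = make_frame([[0, 0, 0], [s, 0, 0], [s / 2, s * np.sqrt(3) / 2, 0]])
        dist = distance_distributions([frame], "bead_bead_pairwise")
        np.testing.assert_allclose(dist.samples, [s] * 3)

    def test_pair_count_is_p_choose_2(self, rng, make_frame):
        p = 9
        dist = distance_distributions(
            [make_frame(rng.normal(size=(p, 3)))], "bead_bead_pairwise"
        )
        assert dist.samples.size == p * (p - 1) // 2
        assert dist.counts.sum() == dist.samples.size

    def test_centroid_kind_count(self, rng, make_frame):
        dist = distance_distributions(
            [make_frame(rng.normal(size=(6, 3)))] * 2, "centroid_bead"
        )
        assert dist.samples.size == 12

    def test_unknown_kind_rejected(self, make_frame):
        with pytest.raises(ValueError, match="kind"):
            distance_distributions([make_frame(np.zeros((2, 3)))], "nope")


class TestWelchTTest:
    def test_identical_samples_p_one(self):
        x = np.array([1.0, 1.0, 1.0])
        res = welch_t_test(x, x)
        assert res.pvalue == 1.0

    def test_separated_normals_tiny_p(self, rng):
        a = rng.normal(0.0, 1.0, 100)
        b = rng.normal(5.0, 1.0, 100)
        assert welch_t_test(a, b).pvalue < 1e-6

    def test_antisymmetric_statistic(self, rng):
        a, b = rng.normal(0, 1, 40), rng.normal(0.5, 2, 60)
        assert welch_t_test(a, b).statistic == pytest.approx(
            -welch_t_test(b, a).statistic
        )


class TestEnsembleRg:
    def test_spread_scaling_is_linear(self, ring_sampler):
        """Mean R_g of the free-ring sampler is proportional to the spread."""
        import numpy as np

        scales = np.array([0.05, 0.1, 0.2, 0.4])
        means = []
        for s in scales:
            frames = ring_sampler(spread=s, n=400)
            means.append(np.mean([gyration_radius(f) for f in frames]))
        slope = np.polyfit(scales, means, 1)[0]
        assert slope == pytest.approx(1.0, rel=0.05)

    def test_pooled_rms_vs_mean_methods_close(self, small_trajectory):
        rms = ensemble_rg(small_trajectory, method="pooled_rms")
        mean = ensemble_rg(small_trajectory, method="mean")
        assert rms > 0 and mean > 0
        assert rms >= mean  # RMS dominates the mean
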