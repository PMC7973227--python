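"""VR barcodes against the brute-force rank oracle; Betti sequences and
distributions."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from oracles import oracle_vr_barcode
from ringtop import (
    Barcode,
    betti_distribution,
    betti_sequence,
    dataset_b1,
    make_toy_cloud,
    trajectory_betti_distributions,
    vr_barcode,
)
from ringtop.persistence import barcode_from_json, barcode_to_json
import ringtop.persistence as ph


class TestVRBarcode:
    def test_unit_square_single_loop(self):
        bc = vr_barcode(make_toy_cloud("unit_square"))
        np.testing.assert_allclose(bc.bars, [[0.5, np.sqrt(2) / 2]], atol=1e-12)
        assert not bc.truncated.any()

    def test_hexagon_loop(self):
        bc = vr_barcode(make_toy_cloud("hexagon_side1"))
        np.testing.assert_allclose(bc.bars, [[0.5, np.sqrt(3) / 2]], atol=1e-12)

    def test_collinear_no_loops(self):
        assert vr_barcode(make_toy_cloud("collinear_7")).n_bars == 0

    def test_figure_eight_two_loops(self):
        assert vr_barcode(make_toy_cloud("figure_eight")).n_bars == 2

    def test_beta0_at_zero_counts_points(self, rng):
        pts = rng.random((6, 3))
        bc = vr_barcode(pts, dimension=0)
        assert bc.n_bars == 6
        assert np.isinf(bc.bars[:, 1]).sum() == 1  # one essential component

    def test_matches_rank_oracle_on_random_clouds(self, rng):
        for _ in range(30):
            n = int(rng.integers(3, 9))
            pts = rng.random((n, 3))
            got = vr_barcode(pts).bars
            want = oracle_vr_barcode(pts)
            assert got.shape == want.shape
            np.testing.assert_allclose(got, want, atol=1e-9)

    def test_python_and_accelerated_reduction_agree(self, rng):
        for n in (6, 12, 18):
            pts = rng.random((n, 3))
            fast = vr_barcode(pts)
            saved = ph._reduce_boundary
            ph._reduce_boundary = ph._reduce_python
            try:
                ref = vr_barcode(pts)
            finally:
                ph._reduce_boundary = saved
            np.testing.assert_allclose(fast.bars, ref.bars, atol=0)

    def test_rigid_motion_invariance(self, rng):
        pts = rng.random((10, 3))
        rot = Rotation.random(random_state=3).as_matrix()
        moved = pts @ rot.T + np.array([2.0, -1.0, 0.5])
        np.testing.assert_allclose(
            vr_barcode(pts).bars, vr_barcode(moved).bars, atol=1e-9
        )

    @staticmethod
    def _bottleneck_within(bars0, bars1, eps):
        """True iff the bottleneck distance between two barcodes is <= eps
        (perfect matching in the bipartite graph that allows diagonal
        matches for low-persistence bars)."""
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import maximum_bipartite_matching

        n0, n1 = len(bars0), len(bars1)
        size = n0 + n1
        adj = np.zeros((size, size), dtype=bool)
        for i in range(n0):
            for j in range(n1):
                adj[i, j] = np.max(np.abs(bars0[i] - bars1[j])) <= eps
            adj[i, n1 + i] = (bars0[i, 1] - bars0[i, 0]) / 2 <= eps
        for j in range(n1):
            adj[n0 + j, j] = (bars1[j, 1] - bars1[j, 0]) / 2 <= eps
        adj[n0:, n1:] = True
        match = maximum_bipartite_matching(csr_matrix(adj), perm_type="column")
        return int((match >= 0).sum()) == size

    def test_stability_under_small_perturbation(self, rng):
        """An epsilon perturbation of every point moves the barcode by at
        most epsilon in the bottleneck sense."""
        eps = 1e-3
        for _ in range(5):
            pts = rng.random((8, 3))
            bars0 = vr_barcode(pts).bars
            noise = rng.uniform(-1, 1, size=pts.shape)
            noise *= eps / np.linalg.norm(noise, axis=1, keepdims=True)
            bars1 = vr_barcode(pts + noise).bars
            assert self._bottleneck_within(bars0, bars1, eps + 1e-12)

    def test_dense_circle_has_unit_betti_interval(self):
        seq = betti_sequence(vr_barcode(make_toy_cloud("circle_40")), 1.0, 400)
        assert (seq.values == 1).any()

    def test_truncation_flag_when_loop_outlives_rmax(self):
        bc = vr_barcode(make_toy_cloud("unit_square"), max_radius=0.6)
        assert bc.n_bars == 1
        assert bc.truncated[0]
        assert bc.bars[0, 1] == 0.6

    def test_duplicate_points_deduplicated_with_warning(self):
        pts = np.vstack([make_toy_cloud("unit_square"), [[0.0, 0.0, 0.0]]])
        with pytest.warns(UserWarning, match="dedup"):
            bc = vr_barcode(pts)
        assert bc.n_bars == 1


class TestBettiSequence:
    def test_empty_barcode_all_zero(self):
        bc = Barcode(1, np.empty((0, 2)), np.empty(0, dtype=bool), 1.0)
        seq = betti_sequence(bc, 1.0, 5)
        np.testing.assert_array_equal(seq.values, np.zeros(5, dtype=int))

    def test_single_bar_half_open_membership(self):
        bc = Barcode(1, np.array([[0.25, 0.75]]), np.array([False]), 1.0)
        seq = betti_sequence(bc, 1.0, 5)
        np.testing.assert_array_equal(seq.values, [0, 1, 1, 0, 0])

    def test_overlapping_bars_add(self):
        bars = np.array([[0.2, 0.8], [0.4, 0.6]])
        bc = Barcode(1, bars, np.array([False, False]), 1.0)
        seq = betti_sequence(bc, 1.0, 11)
        assert seq.values.max() == 2
        np.testing.assert_array_equal(
            seq.values, [0, 0, 1, 1, 2, 2, 1, 1, 0, 0, 0]
        )

    def test_warns_when_bar_outlives_grid(self):
        bc = Barcode(1, np.array([[0.1, 1.5]]), np.array([False]), 2.0)
        with pytest.warns(UserWarning, match="outlive"):
            betti_sequence(bc, 1.0, 10)


class TestBettiDistribution:
    def test_counting_example(self):
        bc = Barcode(1, np.array([[0.25, 0.75]]), np.array([False]), 1.0)
        seq = betti_sequence(bc, 1.0, 5)
        dist = betti_distribution(seq, b1=3)
        np.testing.assert_allclose(dist.probabilities, [0.6, 0.4, 0.0, 0.0])

    def test_all_zero_sequence(self):
        bc = Barcode(1, np.empty((0, 2)), np.empty(0, dtype=bool), 1.0)
        dist = betti_distribution(betti_sequence(bc, 1.0, 8), b1=2)
        np.testing.assert_allclose(dist.probabilities, [1.0, 0.0, 0.0])

    def test_normalization_on_random_barcodes(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 6))
            births = rng.uniform(0, 0.5, n)
            deaths = births + rng.uniform(0.01, 0.5, n)
            bc = Barcode(1, np.column_stack([births, deaths]),
                         np.zeros(n, dtype=bool), 1.0)
            seq = betti_sequence(bc, 1.0, 50)
            dist = betti_distribution(seq, b1=int(seq.values.max()))
            assert dist.probabilities.sum() == pytest.approx(1.0, abs=1e-12)

    def test_undersized_b1_rejected(self):
        bc = Barcode(1, np.array([[0.1, 0.9], [0.2, 0.8]]),
                     np.array([False, False]), 1.0)
        seq = betti_sequence(bc, 1.0, 10)
        with pytest.raises(ValueError, match="B1"):
            betti_distribution(seq, b1=1)


class TestDatasetB1:
    def _traj(self, clouds):
        from ringtop import RingPolymerFrame, SystemConfig, Trajectory

        cfg = SystemConfig(n_beads=len(clouds[0][0]), timestep=1.0,
                           length_unit="angstrom")
        frames = {
            a: [RingPolymerFrame(a, "A", t, np.asarray(c))
                for t, c in enumerate(atom_clouds)]
            for a, atom_clouds in enumerate(clouds)
        }
        return Trajectory(config=cfg, frames=frames)

    def test_loop_free_dataset_zero(self):
        line = make_toy_cloud("collinear_4")
        traj = self._traj([[line, line + 0.1]])
        assert dataset_b1(traj, 1.0, 50) == 0

    def test_square_plus_line_gives_one(self):
        sq = make_toy_cloud("unit_square")
        line = make_toy_cloud("collinear_4")
        traj = self._traj([[sq, line]])
        assert dataset_b1(traj, 1.0, 200) == 1

    def test_monotone_in_appended_frames(self):
        sq = make_toy_cloud("unit_square")
        line = make_toy_cloud("collinear_4")
        b_small = dataset_b1(self._traj([[line, line]]), 1.0, 200)
        b_large = dataset_b1(self._traj([[line, sq]]), 1.0, 200)
        assert b_large >= b_small

    def test_distribution_rows_share_common_length(self):
        sq = make_toy_cloud("unit_square")
        line = make_toy_cloud("collinear_4")
        dists, b1 = trajectory_betti_distributions(self._traj([[sq, line]]),
                                                   1.0, 100)
        assert b1 == 1
        assert dists[0].shape == (2, 2)
        np.testing.assert_allclose(dists[0].sum(axis=1), 1.0, atol=1e-12)


class TestBarcodeJSON:
    def test_round_trip_with_infinite_death(self, rng):
        bc = vr_barcode(rng.random((5, 3)), dimension=0)
        back = barcode_from_json(barcode_to_json(bc))
        np.testing.assert_allclose(back.bars, bc.bars)
        np.testing.assert_array_equal(back.truncated, bc.truncated)
        assert back.dimension == 0
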