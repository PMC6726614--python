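"""Bisector arrangement, distance ranking and pivot generation."""

import numpy as np
import pytest

from spatialmhg import (Bisector, DegenerateTupleError, LabeledCloud,
                        build_bisectors, default_epsilon,
                        enumerate_sample_pivots, rank_by_distance,
                        sample_pivot_from_tuple, score_pivot)
from spatialmhg.controls import bead_control

from conftest import random_cloud


def lam_matrix(cloud, pivots):
    d = np.linalg.norm(cloud.coords[None] - np.atleast_2d(pivots)[:, None], axis=2)
    return cloud.labels[np.argsort(d, axis=1, kind="stable")]


class TestBuildBisectors:
    def test_count_is_b_times_n_minus_b(self):
        cloud = random_cloud(7, n=8, d=2)
        cloud.labels[:] = [1, 1, 1, 1, 0, 0, 0, 0]
        bis = build_bisectors(cloud)
        assert len(bis) == 16  # B(N-B) for the 8-point, 4-positive instance

    def test_all_same_label_yields_empty(self):
        cloud = LabeledCloud(np.random.default_rng(0).uniform(0, 1, (5, 2)),
                             np.zeros(5, int))
        assert len(build_bisectors(cloud)) == 0

    def test_axis_aligned_plane(self):
        cloud = LabeledCloud(np.array([[0.0, 0, 0], [2, 0, 0]]), [1, 0])
        b = build_bisectors(cloud)[0]
        a, bb, c, d = b.coeffs
        # plane x = 1 (up to normal orientation), unit normal
        assert np.hypot(bb, c) == pytest.approx(0, abs=1e-12)
        assert d / a == pytest.approx(-1.0)
        assert abs(a) == pytest.approx(1.0)

    def test_plane_equidistant_and_normal_parallel(self):
        cloud = random_cloud(3, n=10, d=3)
        for b in build_bisectors(cloud):
            xp, xn = cloud.coords[b.pos_idx], cloud.coords[b.neg_idx]
            mid = 0.5 * (xp + xn)
            assert b.normal @ mid + b.offset == pytest.approx(0, abs=1e-9)
            cross = np.cross(b.normal, xp - xn)
            assert np.linalg.norm(cross) == pytest.approx(0, abs=1e-9)

    def test_coincident_pair_skipped_with_warning(self):
        coords = np.array([[0.0, 0], [0.0, 0], [1, 1]])
        cloud = LabeledCloud(coords, [1, 0, 0])
        with pytest.warns(UserWarning, match="coincident"):
            bis = build_bisectors(cloud)
        assert len(bis) == 1


class TestRankByDistance:
    def test_simple_ordering(self):
        cloud = LabeledCloud(np.array([[1.0, 0, 0], [2, 0, 0], [3, 0, 0]]),
                             [1, 0, 1])
        lam, order = rank_by_distance([0, 0, 0], cloud)
        assert lam.tolist() == [1, 0, 1]
        assert order.tolist() == [0, 1, 2]

    def test_pivot_on_data_point_ranks_it_first(self):
        cloud = random_cloud(11, n=9, d=3)
        lam, order = rank_by_distance(cloud.coords[4], cloud)
        assert order[0] == 4

    def test_matches_independent_sort(self, rng):
        cloud = random_cloud(13, n=20, d=3)
        pivot = rng.uniform(0, 10, 3)
        dist = [float(np.linalg.norm(c - pivot)) for c in cloud.coords]
        expect = [cloud.labels[i] for i in sorted(range(20), key=lambda i: dist[i])]
        lam, _ = rank_by_distance(pivot, cloud)
        assert lam.tolist() == expect


class TestScorePivot:
    def test_two_cluster_construct_beats_every_bead(self, two_row_construct):
        """An off-genome pivot midway between the two positive clusters is
        strictly more significant than any pivot placed on a bin."""
        mid = np.array([0.5, 1.5])
        ps = score_pivot(mid, two_row_construct)
        bead = bead_control(two_row_construct)
        assert ps.result.score < bead.score

    def test_no_positives_scores_one(self):
        cloud = LabeledCloud(np.random.default_rng(1).uniform(0, 1, (6, 2)),
                             np.zeros(6, int))
        assert score_pivot([0, 0], cloud).result.score == 1.0

    def test_far_pivot_equals_projection_ranking(self, rng):
        cloud = random_cloud(17, n=12, d=3)
        u = np.array([1.0, 2.0, -0.5])
        u /= np.linalg.norm(u)
        lam, _ = rank_by_distance(1e8 * u, cloud)
        proj = np.argsort(-cloud.coords @ u, kind="stable")
        assert lam.tolist() == cloud.labels[proj].tolist()

    def test_radius_counts_threshold_points(self):
        cloud = random_cloud(19, n=10, d=2)
        ps = score_pivot([5.0, 5.0], cloud)
        dist = np.linalg.norm(cloud.coords - ps.pivot, axis=1)
        assert int((dist <= ps.radius + 1e-12).sum()) >= ps.result.threshold_n


class TestSamplePivots:
    def test_orthogonal_planes(self):
        planes = [Bisector((1.0, 0.0, 0.0, 0.0), 0, 1),
                  Bisector((0.0, 1.0, 0.0, 0.0), 0, 1),
                  Bisector((0.0, 0.0, 1.0, 0.0), 0, 1)]
        p = sample_pivot_from_tuple(planes, 0.01)
        assert np.linalg.norm(p) < 0.05          # within O(eps) of the origin
        assert np.all(np.abs(p) > 1e-12)         # strictly off all three

    def test_parallel_planes_degenerate(self):
        planes = [Bisector((1.0, 0.0, 0.0, 0.0), 0, 1),
                  Bisector((1.0, 0.0, 0.0, -1.0), 0, 1),
                  Bisector((0.0, 0.0, 1.0, 0.0), 0, 1)]
        with pytest.raises(DegenerateTupleError):
            sample_pivot_from_tuple(planes, 0.01)

    @pytest.mark.parametrize("seed", [2, 5, 8])
    def test_lambda_invariant_under_eps_shrink(self, seed):
        """Sampled pivots sit strictly inside cells: shrinking eps by 10x and
        100x leaves every induced ranking unchanged."""
        cloud = random_cloud(seed, d=2)
        eps = default_epsilon(cloud)
        lam = [lam_matrix(cloud, enumerate_sample_pivots(cloud, eps=e))
               for e in (eps, eps / 10, eps / 100)]
        assert (lam[0] == lam[1]).all() and (lam[0] == lam[2]).all()

    def test_counts(self):
        cloud = random_cloud(7, n=8, d=2)
        cloud.labels[:] = [1, 1, 1, 1, 0, 0, 0, 0]
        assert enumerate_sample_pivots(cloud).shape[0] == 120  # C(16,2)
        cloud3 = LabeledCloud(np.random.default_rng(4).uniform(0, 10, (8, 3)),
                              cloud.labels)
        assert enumerate_sample_pivots(cloud3).shape[0] == 560  # C(16,3)

    def test_single_pair_in_3d_yields_no_pivots(self):
        cloud = LabeledCloud(np.array([[0.0, 0, 0], [1, 1, 1]]), [1, 0])
        assert enumerate_sample_pivots(cloud).shape[0] == 0

    def test_subsampling_is_seeded_and_bounded(self):
        cloud = random_cloud(23, n=10, d=2)
        p1 = enumerate_sample_pivots(cloud, max_pivots=50, seed=1)
        p2 = enumerate_sample_pivots(cloud, max_pivots=50, seed=1)
        assert p1.shape[0] <= 50 and np.array_equal(p1, p2)

    @pytest.mark.parametrize("seed", [0, 4])
    def test_bounded_cell_rankings_are_covered(self, seed):
        """Every ranking realised by random pivots whose cell has a bottom
        vertex (finite downward extent) appears among the sampled + bead
        pivots.  Cells unbounded below have no bottom-most vertex and are
        structurally outside the sampler's reach."""
        cloud = random_cloud(seed, n=8, d=2)
        r = np.random.default_rng(seed + 100)
        lo, hi = cloud.bounding_box()
        rand = r.uniform(lo, hi, (20_000, 2))
        covered = {tuple(v) for v in lam_matrix(
            cloud, np.vstack([enumerate_sample_pivots(cloud), cloud.coords]))}
        down = rand + np.array([0.0, -1e7])
        lam_r = lam_matrix(cloud, rand)
        lam_d = lam_matrix(cloud, down)
        bounded = (lam_r != lam_d).any(axis=1)
        missing = {tuple(v) for v in lam_r[bounded]} - covered
        assert not missing
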