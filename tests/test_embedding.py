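"""Contact-map embedding: dissimilarities, NMDS, smoothing, alignment."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from spatialmhg import (ContactMap, DissimilarityMatrix, Embedding3D,
                        EmbeddingConfig, counts_to_dissimilarity,
                        detect_discontinuities, interpolate_outliers,
                        nmds_embed, procrustes_align, snmds)
from spatialmhg.synthetic import (SyntheticSpec, generate_contact_map,
                                  generate_polymer, inject_discontinuities)


def helix_embedding(n=60, pitch=0.3):
    t = np.linspace(0, 6 * np.pi, n)
    coords = np.c_[np.cos(t), np.sin(t), pitch * t]
    return Embedding3D(coords, np.array(["chr1"] * n, dtype=object),
                       np.arange(n))


def full_observed(values):
    obs = np.ones_like(values, dtype=bool) & ~np.eye(len(values), dtype=bool)
    return DissimilarityMatrix(values, obs)


class TestCountsToDissimilarity:
    @pytest.fixture
    def cmap(self):
        counts = np.array([[0, 0, 1.0], [0, 0, 3.0], [1.0, 3.0, 0]])
        bins = pd.DataFrame({"chrom": ["chr1"] * 3, "start": [0, 10, 20],
                             "end": [10, 20, 30]})
        return ContactMap(counts, bins, 10)

    def test_inverse_monotone_with_missing(self, cmap):
        D = counts_to_dissimilarity(cmap)
        assert not D.observed[0, 1]                  # zero count -> missing
        assert D.values[1, 2] < D.values[0, 2]       # higher count, closer
        assert D.values.min() >= 0 and np.diag(D.values).max() == 0

    def test_rank_transform_reverses_count_ranks(self, cmap):
        D = counts_to_dissimilarity(cmap, transform="rank")
        assert D.values[1, 2] < D.values[0, 2]

    def test_all_zero_map_errors(self):
        bins = pd.DataFrame({"chrom": ["chr1"] * 3, "start": [0, 1, 2],
                             "end": [1, 2, 3]})
        with pytest.raises(ValueError):
            counts_to_dissimilarity(ContactMap(np.zeros((3, 3)), bins, 1))

    def test_synthetic_map_correlates_with_true_distance(self):
        truth = generate_polymer(SyntheticSpec(n_chrom=1, bins_per_chrom=40,
                                               seed=2))
        cmap = generate_contact_map(truth, alpha=1.0, depth=5e5, seed=3)
        D = counts_to_dissimilarity(cmap)
        iu = np.triu_indices(40, 1)
        dt = np.linalg.norm(truth.coords[:, None] - truth.coords[None],
                            axis=2)[iu]
        mask = D.observed[iu]
        rho = spearmanr(D.values[iu][mask], dt[mask]).statistic
        assert rho > 0.7


class TestNmdsEmbed:
    def test_exact_line_recovery(self):
        x = np.arange(12, dtype=float)
        D = np.abs(x[:, None] - x[None, :]) / 11.0
        emb = nmds_embed(full_observed(D), EmbeddingConfig(seed=0))
        assert emb.stress < 1e-3
        proj = emb.coords @ np.linalg.svd(
            emb.coords - emb.coords.mean(0))[2][0]
        order = np.argsort(proj)
        assert (order == np.arange(12)).all() or \
            (order == np.arange(12)[::-1]).all()

    def test_recovers_known_configuration(self):
        r = np.random.default_rng(4)
        X = r.standard_normal((25, 3))
        D = np.linalg.norm(X[:, None] - X[None], axis=2)
        emb = nmds_embed(full_observed(D / D.max()), EmbeddingConfig(seed=1))
        ref = Embedding3D(X, np.array(["chr1"] * 25, dtype=object),
                          np.arange(25))
        _, disparity = procrustes_align(ref, emb)
        assert disparity < 0.05

    def test_agrees_with_reference_nmds(self):
        """Cross-check against sklearn's nonmetric SMACOF on a fully observed
        dissimilarity matrix (where both solve the same problem)."""
        from sklearn.manifold import MDS
        r = np.random.default_rng(11)
        X = r.standard_normal((20, 3))
        D = np.linalg.norm(X[:, None] - X[None], axis=2)
        ours = nmds_embed(full_observed(D), EmbeddingConfig(seed=0))
        theirs = MDS(n_components=3, metric=False, dissimilarity="precomputed",
                     random_state=0, n_init=4, max_iter=300,
                     normalized_stress=True).fit(D)
        d_ours = np.linalg.norm(ours.coords[:, None] - ours.coords[None],
                                axis=2)
        d_theirs = np.linalg.norm(theirs.embedding_[:, None] -
                                  theirs.embedding_[None], axis=2)
        iu = np.triu_indices(20, 1)
        assert spearmanr(d_ours[iu], d_theirs[iu]).statistic > 0.95

    def test_too_few_bins(self):
        D = full_observed(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            nmds_embed(D)

    def test_deterministic_given_seed(self):
        r = np.random.default_rng(6)
        D = np.abs(r.standard_normal((10, 10)))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        a = nmds_embed(full_observed(D), EmbeddingConfig(seed=5))
        b = nmds_embed(full_observed(D), EmbeddingConfig(seed=5))
        assert np.array_equal(a.coords, b.coords)


class TestDiscontinuities:
    def test_smooth_helix_has_none(self):
        assert detect_discontinuities(helix_embedding(), 3.0) == []

    def test_teleported_bin_flagged(self):
        emb = helix_embedding()
        emb.coords[30] += np.array([40.0, 0, 0])
        flagged = detect_discontinuities(emb, 3.0)
        assert 30 in flagged

    def test_uniform_line_zero_variance(self):
        coords = np.c_[np.arange(20.0), np.zeros(20), np.zeros(20)]
        emb = Embedding3D(coords, np.array(["chr1"] * 20, dtype=object),
                          np.arange(20))
        assert detect_discontinuities(emb, 3.0) == []

    def test_interpolation_midpoint(self):
        coords = np.array([[0.0, 0, 0], [50, 50, 50], [2, 0, 0], [3, 0, 0]])
        emb = Embedding3D(coords, np.array(["chr1"] * 4, dtype=object),
                          np.arange(4))
        fixed = interpolate_outliers(emb, [1])
        assert fixed.coords[1] == pytest.approx([1.0, 0, 0])

    def test_interpolation_identity_without_outliers(self):
        emb = helix_embedding()
        assert np.array_equal(interpolate_outliers(emb, []).coords, emb.coords)

    def test_run_of_two_evenly_spaced(self):
        coords = np.c_[np.arange(6.0), np.zeros(6), np.zeros(6)]
        coords[2] = [90, 9, 9]
        coords[3] = [-40, 4, 4]
        emb = Embedding3D(coords, np.array(["chr1"] * 6, dtype=object),
                          np.arange(6))
        fixed = interpolate_outliers(emb, [2, 3])
        assert fixed.coords[2] == pytest.approx([2.0, 0, 0])
        assert fixed.coords[3] == pytest.approx([3.0, 0, 0])

    def test_terminal_outlier_extrapolated(self):
        coords = np.c_[np.arange(5.0), np.zeros(5), np.zeros(5)]
        coords[0] = [99, 0, 0]
        emb = Embedding3D(coords, np.array(["chr1"] * 5, dtype=object),
                          np.arange(5))
        fixed = interpolate_outliers(emb, [0])
        assert fixed.coords[0] == pytest.approx([0.0, 0, 0])


class TestSnmds:
    def test_corrupted_map_round_trip(self):
        spec = SyntheticSpec(n_chrom=2, bins_per_chrom=40, seed=3)
        truth = generate_polymer(spec)
        corrupt, _ = inject_discontinuities(truth, 3, magnitude=12.0, seed=4)
        assert len(detect_discontinuities(corrupt, 3.0)) > 0
        cmap = generate_contact_map(corrupt, alpha=1.0, depth=8e5, seed=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            emb = snmds(cmap, EmbeddingConfig(seed=0, nmds_max_iter=150))
        assert detect_discontinuities(emb, 3.0) == []

    def test_smooth_map_unchanged_by_smoothing(self):
        truth = generate_polymer(SyntheticSpec(n_chrom=1, bins_per_chrom=30,
                                               seed=9))
        cmap = generate_contact_map(truth, alpha=1.0, depth=8e5, seed=10)
        cfg = EmbeddingConfig(seed=0, nmds_max_iter=150)
        D = counts_to_dissimilarity(cmap)
        plain = nmds_embed(D, cfg, chrom=truth.chrom, bin_index=truth.bin_index)
        if detect_discontinuities(plain, cfg.smooth_z_threshold) == []:
            smoothed = snmds(cmap, cfg)
            assert np.array_equal(smoothed.coords, plain.coords)


class TestProcrustes:
    def test_rotated_copy_zero_disparity(self):
        r = np.random.default_rng(0)
        X = r.standard_normal((20, 3))
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        meta = (np.array(["chr1"] * 20, dtype=object), np.arange(20))
        e1 = Embedding3D(X, *meta)
        e2 = Embedding3D(2.0 * X @ R.T + 5.0, *meta)
        aligned, disp = procrustes_align(e1, e2)
        assert disp == pytest.approx(0, abs=1e-12)
        assert aligned.coords == pytest.approx(X)

    def test_disparity_grows_with_noise(self):
        r = np.random.default_rng(1)
        X = r.standard_normal((30, 3))
        meta = (np.array(["chr1"] * 30, dtype=object), np.arange(30))
        ref = Embedding3D(X, *meta)
        disps = [procrustes_align(
            ref, Embedding3D(X + s * r.standard_normal(X.shape), *meta))[1]
            for s in (0.01, 0.1, 0.5)]
        assert disps[0] < disps[1] < disps[2]

    def test_reflection_control(self):
        r = np.random.default_rng(2)
        X = r.standard_normal((15, 3))
        mirrored = X * np.array([-1.0, 1.0, 1.0])
        meta = (np.array(["chr1"] * 15, dtype=object), np.arange(15))
        _, d_with = procrustes_align(Embedding3D(X, *meta),
                                     Embedding3D(mirrored, *meta),
                                     allow_reflection=True)
        _, d_without = procrustes_align(Embedding3D(X, *meta),
                                        Embedding3D(mirrored, *meta),
                                        allow_reflection=False)
        assert d_with == pytest.approx(0, abs=1e-12)
        assert d_without > d_with

    def test_mismatched_bins_error(self):
        meta = (np.array(["chr1"] * 5, dtype=object), np.arange(5))
        e1 = Embedding3D(np.zeros((5, 3)), *meta)
        e2 = Embedding3D(np.zeros((6, 3)), np.array(["chr1"] * 6, dtype=object),
                         np.arange(6))
        with pytest.raises(ValueError):
            procrustes_align(e1, e2)
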