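"""PCA+CVA pattern model, split-half resampling and consensus patterns."""

import numpy as np
import pytest

from sonoquant import (
    ParameterError,
    SampleSizeError,
    ScanMatrix,
    consensus_pattern,
    fit_pca_cva,
    make_pattern_dataset,
    split_half,
)
from tests.oracles import fisher_lda_two_class


def corr(a, b):
    a = a - a.mean()
    b = b - b.mean()
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


class TestFitPcaCva:
    def test_planted_two_class_separation_is_found(self):
        # voxel count kept well below the scan count: top-PC alignment with
        # the planted direction degrades as voxels/scans grows
        scans, truth = make_pattern_dataset(20, 12, effect_size=5.0, n_classes=2, seed=0)
        model = fit_pca_cva(scans, q=2)
        assert np.mean(model.classify(scans.X) == scans.classes) == 1.0
        assert abs(corr(model.patterns[0], truth["pattern"])) > 0.95

    def test_three_classes_give_two_patterns_with_unit_within_variance(self):
        scans, _ = make_pattern_dataset(8, 60, effect_size=4.0, n_classes=3, seed=1)
        model = fit_pca_cva(scans, q=5)
        assert model.patterns.shape == (2, 60)
        # pooled within-class variance of each canonical variate is 1
        for j in range(2):
            ss = 0.0
            for c in model.class_labels:
                z = model.scores[scans.classes == c, j]
                ss += ((z - z.mean()) ** 2).sum()
            # ridge regularization perturbs the normalization at O(1e-5)
            assert ss / (scans.n_scans - len(model.class_labels)) == pytest.approx(
                1.0, rel=1e-4
            )

    def test_matches_generalized_eigenvalue_fisher_oracle(self):
        # q = rank, two classes: CVA projection equals classic Fisher LDA
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 50))
        y = np.repeat(["a", "b"], 15)
        X[y == "b"] += 0.8 * rng.normal(size=50) / np.sqrt(50)
        scans = ScanMatrix(X, subjects=np.arange(30).astype(str), classes=y)
        model = fit_pca_cva(scans, q=29, normalize=False)
        w_direct = fisher_lda_two_class(X - X.mean(axis=0), y)
        r = corr(model.patterns[0], w_direct)
        assert abs(r) > 1 - 1e-6

    def test_duplicated_scans_are_ridge_stabilized(self):
        base = np.random.default_rng(4).normal(size=(2, 20))
        X = np.vstack([base[0]] * 3 + [base[1]] * 3)
        scans = ScanMatrix(
            X, subjects=np.array(["s1", "s2", "s3", "s4", "s5", "s6"]),
            classes=np.array(["a"] * 3 + ["b"] * 3),
        )
        model = fit_pca_cva(scans, q=1, normalize=False)  # zero within-class scatter
        assert np.isfinite(model.patterns).all()
        assert np.mean(model.classify(X, normalized_input=True) == scans.classes) == 1.0

    def test_pattern_invariant_to_joint_orthogonal_rotation(self):
        scans, _ = make_pattern_dataset(6, 30, effect_size=3.0, n_classes=2, seed=5)
        q_mat, _ = np.linalg.qr(np.random.default_rng(6).normal(size=(30, 30)))
        rotated = ScanMatrix(scans.X @ q_mat, scans.subjects, scans.classes)
        m1 = fit_pca_cva(scans, q=3, normalize=False)
        m2 = fit_pca_cva(rotated, q=3, normalize=False)
        back = m2.patterns[0] @ q_mat.T
        assert abs(corr(m1.patterns[0], back)) > 1 - 1e-6

    def test_rank_and_class_size_guards(self):
        scans, _ = make_pattern_dataset(4, 10, 1.0, n_classes=2, seed=7)
        with pytest.raises(ParameterError):
            fit_pca_cva(scans, q=50)
        bad = ScanMatrix(
            np.random.default_rng(0).normal(size=(3, 5)) + 10,
            subjects=np.array(["a", "b", "c"]),
            classes=np.array(["x", "x", "y"]),
        )
        with pytest.raises(SampleSizeError):
            fit_pca_cva(bad, q=1)


class TestSplitHalf:
    def test_identical_subjects_reproduce_exactly(self):
        # every subject carries the same two scans, so both halves of any
        # split see identical data and must produce the identical pattern
        rng = np.random.default_rng(8)
        m0, m4 = rng.normal(size=(2, 40))
        X = np.vstack([[m0, m4]] * 6).reshape(12, 40) + 100.0
        scans = ScanMatrix(
            X,
            subjects=np.repeat([f"s{i}" for i in range(6)], 2),
            classes=np.tile(["M0", "M4"], 6),
        )
        metrics = split_half(scans, q=1, n_splits=5, seed=0)
        assert np.allclose(metrics.reproducibility, 1.0, atol=1e-9)

    def test_planted_effect_is_reproducible_and_predictive(self):
        scans, _ = make_pattern_dataset(20, 30, effect_size=5.0, n_classes=3, seed=9)
        metrics = split_half(scans, q=4, n_splits=20, seed=1)
        assert metrics.median_reproducibility >= 0.9
        assert metrics.median_prediction >= 0.95

    def test_null_labels_predict_at_chance(self):
        scans, _ = make_pattern_dataset(12, 120, effect_size=0.0, n_classes=3, seed=10)
        metrics = split_half(scans, q=4, n_splits=20, seed=2)
        assert abs(metrics.median_prediction - 1 / 3) < 0.15
        assert abs(metrics.median_reproducibility) < 0.15

    def test_seed_determinism_and_small_sample_guard(self):
        scans, _ = make_pattern_dataset(6, 30, effect_size=2.0, seed=11)
        a = split_half(scans, q=2, n_splits=6, seed=3)
        b = split_half(scans, q=2, n_splits=6, seed=3)
        assert np.array_equal(a.reproducibility, b.reproducibility)
        assert np.array_equal(a.prediction, b.prediction)
        tiny = ScanMatrix(
            np.random.default_rng(1).normal(size=(6, 10)) + 50,
            subjects=np.repeat(["a", "b", "c"], 2),
            classes=np.tile(["M0", "M4"], 3),
        )
        with pytest.raises(SampleSizeError):
            split_half(tiny, q=1)


class TestConsensus:
    def test_unanimous_splits_return_the_common_pattern(self):
        scans, _ = make_pattern_dataset(16, 120, effect_size=5.0, n_classes=3, seed=9)
        metrics = split_half(scans, q=4, n_splits=10, seed=4)
        consensus = consensus_pattern(metrics, scans=scans)
        assert np.linalg.norm(consensus.patterns[0]) == pytest.approx(1.0)
        # each split pattern correlates strongly with the consensus
        for ma, mb in metrics.models:
            assert abs(corr(consensus.patterns[0], ma.patterns[0])) > 0.9

    def test_sign_ambiguity_is_resolved(self):
        scans, truth = make_pattern_dataset(16, 120, effect_size=5.0, n_classes=3, seed=12)
        metrics = split_half(scans, q=4, n_splits=8, seed=5)
        # flip half the stored patterns: consensus must be unaffected up to sign
        ref = consensus_pattern(metrics, scans=scans).patterns[0]
        for i, (ma, mb) in enumerate(metrics.models):
            if i % 2 == 0:
                ma.patterns = -ma.patterns
        flipped = consensus_pattern(metrics, scans=scans).patterns[0]
        assert abs(corr(ref, flipped)) > 1 - 1e-9

    def test_consensus_tracks_truth_at_least_as_well_as_median_split(self):
        scans, truth = make_pattern_dataset(16, 120, effect_size=5.0, n_classes=3, seed=13)
        metrics = split_half(scans, q=4, n_splits=12, seed=6)
        consensus = consensus_pattern(metrics, scans=scans)
        split_corrs = [
            abs(corr(m.patterns[0], truth["pattern"]))
            for pair in metrics.models
            for m in pair
        ]
        assert abs(corr(consensus.patterns[0], truth["pattern"])) >= np.median(split_corrs) - 1e-6

    def test_all_nonpositive_reproducibility_warns_and_falls_back(self):
        scans, _ = make_pattern_dataset(8, 40, effect_size=0.0, n_classes=2, seed=14)
        metrics = split_half(scans, q=2, n_splits=4, seed=7)
        metrics.reproducibility = np.zeros_like(metrics.reproducibility)
        with pytest.warns(UserWarning, match="nonpositive"):
            consensus_pattern(metrics, scans=scans)

    def test_cv1_scores_separate_classes_on_planted_data(self):
        scans, _ = make_pattern_dataset(16, 120, effect_size=5.0, n_classes=3, seed=15)
        metrics = split_half(scans, q=4, n_splits=10, seed=8)
        consensus = consensus_pattern(metrics, scans=scans)
        cents = [consensus.centroids[c][0] for c in consensus.class_labels]
        assert np.all(np.diff(cents) > 0) or np.all(np.diff(cents) < 0)
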