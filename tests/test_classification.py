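"""Stratified folding, oversampling semantics, nested tuning, CV pipeline."""

import numpy as np
import pytest

import neurodyad as nd
from neurodyad import classification as clf


def imbalanced_labels():
    """The emulated study's category counts: 63 / 286 / 412 / 100."""
    return np.repeat([1, 2, 3, 4], [63, 286, 412, 100])


class TestStratifiedFolds:
    def test_study_scale_fold_sizes(self):
        y = imbalanced_labels()
        folds = nd.stratified_folds(y, 8, seed=0)
        sizes = np.bincount(folds)
        assert set(sizes) <= {107, 108}
        for f in range(8):
            assert np.sum((folds == f) & (y == 1)) in (7, 8)

    def test_folds_partition_everything(self):
        y = imbalanced_labels()
        folds = nd.stratified_folds(y, 8, seed=1)
        assert folds.min() == 0 and folds.max() == 7
        assert len(folds) == 861

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="category"):
            nd.stratified_folds(np.array([1, 1, 1, 2, 2, 2, 2, 2]), 4)


class TestOversampleTraining:
    def test_balanced_input_is_unchanged(self):
        x = np.arange(8).reshape(-1, 1).astype(float)
        y = np.repeat([0, 1], 4)
        xo, yo = nd.oversample_training(x, y, seed=0)
        assert sorted(xo.ravel()) == sorted(x.ravel())
        assert np.bincount(yo).tolist() == [4, 4]

    def test_minority_grown_by_full_passes(self):
        """Class sizes (2, 5): both minority examples appear at least twice and
        at most three times; final counts are equal."""
        x = np.array([[0.0], [1.0], [10.0], [11.0], [12.0], [13.0], [14.0]])
        y = np.array([0, 0, 1, 1, 1, 1, 1])
        xo, yo = nd.oversample_training(x, y, seed=3)
        assert np.bincount(yo).tolist() == [5, 5]
        counts = {v: int((xo.ravel() == v).sum()) for v in (0.0, 1.0)}
        assert sorted(counts.values()) == [2, 3]
        # every original example retained
        assert set(x.ravel()) <= set(xo.ravel())

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((30, 2))
        y = np.repeat([0, 1, 2], [4, 10, 16])
        a = nd.oversample_training(x, y, seed=9)
        b = nd.oversample_training(x, y, seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            nd.oversample_training(np.empty((0, 2)), np.empty(0, int))


class TestNestedGridSearch:
    def test_wide_margin_tie_breaks_to_smallest_c(self):
        rng = np.random.default_rng(1)
        x = np.vstack([rng.normal(-5, 0.1, (24, 2)), rng.normal(5, 0.1, (24, 2))])
        y = np.repeat([0, 1], 24)
        cfg = nd.ClassifierConfig(n_inner_folds=4, c_grid=(0.01, 1.0, 100.0))
        assert nd.nested_grid_search(x, y, cfg, seed=0) == 0.01

    def test_single_point_grid_returned_without_search(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((40, 3))
        y = np.repeat([0, 1], 20)
        cfg = nd.ClassifierConfig(n_inner_folds=4, c_grid=(7.5,))
        assert nd.nested_grid_search(x, y, cfg, seed=0) == 7.5

    def test_shuffled_labels_still_return_a_c(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((48, 4))
        y = rng.permutation(np.repeat([0, 1], 24))
        cfg = nd.ClassifierConfig(n_inner_folds=4, c_grid=(0.1, 10.0))
        assert nd.nested_grid_search(x, y, cfg, seed=0) in (0.1, 10.0)


@pytest.fixture
def small_cfg():
    return nd.ClassifierConfig(
        n_outer_folds=4, n_inner_folds=4, c_grid=(0.01, 1.0, 100.0),
        n_label_perms=10, seed=5,
    )


class TestCrossValidatedPredict:
    def test_perfect_features_classify_perfectly(self, small_cfg):
        rng = np.random.default_rng(4)
        y = np.repeat([1, 2, 3, 4], 30)
        x = np.eye(4)[y - 1] + 0.01 * rng.standard_normal((120, 4))
        res = nd.cross_validated_predict(x, y, small_cfg)
        assert res.overall_accuracy == 1.0
        assert np.allclose(res.confusion, np.eye(4))

    def test_row_normalized_confusion(self, small_cfg):
        rng = np.random.default_rng(5)
        y = np.repeat([1, 2, 3, 4], 30)
        x = rng.standard_normal((120, 6))
        res = nd.cross_validated_predict(x, y, small_cfg)
        assert np.allclose(res.confusion.sum(axis=1), 1.0, atol=1e-9)

    def test_bitwise_deterministic(self, small_cfg):
        rng = np.random.default_rng(6)
        y = np.repeat([1, 2, 3, 4], 25)
        x = rng.standard_normal((100, 5))
        a = nd.cross_validated_predict(x, y, small_cfg)
        b = nd.cross_validated_predict(x, y, small_cfg)
        assert np.array_equal(a.predictions, b.predictions)
        assert a.best_c_per_fold == b.best_c_per_fold

    def test_non_finite_features_rejected(self, small_cfg):
        x = np.full((120, 3), np.nan)
        y = np.repeat([1, 2, 3, 4], 30)
        with pytest.raises(ValueError, match="finite"):
            nd.cross_validated_predict(x, y, small_cfg)

    def test_no_leakage_between_test_fold_and_training(self, small_cfg, monkeypatch):
        """No held-out row is ever seen at fit time for its own fold."""
        rng = np.random.default_rng(7)
        y = np.repeat([1, 2, 3, 4], 30)
        x = rng.standard_normal((120, 4))
        row_key = {tuple(np.round(row, 12)): i for i, row in enumerate(x)}
        seen_at_fit: list[set] = []

        real_make = clf._make_estimator

        def recording_make(c, scheme):
            est = real_make(c, scheme)
            orig_fit = est.fit

            def fit(xx, yy):
                seen = {row_key[tuple(np.round(r, 12))] for r in xx
                        if tuple(np.round(r, 12)) in row_key}
                seen_at_fit.append(seen)
                return orig_fit(xx, yy)

            est.fit = fit
            return est

        monkeypatch.setattr(clf, "_make_estimator", recording_make)
        res = nd.cross_validated_predict(x, y, small_cfg)
        folds = res.fold_assignment
        train_sets = [
            set(np.nonzero(folds != f)[0]) for f in range(small_cfg.n_outer_folds)
        ]
        assert seen_at_fit, "recorder never saw a fit"
        # every fit (inner or outer) must stay inside some fold's training rows,
        # i.e. exclude that fold's entire held-out set
        for seen in seen_at_fit:
            assert any(seen <= tr for tr in train_sets), (
                "a fit used rows spanning every fold's held-out set"
            )


class TestLabelPermutationTest:
    def test_perfect_features_give_minimal_p(self, small_cfg):
        rng = np.random.default_rng(8)
        y = np.repeat([1, 2, 3, 4], 30)
        x = np.eye(4)[y - 1] + 0.01 * rng.standard_normal((120, 4))
        res = nd.label_permutation_test(x, y, small_cfg)
        assert res.p == pytest.approx(1 / (small_cfg.n_label_perms + 1))
        assert res.permutation_null.max() < 1.0

    def test_null_centered_near_chance(self, small_cfg):
        rng = np.random.default_rng(9)
        y = np.repeat([1, 2, 3, 4], 30)
        x = rng.standard_normal((120, 5))
        res = nd.label_permutation_test(x, y, small_cfg)
        assert abs(res.permutation_null.mean() - 0.25) < 0.08

    def test_invalid_n_perm_rejected(self):
        cfg = nd.ClassifierConfig(n_label_perms=0)
        with pytest.raises(ValueError, match="n_label_perms"):
            nd.label_permutation_test(np.zeros((40, 2)), np.repeat([1, 2], 20), cfg)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "bad",
        [
            {"n_outer_folds": 1},
            {"c_grid": (1.0, 0.1)},
            {"c_grid": (-1.0, 1.0)},
            {"multiclass_scheme": "softmax"},
        ],
    )
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            nd.ClassifierConfig(**bad)
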