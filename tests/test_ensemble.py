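"""Stacked ensemble: level-1 linear SVMs, cross-fitting, level-2 forest, TOO gating."""

import numpy as np
import pandas as pd
import pytest

from alphamark.ensemble import (
    StackedModel,
    TOOPrediction,
    cross_fit_level1,
    level1_scores,
    predict_detection,
    predict_too,
    train_level1,
    train_stacked,
)
from alphamark.evaluation import auroc
from alphamark.profiles import MARKER_TYPES


def blobs(n=40, d=10, sep=4.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    y = np.r_[np.zeros(n // 2, int), np.ones(n - n // 2, int)]
    X[y == 1, 0] += sep
    return X, y


class TestLevel1:
    def test_separable_blobs_fit_perfectly(self):
        X, y = blobs()
        model = train_level1(X, y)
        assert (model.predict(X) == y).mean() == 1.0

    def test_single_class_raises(self):
        X, _ = blobs()
        with pytest.raises(ValueError):
            train_level1(X, np.zeros(len(X)))

    def test_duplicated_samples_score_identically(self):
        X, y = blobs(seed=1)
        model = train_level1(X, y)
        s1 = model.decision_function(X)
        s2 = train_level1(np.vstack([X, X]), np.r_[y, y]).decision_function(X)
        # determinism of the fit itself
        s3 = train_level1(X, y).decision_function(X)
        np.testing.assert_array_equal(s1, s3)
        assert s2.shape == s1.shape

    def test_permuted_labels_give_chance_level_auroc(self):
        """Cross-validated AUROC under label permutation sits in the null band."""
        rng = np.random.default_rng(7)
        aurocs = []
        for rep in range(10):
            X = rng.normal(size=(60, 10))
            y = np.r_[np.zeros(30, int), np.ones(30, int)]
            rng.shuffle(y)
            oof = cross_fit_level1(X, y, k_folds=5, seed=rep)
            aurocs.append(auroc(oof[:, 0], y))
        assert 0.3 < np.mean(aurocs) < 0.7


class TestCrossFit:
    def test_leave_one_out_on_six_samples(self):
        X, y = blobs(n=6, d=3)
        oof = cross_fit_level1(X, y, k_folds=3, seed=0)
        assert oof.shape == (6, 1)

    def test_fold_reduction_warns(self):
        X, y = blobs(n=8)
        with pytest.warns(UserWarning, match="reducing folds"):
            cross_fit_level1(X, y, k_folds=10, seed=0)

    def test_fixed_seed_reproducible(self):
        X, y = blobs(n=30, seed=2)
        np.testing.assert_array_equal(
            cross_fit_level1(X, y, seed=5), cross_fit_level1(X, y, seed=5)
        )

    def test_oof_scores_less_optimistic_than_in_sample_on_noise(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(40, 200))   # overfit-prone: d >> n, pure noise
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        in_sample = train_level1(X, y).decision_function(X)
        oof = cross_fit_level1(X, y, k_folds=5, seed=0)[:, 0]
        assert auroc(in_sample, y) > 0.95       # memorized
        assert auroc(oof, y) < 0.8              # honest


class TestTOOPrediction:
    @pytest.mark.parametrize(
        "probs, confidence, called",
        [
            ((0.6, 0.2, 0.15, 0.05), 3.0, True),
            ((0.4, 0.3, 0.2, 0.1), 4 / 3, False),
            ((1.0, 0.0, 0.0, 0.0), np.inf, True),
            ((0.5, 0.5, 0.0, 0.0), 1.0, False),   # top-2 tie -> no call
        ],
    )
    def test_confidence_gate(self, probs, confidence, called):
        pred = TOOPrediction.from_probs(dict(zip("abcd", probs)))
        assert pred.confidence == pytest.approx(confidence)
        assert (pred.call is not None) == called
        if called:
            assert pred.call == pred.top_type

    def test_confidence_always_at_least_one(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = rng.dirichlet(np.ones(4))
            pred = TOOPrediction.from_probs(dict(zip("abcd", p)))
            assert pred.confidence >= 1.0
            assert sum(pred.probs.values()) == pytest.approx(1.0, abs=1e-9)


def _views(n, d, signal_views=(0,), sep=2.5, seed=0, n_classes=2):
    """Four profile views; listed views carry independent class signal."""
    rng = np.random.default_rng(seed)
    y = np.arange(n) % n_classes
    views = {}
    for i, t in enumerate(MARKER_TYPES):
        X = rng.normal(size=(n, d))
        if i in signal_views:
            X[:, 0] += sep * y
        df = pd.DataFrame(X, index=[f"s{j}" for j in range(n)])
        df.attrs["panel_hash"] = f"h{i}"
        views[t] = df
    return views, pd.Series(y, index=[f"s{j}" for j in range(n)])


class TestStacked:
    def test_determinism(self):
        views, y = _views(40, 5, seed=3)
        m1 = train_stacked(views, y, seed=7, n_trees=100)
        m2 = train_stacked(views, y, seed=7, n_trees=100)
        np.testing.assert_array_equal(predict_detection(m1, views), predict_detection(m2, views))

    def test_sample_mismatch_across_views_raises(self):
        views, y = _views(20, 4)
        views["cancer_hypo"] = views["cancer_hypo"].iloc[::-1]
        with pytest.raises(ValueError, match="identical samples"):
            train_stacked(views, y)

    def test_panel_hash_mismatch_raises(self):
        views, y = _views(30, 4)
        model = train_stacked(views, y, n_trees=50)
        bad = {t: v.copy() for t, v in views.items()}
        for t, v in bad.items():
            v.attrs["panel_hash"] = views[t].attrs["panel_hash"]
        bad["tissue_hypo"].attrs["panel_hash"] = "different"
        with pytest.raises(ValueError, match="panel hash"):
            predict_detection(model, bad)

    def test_stacked_tracks_the_informative_view(self):
        """Signal in one view only: stacking must not lose it."""
        train_views, y_train = _views(80, 6, signal_views=(2,), seed=11)
        test_views, y_test = _views(60, 6, signal_views=(2,), seed=12)
        for t in MARKER_TYPES:
            test_views[t].attrs["panel_hash"] = train_views[t].attrs["panel_hash"]
        model = train_stacked(train_views, y_train, seed=0, n_trees=300)
        stacked_auc = auroc(predict_detection(model, test_views), y_test)
        view_auc = auroc(level1_scores(model, test_views)["tissue_hyper"][:, 0], y_test)
        assert stacked_auc >= view_auc - 0.05

    def test_all_noise_views_stay_at_chance(self):
        aucs = []
        for rep in range(5):
            train_views, y_train = _views(60, 6, signal_views=(), seed=100 + rep)
            test_views, y_test = _views(60, 6, signal_views=(), seed=200 + rep)
            for t in MARKER_TYPES:
                test_views[t].attrs["panel_hash"] = train_views[t].attrs["panel_hash"]
            model = train_stacked(train_views, y_train, seed=rep, n_trees=100)
            aucs.append(auroc(predict_detection(model, test_views), y_test))
        assert 0.3 < np.mean(aucs) < 0.7

    def test_detection_scores_are_probabilities(self):
        views, y = _views(40, 5, seed=4)
        model = train_stacked(views, y, n_trees=50)
        rng = np.random.default_rng(0)
        rand_views = {
            t: pd.DataFrame(rng.normal(size=(200, 5)), index=[f"r{j}" for j in range(200)])
            for t in MARKER_TYPES
        }
        for t in MARKER_TYPES:
            rand_views[t].attrs["panel_hash"] = views[t].attrs["panel_hash"]
        scores = predict_detection(model, rand_views)
        assert np.all((scores >= 0) & (scores <= 1))

    def test_too_round_trip(self, tmp_path):
        views, y = _views(80, 6, signal_views=(0, 1), sep=4.0, n_classes=4, seed=5)
        labels = y.map(dict(enumerate(["colon", "liver", "lung", "stomach"])))
        model = train_stacked(views, labels, task="too", n_trees=100, seed=1)
        preds = predict_too(model, views)
        assert len(preds) == 80
        for p in preds:
            assert sum(p.probs.values()) == pytest.approx(1.0, abs=1e-9)
            assert (p.call is None) == (p.confidence < 2.5)
        path = tmp_path / "model.joblib"
        model.save(str(path))
        reloaded = StackedModel.load(str(path))
        assert [p.call for p in predict_too(reloaded, views)] == [p.call for p in preds]

    def test_detection_model_refuses_too_prediction(self):
        views, y = _views(30, 4)
        model = train_stacked(views, y, n_trees=50)
        with pytest.raises(ValueError):
            predict_too(model, views)
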