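"""Random-forest hard and fuzzy classification."""

import numpy as np
import pytest

from phenomap import (CLASS_CODES, UNLABELED, predict_coverage,
                      train_classifier)


def two_cluster_data(n=200, seed=0):
    """Two disjoint feature clusters: coverage 100% corn vs 100% soybean."""
    rng = np.random.default_rng(seed)
    X0 = rng.normal(0.0, 0.3, size=(n // 2, 5))
    X1 = rng.normal(5.0, 0.3, size=(n // 2, 5))
    X = np.vstack([X0, X1])
    cov = np.zeros((n, 3))
    cov[: n // 2, 0] = 100.0   # corn
    cov[n // 2:, 1] = 100.0    # soybean
    cov[:, 2] = 100.0 - cov[:, 0] - cov[:, 1]
    return X, cov


class TestTrain:
    def test_defaults_record_k_and_m(self):
        X, cov = two_cluster_data()
        model = train_classifier(X, cov, "fuzzy")
        assert model.k == 100 and model.m == 1
        for est in model.estimators.values():
            assert est.n_estimators == 100 and est.max_features == 1

    def test_determinism_given_seed(self):
        X, cov = two_cluster_data()
        p1 = predict_coverage(train_classifier(X, cov, "fuzzy", seed=42), X)
        p2 = predict_coverage(train_classifier(X, cov, "fuzzy", seed=42), X)
        np.testing.assert_array_equal(p1, p2)

    def test_separable_clusters_beat_centroid_oracle(self):
        """Fuzzy forests on disjoint clusters err < 5 percentage points,
        matching a nearest-centroid oracle on the same data."""
        X, cov = two_cluster_data(seed=1)
        rng = np.random.default_rng(2)
        X_test = np.vstack([rng.normal(0.0, 0.3, size=(50, 5)),
                            rng.normal(5.0, 0.3, size=(50, 5))])
        truth = np.zeros((3, 100))
        truth[0, :50] = 100.0
        truth[1, 50:] = 100.0
        # independent oracle: nearest centroid classifies the test set exactly
        c0, c1 = X[:100].mean(0), X[100:].mean(0)
        d0 = np.linalg.norm(X_test - c0, axis=1)
        d1 = np.linalg.norm(X_test - c1, axis=1)
        assert ((d1 < d0) == (np.arange(100) >= 50)).all()
        model = train_classifier(X, cov, "fuzzy", seed=0)
        pred = predict_coverage(model, X_test)
        assert np.abs(pred - truth).max() < 5.0

    def test_hard_mode_missing_class_error(self):
        X = np.random.default_rng(0).normal(size=(20, 3))
        y = np.full(20, CLASS_CODES["corn"], dtype=np.uint8)
        with pytest.raises(ValueError, match="soybean|other"):
            train_classifier(X, y, "hard")

    def test_fuzzy_targets_out_of_range_rejected(self):
        X, cov = two_cluster_data()
        cov[0, 0] = 150.0
        with pytest.raises(ValueError):
            train_classifier(X, cov, "fuzzy")


class TestPredict:
    def test_memorized_pure_pixel(self):
        X, cov = two_cluster_data(seed=3)
        model = train_classifier(X, cov, "fuzzy", seed=0)
        pred = predict_coverage(model, X[:1])
        assert pred[0, 0] >= 95.0

    def test_rescale_when_sum_exceeds_100(self):
        """Raw per-crop predictions 70 and 50 rescale to (58.33, 41.67)."""
        class Const:
            def __init__(self, v):
                self.v = v
            def predict(self, X):
                return np.full(len(X), self.v)

        from phenomap.classification import TrainedModel
        model = TrainedModel("fuzzy", {"corn": Const(70.0), "soybean": Const(50.0)},
                             (), training_medians=np.zeros(2))
        pred = predict_coverage(model, np.zeros((1, 2)))
        assert pred[0, 0] == pytest.approx(100 * 70 / 120)
        assert pred[1, 0] == pytest.approx(100 * 50 / 120)
        assert pred[2, 0] == pytest.approx(0.0, abs=1e-9)

    def test_nodata_propagates(self):
        X, cov = two_cluster_data()
        model = train_classifier(X, cov, "fuzzy", seed=0)
        X_test = np.vstack([X[:1], np.full((1, 5), np.nan)])
        pred = predict_coverage(model, X_test)
        assert np.isfinite(pred[:, 0]).all()
        assert np.isnan(pred[:, 1]).all()

    def test_partial_missing_imputed_with_medians(self):
        X, cov = two_cluster_data()
        model = train_classifier(X, cov, "fuzzy", seed=0)
        x = X[:1].copy()
        x[0, 2] = np.nan
        pred = predict_coverage(model, x)
        assert np.isfinite(pred[:, 0]).all()

    def test_outputs_within_bounds_and_sum(self):
        X, cov = two_cluster_data(seed=5)
        model = train_classifier(X, cov, "fuzzy", seed=0)
        rng = np.random.default_rng(9)
        pred = predict_coverage(model, rng.normal(2.5, 2.0, size=(200, 5)))
        assert np.nanmin(pred) >= 0.0 and np.nanmax(pred) <= 100.0
        assert np.all(pred[0] + pred[1] <= 100.0 + 1e-9)

    def test_hard_prediction_labels(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(i * 4, 0.2, size=(30, 4)) for i in range(3)])
        y = np.repeat([CLASS_CODES["other"], CLASS_CODES["corn"],
                       CLASS_CODES["soybean"]], 30).astype(np.uint8)
        model = train_classifier(X, y, "hard", seed=0)
        pred = predict_coverage(model, X)
        assert (pred == y).mean() > 0.99
        assert pred.dtype == np.uint8

    def test_hard_fuzzy_agree_on_pure_landscape(self):
        """On pure pixels, fuzzy corn% > 50 iff the hard label is corn."""
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 0.3, size=(60, 4)),
                       rng.normal(4, 0.3, size=(60, 4)),
                       rng.normal(8, 0.3, size=(60, 4))])
        hard_y = np.repeat([CLASS_CODES["corn"], CLASS_CODES["soybean"],
                            CLASS_CODES["other"]], 60).astype(np.uint8)
        cov = np.zeros((180, 3))
        cov[:60, 0] = 100.0
        cov[60:120, 1] = 100.0
        cov[:, 2] = 100.0 - cov[:, 0] - cov[:, 1]
        hard = predict_coverage(train_classifier(X, hard_y, "hard", seed=0), X)
        fuzzy = predict_coverage(train_classifier(X, cov, "fuzzy", seed=0), X)
        agree = (fuzzy[0] > 50.0) == (hard == CLASS_CODES["corn"])
        assert agree.mean() >= 0.95
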