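"""Risk-model training: separability, class weighting, CV protocol,
serialisation."""

import numpy as np
import pandas as pd
import pytest

from lqrscreen.models import (
    CVConfig,
    MLPConfig,
    TrainedModel,
    predict_risk,
    train_baseline,
    train_mlp,
    train_raw_response_baseline,
)
from lqrscreen.nnet import MLPBinaryClassifier, roc_auc

FAST_CV = CVConfig(n_folds=3)
FAST_MLP = MLPConfig(hidden_layers=(16, 8, 8, 4), max_epochs=60)


def _gaussian_problem(n=2000, d=12, shift=1.5, prevalence=0.5, seed=0):
    rng = np.random.default_rng(seed)
    y = (rng.uniform(size=n) < prevalence).astype(float)
    x = rng.normal(size=(n, d)) + shift * y[:, None]
    cols = [f"f{i}" for i in range(d)]
    return pd.DataFrame(x, columns=cols), y


class TestMLPTraining:
    def test_separable_data_high_auc(self):
        x, y = _gaussian_problem(seed=1)
        model = train_mlp(x.iloc[:1400], y[:1400], FAST_MLP, FAST_CV, seed=1)
        scores = predict_risk(model, x.iloc[1400:])
        assert roc_auc(y[1400:], scores) >= 0.95

    def test_single_class_labels_rejected(self):
        x, _ = _gaussian_problem(n=100)
        with pytest.raises(ValueError, match="single class"):
            train_mlp(x, np.ones(100), FAST_MLP, FAST_CV)

    def test_nan_features_point_to_imputation(self):
        x, y = _gaussian_problem(n=100)
        x.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="imput"):
            train_mlp(x, y, FAST_MLP, FAST_CV)

    def test_class_weighting_boosts_sensitivity(self):
        """At threshold 0.5 on imbalanced data, the class-weighted MLP's
        sensitivity is at least the unweighted one's (paired seeds)."""
        diffs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 1500
            y = (rng.uniform(size=n) < 0.1).astype(float)
            x = rng.normal(size=(n, 8)) + 0.5 * y[:, None]
            tr, te = slice(0, 1100), slice(1100, n)
            xv, yv = x[1000:1100], y[1000:1100]
            weighted = MLPBinaryClassifier(
                hidden_layers=(16, 8, 8, 4), max_epochs=60, seed=seed,
            ).fit(x[:1000], y[:1000], xv, yv)
            unweighted = MLPBinaryClassifier(
                hidden_layers=(16, 8, 8, 4), max_epochs=60, seed=seed,
                class_weight=None,
            ).fit(x[:1000], y[:1000], xv, yv)
            pos = y[te] == 1
            sens_w = (weighted.predict_proba(x[te])[pos] > 0.5).mean()
            sens_u = (unweighted.predict_proba(x[te])[pos] > 0.5).mean()
            diffs.append(sens_w - sens_u)
        assert np.mean(diffs) >= 0

    def test_early_stopping_restores_best_epoch(self):
        x, y = _gaussian_problem(n=800, shift=0.8, seed=3)
        m = MLPBinaryClassifier(hidden_layers=(16, 8, 8, 4), max_epochs=80,
                                seed=3)
        m.fit(x.iloc[:500].to_numpy(), y[:500], x.iloc[500:].to_numpy(),
              y[500:])
        restored_auc = roc_auc(y[500:], m.predict_proba(x.iloc[500:].to_numpy()))
        assert restored_auc >= max(m.history_["val_auc"]) - 1e-9

    def test_fold_metadata_recorded(self):
        x, y = _gaussian_problem(n=600, seed=4)
        model = train_mlp(x, y, FAST_MLP, FAST_CV, seed=4)
        md = model.metadata
        assert len(md["fold_val_auc"]) == 3
        assert md["selected_fold"] == int(np.argmax(md["fold_val_auc"]))
        assert model.validation_scores is not None


class TestBaselines:
    def test_logistic_separable(self):
        x, y = _gaussian_problem(seed=5)
        model = train_baseline("logistic", x.iloc[:1400], y[:1400],
                               cv=FAST_CV, seed=5)
        assert roc_auc(y[1400:], predict_risk(model, x.iloc[1400:])) >= 0.95

    def test_tree_depth_controls_xor(self):
        """Depth-1 trees cannot represent XOR structure; deeper ones can."""
        rng = np.random.default_rng(6)
        n = 2000
        a = rng.integers(0, 2, n)
        b = rng.integers(0, 2, n)
        y = (a ^ b).astype(float)
        x = pd.DataFrame({
            "a": a + rng.normal(0, 0.1, n),
            "b": b + rng.normal(0, 0.1, n),
        })
        stump = train_baseline("tree", x.iloc[:1400], y[:1400],
                               grid={"max_depth": [1],
                                     "min_samples_leaf": [50]},
                               cv=FAST_CV, seed=6)
        deep = train_baseline("tree", x.iloc[:1400], y[:1400],
                              grid={"max_depth": [1, 2, 3],
                                    "min_samples_leaf": [50]},
                              cv=FAST_CV, seed=6)
        auc_stump = roc_auc(y[1400:], predict_risk(stump, x.iloc[1400:]))
        auc_deep = roc_auc(y[1400:], predict_risk(deep, x.iloc[1400:]))
        assert abs(auc_stump - 0.5) < 0.1
        assert auc_deep > 0.9

    def test_gradient_boosting_runs(self):
        x, y = _gaussian_problem(n=600, seed=7)
        model = train_baseline("gradient_boosting", x, y,
                               grid={"learning_rate": [0.1], "max_iter": [50]},
                               cv=FAST_CV, seed=7)
        assert model.metadata["cv_best_auc"] > 0.9

    def test_empty_grid_rejected(self):
        x, y = _gaussian_problem(n=100, seed=8)
        with pytest.raises(ValueError, match="grid"):
            train_baseline("logistic", x, y, grid={"C": []}, cv=FAST_CV)

    def test_grid_selection_deterministic(self):
        x, y = _gaussian_problem(n=400, shift=0.5, seed=9)
        m1 = train_baseline("tree", x, y, cv=FAST_CV, seed=9)
        m2 = train_baseline("tree", x, y, cv=FAST_CV, seed=9)
        assert m1.metadata["best_params"] == m2.metadata["best_params"]

    def test_unknown_kind_rejected(self):
        x, y = _gaussian_problem(n=100)
        with pytest.raises(ValueError, match="unknown baseline"):
            train_baseline("svm", x, y, cv=FAST_CV)


class TestRawResponseBaseline:
    def test_null_data_gives_chance_auc(self):
        rng = np.random.default_rng(10)
        x = pd.DataFrame(rng.integers(0, 6, size=(1500, 6)).astype(float),
                         columns=[f"i{j}" for j in range(6)])
        y = rng.integers(0, 2, 1500).astype(float)
        model = train_raw_response_baseline(x.iloc[:1000], y[:1000],
                                            cv=FAST_CV, seed=10)
        test_auc = roc_auc(y[1000:], predict_risk(model, x.iloc[1000:]))
        assert 0.4 <= test_auc <= 0.6

    def test_missing_responses_rejected(self):
        x = pd.DataFrame({"i1": [1.0, np.nan], "i2": [0.0, 1.0]})
        with pytest.raises(ValueError, match="impute"):
            train_raw_response_baseline(x, np.array([0, 1]), cv=FAST_CV)


class TestPredictRisk:
    def test_codomain_and_rowwise_purity(self):
        x, y = _gaussian_problem(n=400, seed=11)
        model = train_mlp(x, y, FAST_MLP, FAST_CV, seed=11)
        scores = predict_risk(model, x)
        assert np.all((scores >= 0) & (scores <= 1))
        doubled = pd.concat([x.iloc[[5]], x.iloc[[5]]])
        s2 = predict_risk(model, doubled)
        assert s2[0] == s2[1] == scores[5]

    def test_layout_mismatch_descriptive(self):
        x, y = _gaussian_problem(n=200, seed=12)
        model = train_mlp(x, y, FAST_MLP, FAST_CV, seed=12)
        with pytest.raises(ValueError, match="layout"):
            predict_risk(model, x.rename(columns={"f0": "zzz"}))

    @pytest.mark.parametrize("kind", ["mlp", "logistic"])
    def test_serialisation_roundtrip_bit_identical(self, tmp_path, kind):
        x, y = _gaussian_problem(n=400, seed=13)
        if kind == "mlp":
            model = train_mlp(x, y, FAST_MLP, FAST_CV, seed=13)
        else:
            model = train_baseline(kind, x, y, cv=FAST_CV, seed=13)
        before = predict_risk(model, x)
        model.save(tmp_path / "m")
        again = TrainedModel.load(tmp_path / "m")
        after = predict_risk(again, x)
        assert np.array_equal(before, after)
        assert again.kind == model.kind
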