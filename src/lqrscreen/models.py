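"""Risk-model training under the repeated cross-validation protocol.

The primary classifier is the class-weighted MLP; classical baselines
(logistic regression, decision tree), a histogram-based gradient-boosted
trees learner, and a raw-response logistic baseline are trained under the
same regime for comparison.  For the MLP, training data are split ten
times into stratified 80/20 train/validation subsets; each repetition
trains with early stopping monitored on its validation AUC and the model
with the best validation AUC is retained.  Baselines use grid search with
cross-validated AUC.  Trained models predict risk scores in [0, 1].
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_predict
from sklearn.tree import DecisionTreeClassifier

from .nnet import MLPBinaryClassifier, roc_auc
from .preprocess import SplitSpec, stratified_split

__all__ = [
    "MLPConfig",
    "CVConfig",
    "TrainedModel",
    "train_mlp",
    "train_baseline",
    "train_raw_response_baseline",
    "predict_risk",
    "BASELINE_KINDS",
]

BASELINE_KINDS = ("logistic", "tree", "gradient_boosting")


@dataclass(frozen=True)
class MLPConfig:
    """Hyperparameters of the screening MLP (all exposed, defaults below)."""

    hidden_layers: tuple[int, ...] = (64, 32, 16, 8)
    dropout: float = 0.2
    batch_norm: bool = True
    learning_rate: float = 1e-3
    lr_factor: float = 0.5
    lr_patience: int = 3
    early_stopping_patience: int = 10
    max_epochs: int = 200
    batch_size: int = 128

    def build(self, seed: int) -> MLPBinaryClassifier:
        return MLPBinaryClassifier(
            hidden_layers=self.hidden_layers,
            dropout=self.dropout,
            batch_norm=self.batch_norm,
            class_weight="balanced",
            learning_rate=self.learning_rate,
            lr_factor=self.lr_factor,
            lr_patience=self.lr_patience,
            early_stopping_patience=self.early_stopping_patience,
            max_epochs=self.max_epochs,
            batch_size=self.batch_size,
            seed=seed,
        )


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation regime: repetitions and inner validation share."""

    n_folds: int = 10
    inner_validation_fraction: float = 0.20

    def __post_init__(self) -> None:
        if self.n_folds < 1:
            raise ValueError("n_folds must be >= 1")
        if not 0 < self.inner_validation_fraction < 1:
            raise ValueError("inner_validation_fraction must lie in (0, 1)")


def _fold_seed(master: int, fold: int) -> int:
    return int((master * 1_000_003 + fold * 7919 + 17) % 2**31)


@dataclass
class TrainedModel:
    """A fitted risk model with its training metadata.

    ``kind`` is one of mlp / logistic / tree / gradient_boosting /
    raw_response_logistic.  ``validation_scores`` holds the pooled
    validation predictions used downstream for threshold tuning.
    """

    kind: str
    estimator: object
    feature_columns: list[str]
    metadata: dict = field(default_factory=dict)
    validation_scores: pd.DataFrame | None = None

    def summary(self) -> str:
        md = self.metadata
        lines = [
            f"TrainedModel(kind={self.kind})",
            f"  features ({len(self.feature_columns)}): "
            + ", ".join(self.feature_columns[:6])
            + (" ..." if len(self.feature_columns) > 6 else ""),
        ]
        if "fold_val_auc" in md:
            aucs = md["fold_val_auc"]
            lines.append(
                f"  folds: {len(aucs)}  val AUC best={max(aucs):.4f} "
                f"mean={np.mean(aucs):.4f}  selected fold={md['selected_fold']}"
            )
        if "best_params" in md:
            lines.append(f"  grid-search best: {md['best_params']}")
        return "\n".join(lines)

    # -- persistence ---------------------------------------------------
    def save(self, directory) -> None:
        os.makedirs(directory, exist_ok=True)
        meta = {
            "format": "lqrscreen-model",
            "version": 1,
            "kind": self.kind,
            "feature_columns": self.feature_columns,
            "metadata": self.metadata,
        }
        with open(os.path.join(directory, "model.json"), "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
            fh.write("\n")
        if isinstance(self.estimator, MLPBinaryClassifier):
            with open(os.path.join(directory, "weights.json"), "w") as fh:
                fh.write(self.estimator.to_json())
        else:
            joblib.dump(self.estimator,
                        os.path.join(directory, "estimator.joblib"))
        if self.validation_scores is not None:
            self.validation_scores.to_csv(
                os.path.join(directory, "validation_scores.csv"),
                index_label="row")

    @classmethod
    def load(cls, directory) -> "TrainedModel":
        with open(os.path.join(directory, "model.json")) as fh:
            meta = json.load(fh)
        wpath = os.path.join(directory, "weights.json")
        if os.path.exists(wpath):
            with open(wpath) as fh:
                est = MLPBinaryClassifier.from_json(fh.read())
        else:
            est = joblib.load(os.path.join(directory, "estimator.joblib"))
        vpath = os.path.join(directory, "validation_scores.csv")
        vs = pd.read_csv(vpath, index_col="row") if os.path.exists(vpath) else None
        return cls(meta["kind"], est, meta["feature_columns"],
                   meta["metadata"], vs)


def _check_training_inputs(x: np.ndarray, y: np.ndarray) -> None:
    if np.isnan(x).any():
        raise ValueError(
            "features contain missing values; run iterative imputation first"
        )
    if np.unique(y).size < 2:
        raise ValueError("labels contain a single class; cannot train")


def train_mlp(
    features: pd.DataFrame,
    labels,
    cfg: MLPConfig | None = None,
    cv: CVConfig | None = None,
    seed: int = 0,
) -> TrainedModel:
    """Train the class-weighted MLP; retain the best-validation-AUC fold.

    Each of the ``cv.n_folds`` repetitions draws a stratified 80/20
    train/validation split (fold seeds derived from ``seed``), trains with
    early stopping on validation AUC, and the single best model is kept.
    Pooled per-fold validation predictions are stored for threshold tuning.
    """
    cfg = cfg or MLPConfig()
    cv = cv or CVConfig()
    x = features.to_numpy(dtype=float)
    y = np.asarray(labels, dtype=float).ravel()
    _check_training_inputs(x, y)

    best: MLPBinaryClassifier | None = None
    best_auc, best_fold = -np.inf, -1
    fold_aucs: list[float] = []
    pooled_rows: list[np.ndarray] = []
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    for fold in range(cv.n_folds):
        fseed = _fold_seed(seed, fold)
        tr, va = stratified_split(
            y, SplitSpec(test_fraction=cv.inner_validation_fraction,
                         seed=fseed),
        )
        model = cfg.build(seed=fseed)
        model.fit(x[tr], y[tr], x[va], y[va])
        val_scores = model.predict_proba(x[va])
        auc = roc_auc(y[va], val_scores)
        fold_aucs.append(auc)
        pooled_rows.append(va)
        pooled_scores.append(val_scores)
        pooled_labels.append(y[va])
        if auc > best_auc:
            best_auc, best_fold, best = auc, fold, model
    validation = pd.DataFrame({
        "row": np.concatenate(pooled_rows),
        "score": np.concatenate(pooled_scores),
        "label": np.concatenate(pooled_labels),
    }).set_index("row")
    return TrainedModel(
        kind="mlp",
        estimator=best,
        feature_columns=features.columns.tolist(),
        metadata={
            "fold_val_auc": [float(a) for a in fold_aucs],
            "selected_fold": int(best_fold),
            "seed": int(seed),
            "config": cfg.build(0).get_config(),
        },
        validation_scores=validation,
    )


_DEFAULT_GRIDS: dict[str, dict] = {
    "logistic": {"C": [0.01, 0.1, 1.0, 10.0]},
    "tree": {"max_depth": [2, 3, 4, 6, 8], "min_samples_leaf": [10, 50]},
    "gradient_boosting": {"learning_rate": [0.05, 0.1],
                          "max_iter": [100, 200]},
}


def _make_estimator(kind: str, seed: int):
    if kind == "logistic":
        return LogisticRegression(class_weight="balanced", max_iter=2000,
                                  random_state=seed)
    if kind == "tree":
        return DecisionTreeClassifier(class_weight="balanced",
                                      random_state=seed)
    if kind == "gradient_boosting":
        return HistGradientBoostingClassifier(class_weight="balanced",
                                              random_state=seed)
    raise ValueError(f"unknown baseline kind {kind!r}; choose from "
                     f"{BASELINE_KINDS}")


def train_baseline(
    kind: str,
    features: pd.DataFrame,
    labels,
    grid: Mapping[str, Sequence] | None = None,
    cv: CVConfig | None = None,
    seed: int = 0,
) -> TrainedModel:
    """Grid-search a baseline classifier by cross-validated AUC and refit.

    Pooled out-of-fold predictions with the selected hyperparameters are
    stored for threshold tuning.
    """
    cv = cv or CVConfig()
    estimator = _make_estimator(kind, seed)
    grid = dict(grid) if grid is not None else _DEFAULT_GRIDS[kind]
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("hyperparameter grid must be non-empty")
    x = features.to_numpy(dtype=float)
    y = np.asarray(labels, dtype=float).ravel()
    _check_training_inputs(x, y)
    splitter = StratifiedKFold(n_splits=min(cv.n_folds, 5), shuffle=True,
                               random_state=seed)
    search = GridSearchCV(estimator, grid, scoring="roc_auc", cv=splitter,
                          refit=True)
    search.fit(x, y)
    oof = cross_val_predict(
        clone(estimator).set_params(**search.best_params_), x, y,
        cv=StratifiedKFold(5, shuffle=True, random_state=seed),
        method="predict_proba",
    )[:, 1]
    validation = pd.DataFrame(
        {"score": oof, "label": y},
        index=pd.RangeIndex(len(y), name="row"),
    )
    return TrainedModel(
        kind=kind,
        estimator=search.best_estimator_,
        feature_columns=features.columns.tolist(),
        metadata={
            "best_params": search.best_params_,
            "cv_best_auc": float(search.best_score_),
            "seed": int(seed),
        },
        validation_scores=validation,
    )


def train_raw_response_baseline(
    responses: pd.DataFrame,
    labels,
    cv: CVConfig | None = None,
    grid: Mapping[str, Sequence] | None = None,
    seed: int = 0,
) -> TrainedModel:
    """Logistic regression on raw (imputed) item codes — the naive baseline
    that uses questionnaire content directly instead of LQR indices."""
    if responses.isna().any().any():
        raise ValueError("raw responses contain missing values; impute first")
    model = train_baseline("logistic", responses, labels, grid=grid, cv=cv,
                           seed=seed)
    model.kind = "raw_response_logistic"
    return model


def predict_risk(model: TrainedModel, features: pd.DataFrame) -> np.ndarray:
    """Risk scores in [0, 1] for new respondents.

    The feature layout must match training; a mismatch raises with the
    offending columns named.
    """
    cols = features.columns.tolist()
    if cols != model.feature_columns:
        missing = [c for c in model.feature_columns if c not in cols]
        extra = [c for c in cols if c not in model.feature_columns]
        raise ValueError(
            "feature layout mismatch with training metadata; "
            f"missing={missing} unexpected={extra} (order matters)"
        )
    x = features.to_numpy(dtype=float)
    if isinstance(model.estimator, MLPBinaryClassifier):
        scores = model.estimator.predict_proba(x)
    else:
        scores = model.estimator.predict_proba(x)[:, 1]
    return np.clip(scores, 0.0, 1.0)
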