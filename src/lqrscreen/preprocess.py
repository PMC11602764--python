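"""Outcome labels, missing-data imputation, and prevalence-matched splits.

Cognition scores on the 0-27 scale map to three bands — dementia (0-6),
cognitively impaired without dementia (7-11), cognitively normal (12-27) —
and the two impaired bands collapse into the binary screening label.
Missing questionnaire entries are completed by regression-based iterative
(chained) imputation; train/test splits are stratified on the binary label
so both partitions share the cohort's impairment prevalence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer

__all__ = [
    "OutcomeLabel",
    "SplitSpec",
    "derive_ci_label",
    "derive_ci_labels",
    "iterative_impute",
    "stratified_split",
    "CATEGORY_DEMENTIA",
    "CATEGORY_CIND",
    "CATEGORY_NORMAL",
]

CATEGORY_DEMENTIA = "dementia"
CATEGORY_CIND = "cognitively impaired, no dementia"
CATEGORY_NORMAL = "normal"


@dataclass(frozen=True)
class OutcomeLabel:
    """Cognitive-status label derived from a 0-27 cognition score."""

    category: str
    binary_ci: bool
    cognition_score: int


def derive_ci_label(score: int) -> OutcomeLabel:
    """Map a cognition score to its band and the binary impairment label.

    Bands: 0-6 dementia, 7-11 impaired without dementia, 12-27 normal; the
    binary label is true for either impaired band.
    """
    s = int(score)
    if s != score or not 0 <= s <= 27:
        raise ValueError(f"cognition score must be an integer in [0, 27], got {score}")
    if s <= 6:
        cat = CATEGORY_DEMENTIA
    elif s <= 11:
        cat = CATEGORY_CIND
    else:
        cat = CATEGORY_NORMAL
    return OutcomeLabel(cat, cat != CATEGORY_NORMAL, s)


def derive_ci_labels(scores) -> pd.DataFrame:
    """Vectorised :func:`derive_ci_label` over an array of scores."""
    arr = np.asarray(scores)
    labels = [derive_ci_label(s) for s in arr]
    return pd.DataFrame(
        {
            "category": [l.category for l in labels],
            "binary_ci": [l.binary_ci for l in labels],
            "cognition_score": [l.cognition_score for l in labels],
        }
    )


def iterative_impute(
    table: pd.DataFrame,
    max_iter: int = 10,
    tol: float = 1e-3,
    seed: int = 0,
    category_bounds: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Complete a table by regression-based iterative (chained) imputation.

    Each variable with missing entries is regressed on the others in a
    round-robin until changes fall below ``tol`` or ``max_iter`` rounds.
    Columns named in ``category_bounds`` (item -> number of categories K)
    are rounded and clipped to ``[0, K-1]`` after imputation.  Observed
    entries are never altered.

    Raises
    ------
    ValueError
        If a column is entirely missing (nothing to regress on).
    """
    empty = [c for c in table.columns if table[c].isna().all()]
    if empty:
        raise ValueError(f"column(s) entirely missing: {empty}")
    if not table.isna().any().any():
        return table.copy()
    imputer = IterativeImputer(
        max_iter=max_iter, tol=tol, random_state=seed,
        initial_strategy="median", sample_posterior=False,
    )
    with warnings.catch_warnings():
        # chained regressions may stop on max_iter without "converging"
        warnings.simplefilter("ignore")
        completed = imputer.fit_transform(table.to_numpy(dtype=float))
    out = pd.DataFrame(completed, index=table.index, columns=table.columns)
    if category_bounds:
        for col, k in category_bounds.items():
            if col in out.columns:
                out[col] = np.clip(np.round(out[col]), 0, k - 1)
    # restore observed entries verbatim (rounding must not touch them)
    out = out.where(table.isna(), table)
    assert not out.isna().any().any()
    return out


@dataclass(frozen=True)
class SplitSpec:
    """Stratified train/test split specification."""

    test_fraction: float = 0.30
    stratify_on: str = "impairment"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")


def stratified_split(
    labels: pd.Series | np.ndarray,
    spec: SplitSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic per-stratum allocation into train and test index arrays.

    Within every stratum, ``round(n_stratum * test_fraction)`` members are
    assigned to test, so train and test prevalences agree to within one
    respondent per stratum.  Strata with fewer than two members raise a
    warning and go to train.  Returns positional index arrays.
    """
    y = np.asarray(labels)
    n = y.size
    rng = np.random.default_rng(spec.seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for value in np.unique(y):
        members = np.flatnonzero(y == value)
        if members.size < 2:
            warnings.warn(
                f"stratum {value!r} has {members.size} member(s); assigned to train"
            )
            train_idx.append(members)
            continue
        perm = rng.permutation(members)
        n_test = int(round(members.size * spec.test_fraction))
        n_test = min(max(n_test, 1), members.size - 1)
        test_idx.append(perm[:n_test])
        train_idx.append(perm[n_test:])
    train = np.sort(np.concatenate(train_idx)) if train_idx else np.array([], int)
    test = np.sort(np.concatenate(test_idx)) if test_idx else np.array([], int)
    assert train.size + test.size == n
    return train, test
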