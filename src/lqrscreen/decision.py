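"""Cost-ratio referral thresholds.

A respondent is referred for follow-up clinical assessment when their
predicted risk score strictly exceeds the threshold.  The threshold is
chosen to minimise the total screening cost ``r * FN + FP``, where a false
negative (underdiagnosis: an impaired respondent not referred) costs ``r``
times a false positive (overdiagnosis: a normal respondent referred, i.e.
one unnecessary follow-up assessment).  Only the ratio matters.  The
default ``r = 4`` trades off missed cases against follow-up burden; larger
ratios suit settings where follow-up assessment is readily available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["CostRatio", "ThresholdDecision", "select_threshold", "refer",
           "candidate_thresholds"]


@dataclass(frozen=True)
class CostRatio:
    """Ratio of underdiagnosis (FN) to overdiagnosis (FP) cost; default 4."""

    r: float = 4.0

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError("cost ratio must be positive")


@dataclass(frozen=True)
class ThresholdDecision:
    """Selected referral cutoff with its confusion counts and total cost."""

    threshold: float
    cost_ratio: float
    total_cost: float
    n_referred: int
    n_cases_identified: int
    tp: int
    fp: int
    fn: int
    tn: int

    def to_json(self, path=None) -> dict:
        n = self.tp + self.fp + self.fn + self.tn
        n_pos = self.tp + self.fn
        payload = {
            **asdict(self),
            "proportion_referred": self.n_referred / n if n else float("nan"),
            "proportion_identified": (
                self.n_cases_identified / n_pos if n_pos else float("nan")
            ),
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(payload, fh, indent=2, sort_keys=True)
                fh.write("\n")
        return payload


def candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    """{0, 1} plus midpoints between adjacent distinct sorted scores.

    The same candidate set drives threshold selection and the efficiency
    curve, so the two agree pointwise.
    """
    u = np.unique(np.asarray(scores, dtype=float))
    mids = (u[:-1] + u[1:]) / 2.0
    return np.unique(np.concatenate([[0.0], mids, [1.0]]))


def _confusion_at(scores, labels, thresholds):
    """Vectorised FP/FN/TP counts at each threshold (referral: score > t)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    pos_sorted = np.sort(scores[y])
    neg_sorted = np.sort(scores[~y])
    t = np.asarray(thresholds, dtype=float)
    # score > t  <=>  index past the right insertion point
    fn = np.searchsorted(pos_sorted, t, side="right")
    tp = pos_sorted.size - fn
    fp = neg_sorted.size - np.searchsorted(neg_sorted, t, side="right")
    return tp, fp, fn


def select_threshold(scores, labels, cost: CostRatio | float = CostRatio()) -> ThresholdDecision:
    """Pick the candidate threshold minimising ``r * FN + FP``.

    Ties are broken towards the largest threshold (fewest referrals).
    Requires both classes present.
    """
    if not isinstance(cost, CostRatio):
        cost = CostRatio(float(cost))
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("threshold selection requires both classes present")
    cand = candidate_thresholds(scores)
    tp, fp, fn = _confusion_at(scores, y, cand)
    total = cost.r * fn + fp
    best = np.flatnonzero(total == total.min()).max()
    t = float(cand[best])
    n_pos = int(y.sum())
    return ThresholdDecision(
        threshold=t,
        cost_ratio=cost.r,
        total_cost=float(total[best]),
        n_referred=int(tp[best] + fp[best]),
        n_cases_identified=int(tp[best]),
        tp=int(tp[best]),
        fp=int(fp[best]),
        fn=int(fn[best]),
        tn=int(y.size - n_pos - fp[best]),
    )


def refer(scores, threshold: float) -> np.ndarray:
    """Boolean referral vector: referred iff score strictly exceeds the
    threshold (a score exactly at the threshold is not referred)."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    return np.asarray(scores, dtype=float) > threshold
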