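"""Screening evaluation: AUC, efficiency curves, rule-based comparators,
and age-stratified reports.

The efficiency curve sweeps every candidate threshold and plots the
proportion of all individuals referred (a proxy for follow-up resources)
against the proportion of impaired individuals identified (the desired
outcome) — operationally the (positive rate, sensitivity) pairs.  Rule-
based strategies (refer everyone aged 65+, or with a given disease) are
single points in the same plane, making machine-learning and rule-based
screening directly comparable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .decision import CostRatio, ThresholdDecision, candidate_thresholds, refer, select_threshold
from .nnet import roc_auc

__all__ = [
    "auc",
    "EfficiencyCurve",
    "efficiency_curve",
    "RuleStrategy",
    "STANDARD_RULES",
    "rule_point",
    "EvaluationReport",
    "stratified_report",
    "AGE_GROUPS",
]

AGE_GROUPS: tuple[tuple[str, float, float], ...] = (
    ("50-59", 50.0, 60.0),
    ("60-69", 60.0, 70.0),
    ("70-79", 70.0, 80.0),
    ("80+", 80.0, np.inf),
)


def auc(scores, labels) -> float:
    """Area under the ROC curve: the Mann-Whitney probability that a
    random impaired respondent outscores a random normal one, with half
    credit for ties."""
    return roc_auc(np.asarray(labels), np.asarray(scores))


@dataclass
class EfficiencyCurve:
    """Threshold sweep of (proportion referred, proportion identified)."""

    thresholds: np.ndarray
    proportion_referred: np.ndarray
    proportion_identified: np.ndarray
    n: int
    n_impaired: int

    def point_at(self, threshold: float) -> tuple[float, float]:
        """Exact curve point for an arbitrary threshold."""
        i = np.searchsorted(self.thresholds, threshold)
        if i < self.thresholds.size and self.thresholds[i] == threshold:
            return (float(self.proportion_referred[i]),
                    float(self.proportion_identified[i]))
        raise KeyError(f"threshold {threshold} not on the candidate grid")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "proportion_referred": self.proportion_referred,
            "proportion_identified": self.proportion_identified,
        })


def efficiency_curve(scores, labels) -> EfficiencyCurve:
    """Sweep the candidate thresholds shared with threshold selection.

    At a threshold below every score the point is (1, 1); at or above the
    maximum score it is (0, 0).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("efficiency curve requires both classes present")
    cand = candidate_thresholds(scores)
    referred = scores[None, :] > cand[:, None]
    x = referred.mean(axis=1)
    ident = (referred & y[None, :]).sum(axis=1) / y.sum()
    return EfficiencyCurve(cand, x, ident, y.size, int(y.sum()))


@dataclass(frozen=True)
class RuleStrategy:
    """A deterministic referral rule over cohort attributes."""

    name: str
    predicate: Callable[[pd.DataFrame], np.ndarray]
    required_columns: tuple[str, ...]

    def evaluate(self, cohort: pd.DataFrame) -> np.ndarray:
        for col in self.required_columns:
            if col not in cohort.columns:
                raise ValueError(
                    f"rule {self.name!r} requires cohort column {col!r}"
                )
        return np.asarray(self.predicate(cohort), dtype=bool)


def _binary_rule(column: str, name: str) -> RuleStrategy:
    return RuleStrategy(name, lambda c, col=column: c[col].to_numpy() == 1,
                        (column,))


STANDARD_RULES: dict[str, RuleStrategy] = {
    "age65": RuleStrategy("age65", lambda c: c["age"].to_numpy() >= 65,
                          ("age",)),
    "diabetes": _binary_rule("diabetes", "diabetes"),
    "high_blood_pressure": _binary_rule("high_blood_pressure",
                                        "high_blood_pressure"),
    "heart_disease": _binary_rule("heart_disease", "heart_disease"),
    "stroke": _binary_rule("stroke", "stroke"),
}


def rule_point(cohort: pd.DataFrame, rule: RuleStrategy,
               labels=None) -> tuple[float, float]:
    """(proportion referred, proportion of impaired identified) for a rule.

    ``labels`` defaults to the cohort's ``impairment`` column.
    """
    flag = rule.evaluate(cohort)
    if labels is None:
        if "impairment" not in cohort.columns:
            raise ValueError("cohort lacks an 'impairment' column")
        labels = cohort["impairment"]
    y = np.asarray(labels, dtype=bool)
    x = float(flag.mean())
    ident = float((flag & y).sum() / y.sum()) if y.any() else float("nan")
    return x, ident


@dataclass
class EvaluationReport:
    """Overall and age-stratified screening performance at one threshold."""

    auc: float
    decision: ThresholdDecision
    by_age_group: pd.DataFrame
    model_id: str = ""
    feature_set: str = ""

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "model_id": self.model_id,
            "feature_set": self.feature_set,
            "decision": self.decision.to_json(),
            "by_age_group": json.loads(
                self.by_age_group.to_json(orient="index")
            ),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def summary(self) -> str:
        d = self.decision
        n = d.tp + d.fp + d.fn + d.tn
        lines = [
            f"Screening evaluation ({self.model_id or 'model'}; "
            f"features: {self.feature_set or 'n/a'})",
            f"  AUC: {self.auc:.3f}",
            f"  cost ratio {d.cost_ratio:g} -> threshold {d.threshold:.4f}",
            f"  referred: {d.n_referred}/{n} ({100 * d.n_referred / n:.1f}%)"
            f"   impaired identified: {d.n_cases_identified}/{d.tp + d.fn}"
            f" ({100 * d.n_cases_identified / max(d.tp + d.fn, 1):.1f}%)",
            "  by age group:",
        ]
        for grp, row in self.by_age_group.iterrows():
            auctxt = "  n/a" if pd.isna(row["auc"]) else f"{row['auc']:.3f}"
            lines.append(
                f"    {grp:<6} n={int(row['n']):>5}  impaired="
                f"{int(row['n_impaired']):>4}  AUC={auctxt}  referred="
                f"{row['proportion_referred'] * 100:5.1f}%  identified="
                f"{row['proportion_identified'] * 100:5.1f}%"
            )
        return "\n".join(lines)


def stratified_report(
    scores,
    labels,
    cohort: pd.DataFrame,
    cost: CostRatio | float = CostRatio(),
    decision: ThresholdDecision | None = None,
    model_id: str = "",
    feature_set: str = "",
) -> EvaluationReport:
    """Overall AUC plus per-age-group AUC and referral proportions at a
    single (globally selected or supplied) threshold.

    Age bins with a single outcome class get a missing AUC rather than a
    placeholder.  Per-bin referred counts sum to the overall count.
    """
    if "age" not in cohort.columns:
        raise ValueError("cohort lacks an 'age' column")
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if decision is None:
        decision = select_threshold(scores, y, cost)
    else:
        # threshold was tuned elsewhere: restate its confusion counts on
        # *these* data so per-bin counts sum to the overall ones
        referred_all = refer(scores, decision.threshold)
        tp = int((referred_all & y).sum())
        fp = int((referred_all & ~y).sum())
        fn = int((~referred_all & y).sum())
        tn = int((~referred_all & ~y).sum())
        decision = ThresholdDecision(
            threshold=decision.threshold, cost_ratio=decision.cost_ratio,
            total_cost=decision.cost_ratio * fn + fp,
            n_referred=tp + fp, n_cases_identified=tp,
            tp=tp, fp=fp, fn=fn, tn=tn,
        )
    referred = refer(scores, decision.threshold)
    age = cohort["age"].to_numpy(dtype=float)

    rows = []
    for name, lo, hi in AGE_GROUPS:
        sel = (age >= lo) & (age < hi)
        nb = int(sel.sum())
        npos = int(y[sel].sum())
        if nb == 0:
            rows.append({"age_group": name, "n": 0, "n_impaired": 0,
                         "auc": np.nan, "n_referred": 0, "n_identified": 0,
                         "proportion_referred": np.nan,
                         "proportion_identified": np.nan})
            continue
        bin_auc = np.nan
        if 0 < npos < nb:
            bin_auc = auc(scores[sel], y[sel])
        nref = int(referred[sel].sum())
        nid = int((referred & y)[sel].sum())
        rows.append({
            "age_group": name, "n": nb, "n_impaired": npos, "auc": bin_auc,
            "n_referred": nref, "n_identified": nid,
            "proportion_referred": nref / nb,
            "proportion_identified": nid / npos if npos else np.nan,
        })
    table = pd.DataFrame(rows).set_index("age_group")
    return EvaluationReport(
        auc=auc(scores, y),
        decision=decision,
        by_age_group=table,
        model_id=model_id,
        feature_set=feature_set,
    )
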