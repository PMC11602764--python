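"""Synthetic questionnaire cohorts with known GRM structure and injected
low-quality responding (LQR).

The generator emulates a community aging-survey setting: respondents aged
50+ answer several short Likert well-being scales (optimism, hopelessness,
purpose in life, life satisfaction).  A fraction of the cohort has current
cognitive impairment; impaired respondents have a slightly lower mean
latent trait on each scale and a markedly elevated propensity to produce
low-quality answers — random or straight-lined categories and skipped
items.  Because every response is drawn from a known item bank and a known
latent trait, downstream stages (GRM recovery, person-fit indices, risk
models, threshold rules) can be validated against simulation ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .grm import ItemParameters, ResponseMatrix, _cumulative_probs

__all__ = [
    "CohortConfig",
    "generate_item_bank",
    "generate_scale_banks",
    "simulate_cohort",
    "assign_cognition_scores",
    "DEFAULT_SCALES",
]

# Four brief well-being scales: (name, n_items, n_categories).  The first
# three use 6-point agreement categories; life satisfaction uses the 5-item
# 7-point format common to satisfaction-with-life instruments.
DEFAULT_SCALES: tuple[tuple[str, int, int], ...] = (
    ("optimism", 6, 6),
    ("hopelessness", 7, 6),
    ("purpose", 7, 6),
    ("life_satisfaction", 5, 7),
)

# Decade age bins for respondents aged 50+ and their default shares,
# patterned on a large community aging survey.
AGE_BINS: tuple[str, ...] = ("50-59", "60-69", "70-79", "80+")
_AGE_BIN_EDGES = ((50, 60), (60, 70), (70, 80), (80, 95))
_DEFAULT_AGE_PROBS = (0.207, 0.327, 0.312, 0.154)

# Self-reported disease prevalences used by the rule-based comparators.
_DISEASES: dict[str, float] = {
    "high_blood_pressure": 0.54,
    "diabetes": 0.19,
    "heart_disease": 0.23,
    "stroke": 0.07,
}
_DISEASE_AGE_SLOPE = 0.03       # per-year log-odds increase around age 68
_DISEASE_IMPAIRMENT_LOR = 0.3   # impaired respondents report more disease

# Ten-year dementia-or-mortality outcome: logistic in impairment and age.
_FUTURE_INTERCEPT = -2.2
_FUTURE_IMPAIRMENT_BETA = 1.0
_FUTURE_AGE_BETA = 0.6          # per decade above 65


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one simulated cohort.

    Rates are per-item probabilities.  The ``*_impaired`` variants apply to
    respondents with cognitive impairment; elevated values encode the
    premise that impairment manifests as low-quality responding.

    Parameters
    ----------
    n_respondents : int
    scales : sequence of (name, n_items, n_categories)
    prevalence : float
        Cognitive-impairment prevalence, default 0.18.
    age_probs : tuple of float
        Shares of the four decade bins 50-59 / 60-69 / 70-79 / 80+.
    careless_rate_normal, careless_rate_impaired : float
        Per-item probability of a careless (content-free) answer.
    skip_rate_normal, skip_rate_impaired : float
        Per-item probability of a skipped (missing) answer.
    straightline_fraction : float
        Share of careless acts that repeat the previous emitted category
        instead of drawing a category uniformly.
    trait_impairment_shift : float
        Mean latent-trait offset for impaired respondents (trait-scale SD
        units); default -0.1 (content is nearly uninformative about
        impairment, so raw responses barely beat chance).
    age_impairment_log_or : float
        Log-odds tilt of the impaired group's age distribution towards
        older bins; 0 (default) makes age independent of impairment.
    """

    n_respondents: int
    scales: tuple[tuple[str, int, int], ...] = DEFAULT_SCALES
    prevalence: float = 0.18
    age_probs: tuple[float, ...] = _DEFAULT_AGE_PROBS
    careless_rate_normal: float = 0.05
    careless_rate_impaired: float = 0.45
    skip_rate_normal: float = 0.01
    skip_rate_impaired: float = 0.03
    straightline_fraction: float = 0.25
    trait_impairment_shift: float = -0.1
    age_impairment_log_or: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_respondents < 2:
            raise ValueError("n_respondents must be >= 2")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")
        for name in (
            "careless_rate_normal", "careless_rate_impaired",
            "skip_rate_normal", "skip_rate_impaired", "straightline_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for c, s in (
            (self.careless_rate_normal, self.skip_rate_normal),
            (self.careless_rate_impaired, self.skip_rate_impaired),
        ):
            if c + s > 1:
                raise ValueError("careless_rate + skip_rate must be <= 1")
        if len(self.age_probs) != len(AGE_BINS):
            raise ValueError(f"age_probs needs {len(AGE_BINS)} entries")
        if not np.isclose(sum(self.age_probs), 1.0, atol=1e-6):
            raise ValueError("age_probs must sum to 1")
        for name, n_items, k in self.scales:
            if n_items < 1 or k < 2:
                raise ValueError(f"scale {name!r}: invalid size ({n_items}, {k})")

    @property
    def scale_names(self) -> list[str]:
        return [s[0] for s in self.scales]


def generate_item_bank(
    n_items: int, n_categories: int, seed: int, prefix: str = "item"
) -> list[ItemParameters]:
    """Draw a random item bank with realistic GRM parameters.

    Discriminations are uniform on [0.8, 2.5]; thresholds are built from
    uniform gaps, centred per item with a small location shift, and always
    lie within [-2.5, 2.5].  Deterministic given ``seed``.
    """
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    if n_categories < 2:
        raise ValueError("n_categories must be >= 2")
    rng = np.random.default_rng(seed)
    bank = []
    for i in range(n_items):
        a = rng.uniform(0.8, 2.5)
        n_thr = n_categories - 1
        if n_thr == 1:
            b = np.array([rng.uniform(-1.0, 1.0)])
        else:
            gaps = rng.uniform(0.3, 0.9, size=n_thr - 1)
            b = np.concatenate([[0.0], np.cumsum(gaps)])
            b -= b.mean()
            shift = rng.uniform(-0.7, 0.7)
            lo, hi = -2.5 - b[0], 2.5 - b[-1]
            b += np.clip(shift, lo, hi)
        bank.append(ItemParameters(f"{prefix}_{i + 1}", float(a),
                                   tuple(b.tolist())))
    return bank


def generate_scale_banks(
    scales: Sequence[tuple[str, int, int]], seed: int
) -> dict[str, list[ItemParameters]]:
    """One item bank per scale, with per-scale seeds derived from ``seed``."""
    children = np.random.SeedSequence(seed).spawn(len(scales))
    return {
        name: generate_item_bank(
            n_items, k, int(child.generate_state(1)[0] % 2**31), prefix=name
        )
        for (name, n_items, k), child in zip(scales, children)
    }


def _sample_grm(
    bank: Sequence[ItemParameters], theta: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised GRM category draws, one column per item."""
    n = theta.size
    out = np.empty((n, len(bank)), dtype=np.int64)
    for j, item in enumerate(bank):
        cum = _cumulative_probs(item, theta)           # (K-1, n)
        u = rng.uniform(size=n)
        out[:, j] = (u[None, :] < cum).sum(axis=0)
    return out


def _draw_ages(
    rng: np.random.Generator, impaired: np.ndarray, cfg: CohortConfig
) -> np.ndarray:
    """Continuous ages from the decade-bin distribution; the impaired
    group's bin probabilities can be tilted towards older bins."""
    probs = np.asarray(cfg.age_probs, dtype=float)
    n = impaired.size
    bins = np.empty(n, dtype=np.int64)
    normal = ~impaired
    bins[normal] = rng.choice(len(AGE_BINS), size=int(normal.sum()), p=probs)
    tilt = probs * np.exp(cfg.age_impairment_log_or * np.arange(len(AGE_BINS)))
    tilt /= tilt.sum()
    bins[impaired] = rng.choice(len(AGE_BINS), size=int(impaired.sum()), p=tilt)
    lo = np.array([e[0] for e in _AGE_BIN_EDGES])[bins]
    hi = np.array([e[1] for e in _AGE_BIN_EDGES])[bins]
    return np.round(lo + rng.uniform(size=n) * (hi - lo), 1)


def simulate_cohort(
    config: CohortConfig,
    banks: Mapping[str, Sequence[ItemParameters]] | Sequence[ItemParameters] | None = None,
) -> tuple[ResponseMatrix, pd.DataFrame]:
    """Simulate a cohort of questionnaire responses with LQR behaviours.

    For every respondent a latent trait is drawn per scale,
    ``theta ~ N(shift * impaired, 1)``; each item response is then, in
    order of precedence, careless (uniform category or straight-line of the
    previous one), skipped (missing), or an honest GRM draw.

    Parameters
    ----------
    config : CohortConfig
    banks : mapping scale name -> item bank, optional
        Defaults to :func:`generate_scale_banks` seeded from the config.
        A flat item list is accepted and split across scales in order.

    Returns
    -------
    responses : ResponseMatrix
    cohort : DataFrame
        One row per respondent with age, gender, impairment, future_event,
        disease indicators, and simulation truth (per-scale traits and the
        careless flag).
    """
    if banks is None:
        banks = generate_scale_banks(config.scales, config.seed)
    elif not isinstance(banks, Mapping):
        flat = list(banks)
        banks = {}
        pos = 0
        for name, n_items, _k in config.scales:
            banks[name] = flat[pos:pos + n_items]
            pos += n_items
        if pos != len(flat):
            raise ValueError(
                f"flat bank has {len(flat)} items but config scales need {pos}"
            )
    for name, n_items, k in config.scales:
        bank = banks.get(name)
        if bank is None or len(bank) != n_items:
            raise ValueError(f"bank for scale {name!r} missing or wrong length")
        if any(it.n_categories != k for it in bank):
            raise ValueError(f"bank for scale {name!r} has wrong K")

    rng = np.random.default_rng(config.seed)
    n = config.n_respondents
    impaired = rng.uniform(size=n) < config.prevalence
    age = _draw_ages(rng, impaired, config)
    gender = rng.integers(0, 2, size=n)

    careless_rate = np.where(impaired, config.careless_rate_impaired,
                             config.careless_rate_normal)
    skip_rate = np.where(impaired, config.skip_rate_impaired,
                         config.skip_rate_normal)

    cohort = pd.DataFrame({
        "respondent_id": [f"r{i + 1:05d}" for i in range(n)],
        "age": age,
        "gender": gender,
        "impairment": impaired.astype(np.int64),
    }).set_index("respondent_id")

    # disease indicators for the rule-based screening comparators
    for disease, prev in _DISEASES.items():
        base = np.log(prev / (1 - prev))
        logit = (base + _DISEASE_AGE_SLOPE * (age - 68.0)
                 + _DISEASE_IMPAIRMENT_LOR * impaired)
        cohort[disease] = (rng.uniform(size=n) < expit(logit)).astype(np.int64)

    # ten-year dementia-or-mortality outcome
    logit = (_FUTURE_INTERCEPT + _FUTURE_IMPAIRMENT_BETA * impaired
             + _FUTURE_AGE_BETA * (age - 65.0) / 10.0)
    cohort["future_event"] = (rng.uniform(size=n) < expit(logit)).astype(np.int64)

    all_values: list[np.ndarray] = []
    all_missing: list[np.ndarray] = []
    item_ids: list[str] = []
    n_cats: list[int] = []
    any_careless = np.zeros(n, dtype=bool)
    first_theta: np.ndarray | None = None
    for name, n_items, k in config.scales:
        theta = rng.normal(config.trait_impairment_shift * impaired, 1.0)
        cohort[f"true_theta_{name}"] = theta
        if first_theta is None:
            first_theta = theta
        honest = _sample_grm(banks[name], theta, rng)
        values = np.empty((n, n_items), dtype=np.int64)
        missing = np.zeros((n, n_items), dtype=bool)
        prev_cat = np.full(n, -1, dtype=np.int64)  # last emitted category
        for j in range(n_items):
            u = rng.uniform(size=n)
            is_careless = u < careless_rate
            is_skip = (~is_careless) & (u < careless_rate + skip_rate)
            col = honest[:, j].copy()
            uniform_draw = rng.integers(0, k, size=n)
            straight = rng.uniform(size=n) < config.straightline_fraction
            careless_col = np.where(straight & (prev_cat >= 0),
                                    np.minimum(prev_cat, k - 1), uniform_draw)
            col[is_careless] = careless_col[is_careless]
            values[:, j] = col
            missing[:, j] = is_skip
            any_careless |= is_careless
            prev_cat = np.where(is_skip, prev_cat, col)
        all_values.append(values)
        all_missing.append(missing)
        item_ids.extend(it.item_id for it in banks[name])
        n_cats.extend([k] * n_items)

    cohort["true_careless"] = any_careless.astype(np.int64)
    cohort["true_theta"] = first_theta
    responses = ResponseMatrix(
        np.hstack(all_values), np.hstack(all_missing), item_ids,
        cohort.index.tolist(), n_cats,
    )
    return responses, cohort


def assign_cognition_scores(cohort: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Attach 0-27 cognition scores consistent with the impairment labels.

    Impaired respondents draw uniformly from 0-11 (the dementia plus
    impaired-no-dementia bands), normal respondents from 12-27, so deriving
    the binary label from the score reproduces the input labels exactly.
    """
    if "impairment" not in cohort.columns:
        raise ValueError("cohort lacks an 'impairment' column")
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    impaired = out["impairment"].to_numpy(dtype=bool)
    scores = np.where(
        impaired,
        rng.integers(0, 12, size=len(out)),
        rng.integers(12, 28, size=len(out)),
    )
    out["cognition_score"] = scores.astype(np.int64)
    return out


def save_truth(cohort: pd.DataFrame, banks: Mapping[str, Sequence[ItemParameters]],
               path) -> None:
    """Write simulation ground truth (item banks, traits, careless flags)."""
    payload = {
        "banks": {name: [it.to_dict() for it in bank]
                  for name, bank in banks.items()},
        "true_theta": {
            c: cohort[c].round(9).tolist()
            for c in cohort.columns if c.startswith("true_theta_")
        },
        "true_careless": cohort["true_careless"].tolist(),
        "respondent_id": cohort.index.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True)
        fh.write("\n")
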