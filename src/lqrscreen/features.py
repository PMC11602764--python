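"""Low-quality-response (LQR) indices derived from a fitted GRM.

Two person-fit indices are computed per respondent and item, conditioning
on the respondent's EAP latent trait so that questionnaire *content* is
removed and only statistical misfit remains:

* squared residual  ``s_ij = (x_ij - E[X_i | theta_j])**2`` — large values
  flag responses far from the model's expectation;
* observed-response probability  ``p_ij = P_{i, x_ij}(theta_j)`` — small
  values flag improbable category choices.

Per-item indices (two predictors per item) are the default layout; an
aggregated mode (per-scale mean squared residual and mean log probability)
is available behind a flag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grm import (
    ItemParameters,
    LatentTraitEstimate,
    QuadratureConfig,
    ResponseMatrix,
    category_probabilities,
    eap_scores,
    expected_response,
)

__all__ = [
    "squared_residual_index",
    "response_probability_index",
    "build_feature_table",
    "LQRFeatureTable",
]

DEMOGRAPHIC_COLUMNS = ("age", "gender")


def _as_row(row, bank: Sequence[ItemParameters]) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(row, dtype=float).ravel()
    if arr.size != len(bank):
        raise ValueError(
            f"row has {arr.size} responses but bank has {len(bank)} items"
        )
    missing = ~np.isfinite(arr)
    codes = np.where(missing, 0, arr).astype(np.int64)
    return codes, missing


def squared_residual_index(
    row, bank: Sequence[ItemParameters], trait: LatentTraitEstimate
) -> np.ndarray:
    """Per-item squared residuals ``(x - E[X|theta])**2``; NaN where missing."""
    codes, missing = _as_row(row, bank)
    out = np.empty(len(bank))
    for j, item in enumerate(bank):
        out[j] = (codes[j] - expected_response(item, trait.theta)) ** 2
    out[missing] = np.nan
    return out


def response_probability_index(
    row, bank: Sequence[ItemParameters], trait: LatentTraitEstimate
) -> np.ndarray:
    """Per-item probabilities of the observed categories; NaN where missing."""
    codes, missing = _as_row(row, bank)
    out = np.empty(len(bank))
    for j, item in enumerate(bank):
        out[j] = category_probabilities(item, trait.theta)[codes[j]]
    out[missing] = np.nan
    return out


def _matrix_indices(
    responses: ResponseMatrix,
    bank: Sequence[ItemParameters],
    theta: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised (squared residual, probability) arrays, shape (n, m)."""
    n, m = responses.shape
    sq = np.empty((n, m))
    pr = np.empty((n, m))
    for j, item in enumerate(bank):
        probs = category_probabilities(item, theta)        # (K, n)
        exp = np.arange(item.n_categories) @ probs         # (n,)
        codes = responses.values[:, j]
        obs = ~responses.missing_mask[:, j]
        sq[:, j] = np.where(obs, (codes - exp) ** 2, np.nan)
        pr[:, j] = np.where(obs, probs[np.clip(codes, 0, None), np.arange(n)],
                            np.nan)
    return sq, pr


@dataclass
class LQRFeatureTable:
    """Predictor table of LQR indices plus optional demographics.

    ``frame`` holds one row per respondent; ``metadata`` records which
    scales contributed, the column layout mode, and provenance per column.
    """

    frame: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def columns(self) -> list[str]:
        return self.frame.columns.tolist()

    def to_csv(self, path, sidecar: bool = True) -> None:
        self.frame.to_csv(path, index_label="respondent_id",
                          float_format="%.10g")
        if sidecar:
            side = str(path) + ".meta.json"
            with open(side, "w") as fh:
                json.dump(self.metadata, fh, indent=2, sort_keys=True)
                fh.write("\n")


def build_feature_table(
    responses: ResponseMatrix,
    banks: Mapping[str, Sequence[ItemParameters]],
    cohort: pd.DataFrame | None = None,
    scales: Sequence[str] | None = None,
    include_demographics: bool = False,
    aggregate: bool = False,
    log_probability: bool = False,
    traits: Mapping[str, pd.DataFrame] | None = None,
    quad: QuadratureConfig | None = None,
) -> LQRFeatureTable:
    """Assemble the LQR predictor table.

    The latent trait is estimated per scale from that scale's own items
    (unless precomputed ``traits`` are supplied), then both indices are
    computed for every item of the selected scales.  Missing responses
    yield missing features; impute either the responses beforehand or the
    features afterwards.

    Parameters
    ----------
    responses : ResponseMatrix
        Full response matrix; must contain every item of each selected scale.
    banks : mapping scale -> fitted item bank
    cohort : DataFrame, optional
        Needed when ``include_demographics`` to supply age and gender.
    scales : sequence of str, optional
        Scale selection; defaults to all keys of ``banks``.  Multiple
        scales concatenate their feature blocks.
    aggregate : bool
        Collapse to per-scale mean squared residual and mean log
        probability (2 columns per scale) instead of 2 per item.
    log_probability : bool
        Emit log(p) instead of raw probabilities in per-item mode.
    """
    chosen = list(scales) if scales is not None else list(banks.keys())
    for s in chosen:
        if s not in banks:
            raise ValueError(f"unknown scale {s!r}; have {sorted(banks)}")

    blocks: list[pd.DataFrame] = []
    provenance: dict[str, str] = {}
    for scale in chosen:
        bank = list(banks[scale])
        sub = responses.subset_items([it.item_id for it in bank])
        if traits is not None and scale in traits:
            theta = np.asarray(traits[scale]["theta"], dtype=float)
        else:
            theta = eap_scores(sub, bank, quad)["theta"].to_numpy()
        sq, pr = _matrix_indices(sub, bank, theta)
        if aggregate:
            with np.errstate(invalid="ignore"):
                block = pd.DataFrame(
                    {
                        f"{scale}_mean_sqres": np.nanmean(sq, axis=1),
                        f"{scale}_mean_logprob": np.nanmean(np.log(pr), axis=1),
                    },
                    index=sub.respondent_ids,
                )
            provenance[f"{scale}_mean_sqres"] = f"scale {scale}: mean s_ij"
            provenance[f"{scale}_mean_logprob"] = f"scale {scale}: mean log p_ij"
        else:
            cols: dict[str, np.ndarray] = {}
            for j, item in enumerate(bank):
                cols[f"{item.item_id}_sqres"] = sq[:, j]
                provenance[f"{item.item_id}_sqres"] = (
                    f"scale {scale}: squared residual of {item.item_id}"
                )
                pcol = np.log(pr[:, j]) if log_probability else pr[:, j]
                name = f"{item.item_id}_logprob" if log_probability else \
                    f"{item.item_id}_prob"
                cols[name] = pcol
                provenance[name] = (
                    f"scale {scale}: observed-response probability of "
                    f"{item.item_id}"
                )
            block = pd.DataFrame(cols, index=sub.respondent_ids)
        blocks.append(block)

    frame = pd.concat(blocks, axis=1)
    if include_demographics:
        if cohort is None:
            raise ValueError("include_demographics requires a cohort table")
        for col in DEMOGRAPHIC_COLUMNS:
            if col not in cohort.columns:
                raise ValueError(f"cohort lacks demographic column {col!r}")
            frame[col] = cohort.loc[frame.index, col].to_numpy(dtype=float)
            provenance[col] = "demographics"

    metadata = {
        "scales": chosen,
        "aggregate": aggregate,
        "log_probability": log_probability,
        "include_demographics": include_demographics,
        "columns": provenance,
    }
    return LQRFeatureTable(frame, metadata)
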