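"""End-to-end screening pipeline: simulate/ingest -> impute -> fit GRM ->
LQR features -> train -> threshold -> evaluate.

A validated :class:`RunConfig` drives every stage; all randomness derives
from its single seed, and every artifact (responses, cohort, item banks,
features, model, decision, report) is written with a manifest of content
hashes, so identical configurations reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .cohort import (
    DEFAULT_SCALES,
    CohortConfig,
    assign_cognition_scores,
    generate_scale_banks,
    simulate_cohort,
    save_truth,
)
from .decision import CostRatio, select_threshold
from .evaluation import STANDARD_RULES, rule_point, stratified_report
from .features import build_feature_table
from .fileio import file_sha256, write_cohort, write_json, write_responses
from .grm import GradedResponseModel, QuadratureConfig, ResponseMatrix, save_item_bank
from .models import (
    CVConfig,
    MLPConfig,
    TrainedModel,
    predict_risk,
    train_baseline,
    train_mlp,
    train_raw_response_baseline,
)
from .preprocess import SplitSpec, iterative_impute, stratified_split

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


class CohortParams(BaseModel):
    """Synthetic-cohort knobs (see :class:`lqrscreen.cohort.CohortConfig`)."""

    model_config = ConfigDict(extra="forbid")

    n_respondents: int = Field(2000, ge=2)
    prevalence: float = Field(0.18, gt=0, lt=1)
    careless_rate_normal: float = Field(0.05, ge=0, le=1)
    careless_rate_impaired: float = Field(0.45, ge=0, le=1)
    skip_rate_normal: float = Field(0.01, ge=0, le=1)
    skip_rate_impaired: float = Field(0.03, ge=0, le=1)
    straightline_fraction: float = Field(0.25, ge=0, le=1)
    trait_impairment_shift: float = -0.1
    age_impairment_log_or: float = 0.0


class FeatureParams(BaseModel):
    model_config = ConfigDict(extra="forbid")

    scales: Optional[list[str]] = None  # None = all simulated scales
    include_demographics: bool = False
    aggregate: bool = False
    log_probability: bool = False


class ModelParams(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kind: Literal["mlp", "logistic", "tree", "gradient_boosting"] = "mlp"
    n_folds: int = Field(10, ge=1)
    inner_validation_fraction: float = Field(0.20, gt=0, lt=1)
    hidden_layers: list[int] = [64, 32, 16, 8]
    dropout: float = Field(0.2, ge=0, lt=1)
    max_epochs: int = Field(200, ge=1)
    batch_size: int = Field(128, ge=2)


class RunConfig(BaseModel):
    """Validated end-to-end run configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    cohort: CohortParams = CohortParams()
    features: FeatureParams = FeatureParams()
    model: ModelParams = ModelParams()
    cost_ratio: float = Field(4.0, gt=0)
    test_fraction: float = Field(0.30, gt=0, lt=1)
    impute_target: Literal["responses", "features"] = "responses"
    train_raw_baseline: bool = False
    seed: int = Field(0, ge=0, lt=2**31)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def config_hash(self) -> str:
        canon = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


@dataclass
class PipelineResult:
    """Artifacts of one end-to-end run."""

    config: RunConfig
    banks: dict
    cohort: pd.DataFrame
    responses: ResponseMatrix
    feature_table: object
    model: TrainedModel
    decision: object
    report: object
    raw_baseline_report: object | None
    manifest: dict


def _derive_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % 2**31


def run_pipeline(config: RunConfig, out_dir: str | os.PathLike) -> PipelineResult:
    """Execute the full screening workflow and write all artifacts.

    Stage order follows the study design: the cohort's responses are
    imputed first (by default), each scale's GRM is fitted to the full
    imputed data, LQR features are assembled, the cohort is split with
    matched impairment prevalence, the risk model is trained on the
    training partition only, the referral threshold is tuned on pooled
    validation predictions, and the report is computed on the held-out
    test partition.
    """
    os.makedirs(out_dir, exist_ok=True)
    seed = config.seed
    cc = config.cohort

    # -- simulate -------------------------------------------------------
    cohort_cfg = CohortConfig(
        n_respondents=cc.n_respondents,
        scales=DEFAULT_SCALES,
        prevalence=cc.prevalence,
        careless_rate_normal=cc.careless_rate_normal,
        careless_rate_impaired=cc.careless_rate_impaired,
        skip_rate_normal=cc.skip_rate_normal,
        skip_rate_impaired=cc.skip_rate_impaired,
        straightline_fraction=cc.straightline_fraction,
        trait_impairment_shift=cc.trait_impairment_shift,
        age_impairment_log_or=cc.age_impairment_log_or,
        seed=_derive_seed(seed, "cohort"),
    )
    true_banks = generate_scale_banks(cohort_cfg.scales, cohort_cfg.seed)
    responses, cohort = simulate_cohort(cohort_cfg, true_banks)
    cohort = assign_cognition_scores(cohort, _derive_seed(seed, "scores"))
    write_responses(responses, os.path.join(out_dir, "responses.csv"))
    write_cohort(cohort, os.path.join(out_dir, "cohort.csv"))
    save_truth(cohort, true_banks, os.path.join(out_dir, "truth.json"))

    # -- impute ---------------------------------------------------------
    resp_df = responses.to_dataframe()
    bounds = dict(zip(responses.item_ids, responses.n_categories))
    if config.impute_target == "responses" and resp_df.isna().any().any():
        completed = iterative_impute(
            resp_df, seed=_derive_seed(seed, "impute"), category_bounds=bounds
        )
        responses_c = ResponseMatrix.from_dataframe(
            completed, n_categories=responses.n_categories
        )
    else:
        responses_c = responses

    # -- fit one GRM per scale -----------------------------------------
    quad = QuadratureConfig()
    banks = {}
    fit_meta = {}
    bank_dir = os.path.join(out_dir, "banks")
    os.makedirs(bank_dir, exist_ok=True)
    for name, n_items, _k in cohort_cfg.scales:
        ids = [it.item_id for it in true_banks[name]]
        res = GradedResponseModel(responses_c.subset_items(ids), quad).fit()
        banks[name] = res.item_parameters
        fit_meta[name] = {
            "llf": res.llf, "n_iter": res.n_iter, "converged": res.converged,
        }
        save_item_bank(res.item_parameters,
                       os.path.join(bank_dir, f"{name}.json"))
    write_json(fit_meta, os.path.join(out_dir, "grm_fit.json"))

    # -- features -------------------------------------------------------
    fp = config.features
    table = build_feature_table(
        responses_c, banks, cohort=cohort,
        scales=fp.scales,
        include_demographics=fp.include_demographics,
        aggregate=fp.aggregate,
        log_probability=fp.log_probability,
        quad=quad,
    )
    frame = table.frame
    if frame.isna().any().any():  # impute_target == "features", or skips kept
        frame = iterative_impute(frame, seed=_derive_seed(seed, "impute"))
        table.frame = frame
    table.to_csv(os.path.join(out_dir, "features.csv"))

    # -- split ----------------------------------------------------------
    y = cohort["impairment"].to_numpy()
    train_idx, test_idx = stratified_split(
        y, SplitSpec(test_fraction=config.test_fraction,
                     seed=_derive_seed(seed, "split")),
    )
    manifest_split = pd.DataFrame(
        {"partition": np.where(np.isin(np.arange(y.size), test_idx),
                               "test", "train")},
        index=cohort.index,
    )
    manifest_split.to_csv(os.path.join(out_dir, "split_manifest.csv"),
                          index_label="respondent_id")

    # -- train ----------------------------------------------------------
    mp = config.model
    cv = CVConfig(n_folds=mp.n_folds,
                  inner_validation_fraction=mp.inner_validation_fraction)
    x_train, x_test = frame.iloc[train_idx], frame.iloc[test_idx]
    y_train, y_test = y[train_idx], y[test_idx]
    model_seed = _derive_seed(seed, "model")
    if mp.kind == "mlp":
        mlp_cfg = MLPConfig(hidden_layers=tuple(mp.hidden_layers),
                            dropout=mp.dropout, max_epochs=mp.max_epochs,
                            batch_size=mp.batch_size)
        model = train_mlp(x_train, y_train, mlp_cfg, cv, seed=model_seed)
    else:
        model = train_baseline(mp.kind, x_train, y_train, cv=cv,
                               seed=model_seed)
    model.save(os.path.join(out_dir, "model"))

    # -- threshold on pooled validation predictions --------------------
    val = model.validation_scores
    decision = select_threshold(val["score"].to_numpy(),
                                val["label"].to_numpy(),
                                CostRatio(config.cost_ratio))
    decision.to_json(os.path.join(out_dir, "decision.json"))

    # -- evaluate on the held-out test partition ------------------------
    test_scores = predict_risk(model, x_test)
    report = stratified_report(
        test_scores, y_test, cohort.iloc[test_idx],
        decision=decision, model_id=mp.kind,
        feature_set="+".join(table.metadata["scales"])
        + ("+demographics" if fp.include_demographics else ""),
    )
    report.to_json(os.path.join(out_dir, "report.json"))
    report.by_age_group.to_csv(os.path.join(out_dir, "report_by_age.csv"),
                               float_format="%.10g")

    rules = {
        name: rule_point(cohort.iloc[test_idx], rule, labels=y_test)
        for name, rule in STANDARD_RULES.items()
    }
    write_json(
        {k: {"proportion_referred": v[0], "proportion_identified": v[1]}
         for k, v in rules.items()},
        os.path.join(out_dir, "rule_points.json"),
    )

    raw_report = None
    if config.train_raw_baseline:
        raw_model = train_raw_response_baseline(
            responses_c.to_dataframe().iloc[train_idx], y_train, cv=cv,
            seed=model_seed,
        )
        raw_scores = predict_risk(
            raw_model, responses_c.to_dataframe().iloc[test_idx]
        )
        raw_report = stratified_report(
            raw_scores, y_test, cohort.iloc[test_idx],
            cost=CostRatio(config.cost_ratio),
            model_id="raw_response_logistic", feature_set="raw responses",
        )
        raw_report.to_json(os.path.join(out_dir, "report_raw_baseline.json"))

    # -- manifest -------------------------------------------------------
    artifacts = sorted(
        os.path.relpath(os.path.join(root, f), out_dir)
        for root, _dirs, files in os.walk(out_dir)
        for f in files
        if f != "manifest.json"
    )
    manifest = {
        "package_version": __version__,
        "config": config.model_dump(),
        "config_hash": config.config_hash(),
        "seed": seed,
        "artifact_hashes": {
            a: file_sha256(os.path.join(out_dir, a)) for a in artifacts
        },
    }
    write_json(manifest, os.path.join(out_dir, "manifest.json"))

    return PipelineResult(
        config=config, banks=banks, cohort=cohort, responses=responses_c,
        feature_table=table, model=model, decision=decision, report=report,
        raw_baseline_report=raw_report, manifest=manifest,
    )
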