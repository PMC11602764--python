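"""Synthetic cohort generator: determinism, LQR injection, label truth."""

import numpy as np
import pytest
from scipy import stats

from lqrscreen.cohort import (
    DEFAULT_SCALES,
    CohortConfig,
    assign_cognition_scores,
    generate_item_bank,
    generate_scale_banks,
    simulate_cohort,
)
from lqrscreen.grm import category_probabilities
from lqrscreen.preprocess import derive_ci_labels


class TestItemBankGeneration:
    @pytest.mark.parametrize("n_items,k", [(6, 6), (1, 2), (7, 4)])
    def test_invariants(self, n_items, k):
        bank = generate_item_bank(n_items, k, seed=1)
        assert len(bank) == n_items
        for item in bank:
            assert item.discrimination > 0
            assert len(item.thresholds) == k - 1
            assert all(np.diff(item.thresholds) > 0)
            assert min(item.thresholds) >= -2.5
            assert max(item.thresholds) <= 2.5

    def test_deterministic_given_seed(self):
        assert generate_item_bank(6, 6, seed=7) == generate_item_bank(6, 6, seed=7)
        assert generate_item_bank(6, 6, seed=7) != generate_item_bank(6, 6, seed=8)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            generate_item_bank(0, 6, seed=1)
        with pytest.raises(ValueError):
            generate_item_bank(3, 1, seed=1)


class TestSimulateCohort:
    def test_deterministic_given_seed(self):
        cfg = CohortConfig(n_respondents=200, seed=5)
        r1, c1 = simulate_cohort(cfg)
        r2, c2 = simulate_cohort(cfg)
        assert np.array_equal(r1.values, r2.values)
        assert np.array_equal(r1.missing_mask, r2.missing_mask)
        assert c1.equals(c2)

    def test_all_skip_yields_all_missing(self):
        cfg = CohortConfig(
            n_respondents=50, scales=(("s", 4, 5),),
            careless_rate_normal=0.0, careless_rate_impaired=0.0,
            skip_rate_normal=1.0, skip_rate_impaired=1.0, seed=2,
        )
        responses, _ = simulate_cohort(cfg)
        assert responses.missing_mask.all()

    def test_prevalence_within_binomial_interval(self):
        cfg = CohortConfig(n_respondents=10_000, prevalence=0.18, seed=3)
        _, cohort = simulate_cohort(cfg)
        p_hat = cohort["impairment"].mean()
        half = 2.576 * np.sqrt(0.18 * 0.82 / 10_000)
        assert abs(p_hat - 0.18) <= half

    def test_pure_grm_category_frequencies_match_model(self, item_bank):
        """Without LQR, empirical category shares equal the GRM
        probabilities averaged over the drawn traits (3 MC SEs)."""
        cfg = CohortConfig(
            n_respondents=5000, scales=(("s", 6, 6),),
            careless_rate_normal=0.0, careless_rate_impaired=0.0,
            skip_rate_normal=0.0, skip_rate_impaired=0.0,
            trait_impairment_shift=0.0, seed=4,
        )
        responses, cohort = simulate_cohort(cfg, {"s": item_bank})
        theta = cohort["true_theta_s"].to_numpy()
        for j, item in enumerate(item_bank):
            expected = category_probabilities(item, theta).mean(axis=1)
            counts = np.bincount(responses.values[:, j], minlength=6)
            observed = counts / 5000
            se = np.sqrt(expected * (1 - expected) / 5000)
            assert np.all(np.abs(observed - expected) <= 3 * se + 1e-9)

    def test_impaired_group_skips_more(self):
        cfg = CohortConfig(
            n_respondents=8000, skip_rate_normal=0.01,
            skip_rate_impaired=0.10, seed=6,
        )
        responses, cohort = simulate_cohort(cfg)
        imp = cohort["impairment"].to_numpy(dtype=bool)
        assert (responses.missing_mask[imp].mean()
                > responses.missing_mask[~imp].mean())

    def test_straightlined_rows_have_lower_variance(self):
        """Careless straight-lining depresses within-respondent response
        variance relative to honest GRM responding."""
        base = dict(n_respondents=1000, scales=(("s", 6, 6),),
                    skip_rate_normal=0.0, skip_rate_impaired=0.0,
                    trait_impairment_shift=0.0, seed=7)
        honest, _ = simulate_cohort(CohortConfig(
            careless_rate_normal=0.0, careless_rate_impaired=0.0, **base))
        lined, _ = simulate_cohort(CohortConfig(
            careless_rate_normal=1.0, careless_rate_impaired=1.0,
            straightline_fraction=1.0, **base))
        assert (lined.values.var(axis=1).mean()
                < honest.values.var(axis=1).mean())

    def test_no_group_difference_when_rates_equal(self):
        """With equal LQR rates and no trait shift the response
        distribution is exchangeable across impairment groups."""
        pvals = []
        for seed in range(20):
            cfg = CohortConfig(
                n_respondents=600, scales=(("s", 6, 6),),
                careless_rate_normal=0.1, careless_rate_impaired=0.1,
                skip_rate_normal=0.0, skip_rate_impaired=0.0,
                trait_impairment_shift=0.0, seed=1000 + seed,
            )
            responses, cohort = simulate_cohort(cfg)
            imp = cohort["impairment"].to_numpy(dtype=bool)
            means = responses.values.mean(axis=1)
            pvals.append(stats.ttest_ind(means[imp], means[~imp]).pvalue)
        # at alpha = 0.01, expect ~0.2 rejections in 20 replicates
        assert np.sum(np.asarray(pvals) < 0.01) <= 2

    def test_flat_bank_accepted_and_length_checked(self, item_bank):
        cfg = CohortConfig(n_respondents=50, scales=(("s", 6, 6),), seed=1)
        responses, _ = simulate_cohort(cfg, list(item_bank))
        assert responses.shape == (50, 6)
        with pytest.raises(ValueError):
            simulate_cohort(cfg, list(item_bank)[:5])

    def test_config_validation(self):
        with pytest.raises(ValueError):
            CohortConfig(n_respondents=1)
        with pytest.raises(ValueError):
            CohortConfig(n_respondents=10, prevalence=0.0)
        with pytest.raises(ValueError):
            CohortConfig(n_respondents=10, careless_rate_normal=1.2)
        with pytest.raises(ValueError):
            CohortConfig(n_respondents=10, careless_rate_normal=0.8,
                         skip_rate_normal=0.5)


class TestCognitionScores:
    def test_bands_respect_labels_and_roundtrip(self):
        cfg = CohortConfig(n_respondents=500, seed=9)
        _, cohort = simulate_cohort(cfg)
        scored = assign_cognition_scores(cohort, seed=1)
        scores = scored["cognition_score"]
        imp = scored["impairment"].astype(bool)
        assert scores.between(0, 27).all()
        assert scores[imp].between(0, 11).all()
        assert scores[~imp].between(12, 27).all()
        derived = derive_ci_labels(scores.to_numpy())
        assert (derived["binary_ci"].to_numpy() == imp.to_numpy()).all()

    def test_missing_label_column_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError, match="impairment"):
            assign_cognition_scores(pd.DataFrame({"age": [60]}), seed=0)


def test_default_scales_match_study_layout():
    names = [s[0] for s in DEFAULT_SCALES]
    assert names == ["optimism", "hopelessness", "purpose", "life_satisfaction"]
    assert [s[1] for s in DEFAULT_SCALES] == [6, 7, 7, 5]


def test_scale_banks_are_reproducible():
    b1 = generate_scale_banks(DEFAULT_SCALES, seed=3)
    b2 = generate_scale_banks(DEFAULT_SCALES, seed=3)
    assert b1 == b2
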