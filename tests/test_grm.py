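"""Graded response model: probability kernels, EM estimation, EAP scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lqrscreen.grm import (
    EstimationError,
    GradedResponseModel,
    ItemParameters,
    QuadratureConfig,
    ResponseMatrix,
    category_probabilities,
    eap_scores,
    estimate_theta_eap,
    expected_response,
    load_item_bank,
    save_item_bank,
)

SYM_ITEM = ItemParameters("sym", 1.5, (-1.0, 1.0))


class TestItemParameters:
    def test_rejects_nonpositive_discrimination(self):
        with pytest.raises(ValueError, match="discrimination"):
            ItemParameters("x", 0.0, (0.0,))

    def test_rejects_unordered_thresholds(self):
        with pytest.raises(ValueError, match="increasing"):
            ItemParameters("x", 1.0, (0.5, 0.5))

    def test_json_roundtrip(self, item_bank, tmp_path):
        path = tmp_path / "bank.json"
        save_item_bank(item_bank, path)
        again = load_item_bank(path)
        assert again == item_bank


class TestCategoryProbabilities:
    def test_dichotomous_item_at_threshold_splits_evenly(self):
        p = category_probabilities(ItemParameters("d", 1.0, (0.0,)), 0.0)
        np.testing.assert_allclose(p, [0.5, 0.5], atol=1e-15)

    def test_symmetric_three_category_closed_form(self):
        # P*_1(0) = logistic(1.5), P*_2(0) = logistic(-1.5)
        p = category_probabilities(SYM_ITEM, 0.0)
        np.testing.assert_allclose(p, [0.18243, 0.63515, 0.18243], atol=1e-5)

    def test_mass_moves_to_top_category_at_large_theta(self):
        p = category_probabilities(SYM_ITEM, 40.0)
        assert p[-1] > 1 - 1e-12

    @given(
        a=st.floats(0.2, 3.0),
        b1=st.floats(-2.0, 0.0),
        gap=st.floats(0.1, 2.0),
        theta=st.floats(-5.0, 5.0),
    )
    def test_normalisation_and_nonnegativity(self, a, b1, gap, theta):
        item = ItemParameters("h", a, (b1, b1 + gap, b1 + 2 * gap))
        p = category_probabilities(item, theta)
        assert np.all(p >= 0)
        assert abs(p.sum() - 1.0) < 1e-12

    def test_cumulative_curves_monotone_in_theta_and_k(self, item_bank):
        from lqrscreen.grm import _cumulative_probs

        thetas = np.linspace(-5, 5, 101)
        for item in item_bank:
            cum = _cumulative_probs(item, thetas)
            assert np.all(np.diff(cum, axis=1) > 0)       # increasing in theta
            assert np.all(np.diff(cum, axis=0) < 0)       # decreasing in k


class TestExpectedResponse:
    def test_symmetric_item_at_zero_is_middle_category(self):
        assert expected_response(SYM_ITEM, 0.0) == pytest.approx(1.0, abs=1e-12)

    def test_limits(self):
        assert expected_response(SYM_ITEM, -40.0) == pytest.approx(0.0, abs=1e-12)
        assert expected_response(SYM_ITEM, 40.0) == pytest.approx(2.0, abs=1e-12)

    def test_strictly_increasing_in_theta(self, item_bank):
        grid = np.linspace(-4, 4, 100)
        for item in item_bank:
            vals = expected_response(item, grid)
            assert np.all(np.diff(vals) > 0)


class TestFit:
    def test_parameter_recovery_on_clean_data(self, item_bank, clean_cohort):
        responses, _ = clean_cohort
        model = GradedResponseModel(responses)
        res = model.fit()
        a_err = [
            hat.discrimination - true.discrimination
            for hat, true in zip(res.item_parameters, item_bank)
        ]
        b_err = np.concatenate([
            np.subtract(hat.thresholds, true.thresholds)
            for hat, true in zip(res.item_parameters, item_bank)
        ])
        assert np.sqrt(np.mean(np.square(a_err))) <= 0.15
        assert np.sqrt(np.mean(b_err**2)) <= 0.15
        # MLE dominates the generating parameters on its training data
        assert res.llf >= model.loglike(item_bank)

    def test_em_loglik_nondecreasing(self, clean_cohort):
        responses, _ = clean_cohort
        res = GradedResponseModel(responses).fit()
        trace = np.asarray(res.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-8)

    def test_fitted_trait_scale_is_anchored(self, clean_cohort):
        responses, _ = clean_cohort
        res = GradedResponseModel(responses).fit()
        theta = res.eap()["theta"]
        assert abs(theta.mean()) < 0.1
        assert 0.85 <= theta.std() <= 1.15

    def test_single_observed_category_names_item(self):
        df = pd.DataFrame({"ok": [0, 1, 2, 1, 0, 2], "flat": [0] * 6})
        with pytest.raises(EstimationError, match="flat"):
            GradedResponseModel(df).fit()

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            GradedResponseModel(pd.DataFrame())


class TestEAP:
    def test_all_missing_row_returns_prior(self, item_bank):
        est = estimate_theta_eap([np.nan] * 6, item_bank)
        assert est.theta == pytest.approx(0.0, abs=1e-12)
        assert est.posterior_sd == pytest.approx(1.0, abs=1e-6)

    def test_posterior_sd_never_exceeds_prior(self, item_bank, clean_cohort):
        responses, _ = clean_cohort
        sd = eap_scores(responses, item_bank)["posterior_sd"]
        assert np.all(sd <= 1.0 + 1e-8)

    def test_matches_dense_grid_oracle(self, item_bank, clean_cohort):
        responses, _ = clean_cohort
        eap = eap_scores(responses, item_bank)
        grid = np.linspace(-6, 6, 10_001)
        w = np.exp(-0.5 * grid**2)
        w[[0, -1]] *= 0.5
        logp = [np.log(category_probabilities(it, grid)) for it in item_bank]
        rng = np.random.default_rng(0)
        for i in rng.choice(responses.shape[0], 25, replace=False):
            ll = np.log(w).copy()
            for j in range(6):
                if not responses.missing_mask[i, j]:
                    ll += logp[j][responses.values[i, j]]
            wgt = np.exp(ll - ll.max())
            wgt /= wgt.sum()
            mean = wgt @ grid
            sd = np.sqrt(wgt @ grid**2 - mean**2)
            assert abs(mean - eap["theta"].iloc[i]) < 1e-6
            assert abs(sd - eap["posterior_sd"].iloc[i]) < 1e-6

    def test_higher_category_never_decreases_eap(self, item_bank):
        rng = np.random.default_rng(42)
        for _ in range(20):
            row = rng.integers(0, 6, size=6).astype(float)
            j = rng.integers(0, 6)
            if row[j] == 5:
                row[j] = 4
            bumped = row.copy()
            bumped[j] += 1
            low = estimate_theta_eap(row, item_bank).theta
            high = estimate_theta_eap(bumped, item_bank).theta
            assert high >= low

    def test_gauss_hermite_agrees_with_equal_grid(self, item_bank):
        row = [2, 3, 1, 4, 2, np.nan]
        eq = estimate_theta_eap(row, item_bank, QuadratureConfig())
        gh = estimate_theta_eap(
            row, item_bank, QuadratureConfig(n_nodes=61, scheme="gauss-hermite")
        )
        assert eq.theta == pytest.approx(gh.theta, abs=1e-6)


class TestResponseMatrix:
    def test_dataframe_roundtrip_preserves_missing(self, clean_cohort):
        responses, _ = clean_cohort
        df = responses.to_dataframe()
        again = ResponseMatrix.from_dataframe(df, responses.n_categories)
        assert np.array_equal(again.missing_mask, responses.missing_mask)
        obs = ~responses.missing_mask
        assert np.array_equal(again.values[obs], responses.values[obs])

    def test_out_of_range_code_rejected(self):
        df = pd.DataFrame({"a": [0, 7]})
        with pytest.raises(ValueError, match="exceeds"):
            ResponseMatrix.from_dataframe(df, n_categories=[6])
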