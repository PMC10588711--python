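"""Model core: linear predictor, logistic link, likelihood, priors."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from birt import (
    ModelSpec,
    ParameterSet,
    ResponseData,
    linear_predictor,
    log_likelihood,
    log_posterior,
    log_prior,
    response_probability,
)

from conftest import random_parameter_set, random_response_data


# ---------------------------------------------------------------------------
# independent oracle: literal transcription of the model formulas
# ---------------------------------------------------------------------------

def oracle_log_posterior(params, data, spec):
    total = 0.0
    for i, j, r in zip(data.item_ids, data.taker_ids, data.responses):
        z = params.theta[j] - params.beta[i]
        if spec.is_two_pl:
            z = params.alpha[i] * z
        p = 1.0 / (1.0 + math.exp(-z))
        total += math.log(p) if r == 1 else math.log(1.0 - p)
    for t in params.theta:
        total += norm.logpdf(t, loc=spec.theta_prior_mean,
                             scale=math.sqrt(spec.theta_prior_var))
    for b in params.beta:
        total += norm.logpdf(b, loc=spec.beta_prior_mean,
                             scale=math.sqrt(spec.beta_prior_var))
    if spec.is_two_pl:
        for a in params.alpha:
            total += norm.logpdf(math.log(a), loc=spec.logalpha_prior_mean,
                                 scale=math.sqrt(spec.logalpha_prior_var))
    return total


class TestLinearPredictor:
    def test_one_pl_is_ability_minus_difficulty(self, one_pl):
        p = ParameterSet(theta=[2.0], beta=[2.0])
        assert linear_predictor(p, 0, 0, one_pl) == 0.0

    def test_two_pl_scales_by_discrimination(self, two_pl):
        p = ParameterSet(theta=[1.5], beta=[0.5], alpha=[2.0])
        assert linear_predictor(p, 0, 0, two_pl) == pytest.approx(2.0)

    def test_nonpositive_discrimination_rejected(self):
        with pytest.raises(ValueError):
            ParameterSet(theta=[0.0], beta=[0.0], alpha=[0.0])

    def test_missing_alpha_under_two_pl_is_configuration_error(self, two_pl):
        p = ParameterSet(theta=[0.0], beta=[0.0])
        with pytest.raises(ValueError):
            linear_predictor(p, 0, 0, two_pl)

    def test_out_of_range_indices_rejected(self, one_pl):
        p = ParameterSet(theta=[0.0], beta=[0.0])
        with pytest.raises(IndexError):
            linear_predictor(p, 1, 0, one_pl)


class TestResponseProbability:
    @pytest.mark.parametrize("z,expected", [
        (0.0, 0.5),
        (2.0, 0.8807970779778823),
    ])
    def test_known_values(self, z, expected):
        assert response_probability(z) == pytest.approx(expected, abs=1e-15)

    @given(st.floats(-700, 700))
    @settings(derandomize=True, max_examples=50)
    def test_antisymmetry(self, z):
        assert response_probability(-z) == pytest.approx(
            1.0 - response_probability(z), abs=1e-12)

    def test_stable_at_extreme_predictors(self):
        assert response_probability(700.0) == pytest.approx(1.0)
        assert response_probability(-700.0) == pytest.approx(0.0, abs=1e-300)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            response_probability(np.inf)

    @given(st.floats(-30, 30), st.floats(0.01, 30))
    @settings(derandomize=True, max_examples=50)
    def test_strictly_increasing(self, z, dz):
        assert response_probability(z + dz) > response_probability(z)


class TestResponseData:
    def test_rejects_non_binary_responses(self):
        with pytest.raises(ValueError):
            ResponseData.from_records([(0, 0, 2)])

    def test_rejects_duplicate_cells(self):
        with pytest.raises(ValueError):
            ResponseData.from_records([(0, 0, 1), (0, 0, 0)])

    def test_fitting_requires_full_roster_coverage(self):
        d = ResponseData.from_records([(0, 0, 1)], n_items=2, n_takers=1)
        with pytest.raises(ValueError):
            d.validate(for_fitting=True)

    def test_csv_round_trip(self, tiny_data, tmp_path):
        path = tmp_path / "resp.csv"
        tiny_data.to_csv(path)
        assert ResponseData.from_csv(path) == tiny_data
        header = path.read_text().splitlines()[0]
        assert header == "item_id,taker_id,response"


class TestLogLikelihood:
    def test_all_half_probability_configuration(self, one_pl):
        data = ResponseData.from_records(
            [(i, j, (i + j) % 2) for i in range(2) for j in range(2)])
        params = ParameterSet(theta=[0.7, 0.7], beta=[0.7, 0.7])
        assert log_likelihood(params, data, one_pl) == pytest.approx(
            4 * math.log(0.5), abs=1e-12)

    def test_near_certain_correct_response(self, one_pl):
        data = ResponseData.from_records([(0, 0, 1)])
        params = ParameterSet(theta=[20.0], beta=[0.0])
        # log(logistic(20)) ~ -2.06e-9
        assert log_likelihood(params, data, one_pl) == pytest.approx(
            math.log(1.0 / (1.0 + math.exp(-20.0))), rel=1e-12)

    def test_record_order_does_not_change_value(self, one_pl):
        rng = np.random.default_rng(0)
        data = random_response_data(rng, 5, 4)
        params = random_parameter_set(rng, 5, 4, two_pl=False)
        perm = rng.permutation(data.n_records)
        shuffled = ResponseData(data.item_ids[perm], data.taker_ids[perm],
                                data.responses[perm], data.n_items, data.n_takers)
        assert log_likelihood(params, data, one_pl) == log_likelihood(
            params, shuffled, one_pl)

    def test_empty_data_rejected(self, one_pl):
        empty = ResponseData.from_records([], n_items=1, n_takers=1)
        params = ParameterSet(theta=[0.0], beta=[0.0])
        with pytest.raises(ValueError):
            log_likelihood(params, empty, one_pl)


class TestLogPrior:
    def test_single_ability_at_prior_mean(self, one_pl):
        params = ParameterSet(theta=[0.0], beta=np.empty(0))
        assert log_prior(params, one_pl) == pytest.approx(-0.5 * math.log(4 * math.pi),
                                                          abs=1e-9)

    def test_discrimination_term_at_its_mode(self, two_pl):
        params = ParameterSet(theta=np.empty(0), beta=[0.0], alpha=[math.exp(0.5)])
        beta_term = -0.5 * math.log(4 * math.pi)
        expected = beta_term - 0.5 * math.log(2 * math.pi)
        assert log_prior(params, two_pl) == pytest.approx(expected, abs=1e-9)

    def test_maximized_at_prior_means(self, two_pl):
        rng = np.random.default_rng(1)
        mode = ParameterSet(theta=[0.0, 0.0], beta=[0.0], alpha=[math.exp(0.5)])
        best = log_prior(mode, two_pl)
        for _ in range(20):
            other = random_parameter_set(rng, 1, 2, two_pl=True)
            assert log_prior(other, two_pl) <= best


class TestLogPosterior:
    def test_closed_form_single_cell(self, one_pl):
        data = ResponseData.from_records([(0, 0, 1)])
        params = ParameterSet(theta=[0.0], beta=[0.0])
        expected = math.log(0.5) + 2 * (-0.5 * math.log(4 * math.pi))
        assert log_posterior(params, data, one_pl) == pytest.approx(expected, abs=1e-8)

    def test_is_sum_of_likelihood_and_prior(self, tiny_data, one_pl):
        params = ParameterSet(theta=[0.3, -0.4], beta=[0.1, 0.9, -1.1])
        assert log_posterior(params, tiny_data, one_pl) == pytest.approx(
            log_likelihood(params, tiny_data, one_pl) + log_prior(params, one_pl))

    @pytest.mark.parametrize("use_two_pl", [False, True])
    def test_matches_brute_force_oracle(self, use_two_pl, one_pl, two_pl):
        """Vectorized log-posterior agrees with a literal transcription to 1e-10."""
        spec = two_pl if use_two_pl else one_pl
        rng = np.random.default_rng(123)
        for _ in range(100):
            n_items = int(rng.integers(1, 6))
            n_takers = int(rng.integers(1, 5))
            data = random_response_data(rng, n_items, n_takers)
            params = random_parameter_set(rng, n_items, n_takers, use_two_pl)
            assert log_posterior(params, data, spec) == pytest.approx(
                oracle_log_posterior(params, data, spec), abs=1e-10)

    def test_monotone_in_ability_for_correct_responses(self, two_pl):
        """p increases with theta and decreases with beta at fixed alpha > 0."""
        base = ParameterSet(theta=[0.2], beta=[0.1], alpha=[1.3])
        z0 = linear_predictor(base, 0, 0, two_pl)
        higher = ParameterSet(theta=[0.8], beta=[0.1], alpha=[1.3])
        harder = ParameterSet(theta=[0.2], beta=[0.9], alpha=[1.3])
        assert response_probability(linear_predictor(higher, 0, 0, two_pl)) > response_probability(z0)
        assert response_probability(linear_predictor(harder, 0, 0, two_pl)) < response_probability(z0)
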