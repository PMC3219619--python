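"""Likelihood, coordinate-ascent fitting, BIC comparison and confidence
bands."""

import math

import numpy as np
import pytest
from scipy.special import gammaln

from shoalbayes import (
    ExperimentConfig,
    InvalidInputError,
    ObservedDataset,
    bic,
    bic_classic,
    bic_weights,
    confidence_band,
    default_stickleback_design,
    expected_counts_dataset,
    fit,
    fit_multistart,
    generate_synthetic_dataset,
    log_likelihood,
    model_selection_study,
    rmse,
)


@pytest.fixture(scope="module")
def small_design():
    return default_stickleback_design()


@pytest.fixture(scope="module")
def synthetic_25(small_design):
    return generate_synthetic_dataset(small_design, "symmetric", {"s": 2.5},
                                      seed=2024).dataset


class TestLogLikelihood:
    def test_closed_form_binomial_case(self):
        """s=1, N=2, counts (5,10,5): multinomial with p=(1/4,1/2,1/4)."""
        cfg = ExperimentConfig(group_size=2, condition_id="c")
        data = ObservedDataset((cfg,), (np.array([5, 10, 5]),))
        expected = (gammaln(21) - gammaln(6) * 2 - gammaln(11)
                    + 5 * math.log(0.25) + 10 * math.log(0.5)
                    + 5 * math.log(0.25))
        assert log_likelihood("symmetric", {"s": 1.0}, data) == \
            pytest.approx(expected, rel=1e-12)

    def test_generating_parameter_beats_distant_one(self, synthetic_25):
        ll_true = log_likelihood("symmetric", {"s": 2.5}, synthetic_25)
        ll_far = log_likelihood("symmetric", {"s": 20.0}, synthetic_25)
        assert ll_true > ll_far

    def test_permutation_invariance(self):
        cfgs = tuple(ExperimentConfig(group_size=2, condition_id=f"c{i}")
                     for i in range(3))
        tables = (np.array([5, 10, 5]), np.array([12, 4, 4]), np.array([0, 2, 18]))
        fwd = ObservedDataset(cfgs, tables)
        rev = ObservedDataset(cfgs[::-1], tables[::-1])
        assert log_likelihood("symmetric", {"s": 2.0}, fwd) == \
            pytest.approx(log_likelihood("symmetric", {"s": 2.0}, rev), rel=1e-13)

    def test_smooth_single_maximum_on_grid(self, synthetic_25):
        """The one-parameter likelihood is unimodal along s."""
        grid = np.linspace(1.2, 6.0, 49)
        lls = [log_likelihood("symmetric", {"s": float(s)}, synthetic_25)
               for s in grid]
        diffs = np.sign(np.diff(lls))
        flips = np.sum(diffs[:-1] != diffs[1:])
        assert flips == 1  # rises then falls exactly once


class TestRmse:
    def test_zero_for_matching_proportions(self):
        cfg = ExperimentConfig(group_size=2, condition_id="c")
        data = expected_counts_dataset("symmetric", {"s": 1.0}, [cfg],
                                       repetitions=4)
        assert rmse("symmetric", {"s": 1.0}, data) == pytest.approx(0.0, abs=1e-12)

    def test_direct_formula_two_outcomes(self):
        cfg = ExperimentConfig(group_size=1, condition_id="c")
        data = ObservedDataset((cfg,), (np.array([20, 0]),))
        # prediction (0.5, 0.5) vs observed (1, 0)
        assert rmse("symmetric", {"s": 3.0}, data) == pytest.approx(0.5, abs=1e-12)

    def test_single_minimum_along_sweep(self, synthetic_25):
        grid = np.linspace(1.4, 5.0, 25)
        errs = [rmse("symmetric", {"s": float(s)}, synthetic_25) for s in grid]
        best = int(np.argmin(errs))
        assert 0 < best < len(grid) - 1
        assert all(errs[i] >= errs[i + 1] - 1e-12 for i in range(best))
        assert all(errs[i] <= errs[i + 1] + 1e-12 for i in range(best, len(grid) - 1))


class TestFit:
    def test_recovers_from_idealized_counts(self, small_design):
        data = expected_counts_dataset("symmetric", {"s": 2.5},
                                       small_design.conditions, repetitions=20)
        res = fit("symmetric", data, {"s": 1.2})
        assert res.converged
        assert 2.2 <= res.params["s"] <= 2.8

    def test_null_recovery(self, small_design):
        data = expected_counts_dataset("symmetric", {"s": 1.0},
                                       small_design.conditions, repetitions=20)
        res = fit("symmetric", data, {"s": 3.0})
        assert res.params["s"] == pytest.approx(1.0, abs=0.05)

    def test_unanimous_data_hits_upper_bound(self):
        cfg = ExperimentConfig(group_size=4, condition_id="c")
        counts = np.array([10, 0, 0, 0, 10])
        data = ObservedDataset((cfg,), (counts,))
        res = fit("symmetric", data, {"s": 2.0})
        assert res.bounds_hit["s"]

    def test_trace_is_monotone(self, synthetic_25):
        res = fit("symmetric", synthetic_25, {"s": 1.1})
        assert all(b >= a - 1e-9 for a, b in zip(res.trace, res.trace[1:]))

    def test_multistart_agrees_with_single_start(self, synthetic_25):
        single = fit("symmetric", synthetic_25, {"s": 1.5})
        multi = fit_multistart("symmetric", synthetic_25, {"s": 1.5},
                               n_starts=4, seed=9)
        assert multi.params["s"] == pytest.approx(single.params["s"], rel=1e-3)

    def test_frozen_parameters_excluded_from_k(self, synthetic_25):
        res = fit("asymmetric", synthetic_25, {"a": 1.0, "s": 2.0}, free=["s"])
        assert res.k == 1
        assert res.params["a"] == 1.0


class TestBic:
    def test_no_parameters_is_plain_loglik(self):
        assert bic(-123.4, 0, 380) == -123.4

    def test_penalty_half_log_n_per_parameter(self):
        b1 = bic(-100.0, 1, 380)
        b2 = bic(-100.0, 2, 380)
        assert b1 - b2 == pytest.approx(0.5 * math.log(380), rel=1e-12)

    def test_classic_convention_preserves_ranking(self):
        pairs = [(-100.0, 1), (-98.0, 2), (-97.5, 4)]
        select_largest = [bic(ll, k, 380) for ll, k in pairs]
        minimise_me = [bic_classic(ll, k, 380) for ll, k in pairs]
        assert np.argsort(select_largest).tolist() == \
            np.argsort(minimise_me)[::-1].tolist()

    def test_weights_normalize(self):
        w = bic_weights([-500.0, -502.0, -510.0])
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_weight_examples(self):
        np.testing.assert_allclose(bic_weights([-3.0]), [1.0])
        np.testing.assert_allclose(bic_weights([-7.0, -7.0, -7.0]),
                                   [1 / 3] * 3, atol=1e-12)
        w = bic_weights([0.0, -math.log(9.0)])
        np.testing.assert_allclose(w, [0.9, 0.1], atol=1e-12)

    def test_extreme_spread_does_not_overflow(self):
        w = bic_weights([-1e6, 0.0, -2e6])
        assert w[1] == pytest.approx(1.0)


class TestModelSelection:
    def test_identical_candidates_split_weight(self, synthetic_25):
        cand = {"variant": "symmetric", "init": {"s": 2.0}}
        ranked = model_selection_study([dict(cand), dict(cand)], synthetic_25)
        assert ranked[0].bic_weight == pytest.approx(0.5, abs=1e-9)

    def test_superfluous_parameters_penalized(self, synthetic_25):
        """Symmetric-generated data: the 1-parameter rule outranks the
        4-parameter side/indecision-specific variant."""
        ranked = model_selection_study([
            {"variant": "symmetric", "init": {"s": 2.0}},
            {"variant": "asymmetric-full",
             "init": {"a": 1.0, "s_x": 2.0, "s_y": 2.0, "s_u": 1.0}},
        ], synthetic_25)
        assert ranked[0].variant == "symmetric"

    def test_true_asymmetry_detected(self):
        from shoalbayes import predator_design
        study = generate_synthetic_dataset(predator_design(), "asymmetric",
                                           {"a": 3.0, "s": 2.5}, seed=77)
        ranked = model_selection_study([
            {"variant": "symmetric", "init": {"s": 2.0}},
            {"variant": "asymmetric", "init": {"a": 1.0, "s": 2.0}},
        ], study.dataset)
        assert ranked[0].variant == "asymmetric"
        assert ranked[0].bic_weight > 0.9


class TestConfidenceBand:
    def test_point_prediction_inside_band(self, small_design):
        from shoalbayes.inference import predicted_distributions
        conds = small_design.conditions[:4]
        band = confidence_band("symmetric", {"s": 2.5}, conds, n_sim=400, seed=1)
        preds = predicted_distributions("symmetric", {"s": 2.5}, conds)
        for lo, hi, p in zip(band.lower, band.upper, preds):
            assert np.all(lo <= p + 1e-12) and np.all(p <= hi + 1e-12)

    def test_band_shrinks_with_more_repetitions(self, small_design):
        conds = small_design.conditions[:4]
        narrow = confidence_band("symmetric", {"s": 2.5}, conds,
                                 repetitions=200, n_sim=400, seed=2)
        wide = confidence_band("symmetric", {"s": 2.5}, conds,
                               repetitions=20, n_sim=400, seed=2)
        w_wide = sum(float(np.mean(h - l)) for l, h in zip(wide.lower, wide.upper))
        w_narrow = sum(float(np.mean(h - l))
                       for l, h in zip(narrow.lower, narrow.upper))
        assert w_narrow < w_wide

    def test_full_level_spans_achievable_range(self, small_design):
        conds = small_design.conditions[:1]
        band = confidence_band("symmetric", {"s": 2.5}, conds,
                               level=0.999999, n_sim=500, seed=3)
        assert np.all(band.lower[0] >= 0.0) and np.all(band.upper[0] <= 1.0)

    def test_invalid_level_rejected(self, small_design):
        with pytest.raises(InvalidInputError):
            confidence_band("symmetric", {"s": 2.5},
                            small_design.conditions[:1], level=1.5)
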