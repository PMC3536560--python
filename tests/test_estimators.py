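"""The six interval approaches: worked-example values, invariants, oracles."""

import math

import numpy as np
import pytest
from hypothesis import given
from scipy.stats import binom, norm

import nccpv
from nccpv import (
    BoundaryError,
    EstimatorConfig,
    NestedSample,
    SeparationError,
    Target,
    ValidationError,
    corrected_predictive_value,
    estimate_all,
)
from nccpv.estimators import (
    ci_bootstrap,
    ci_corrected_wald,
    ci_mercaldo,
    ci_mercaldo_logit,
    ci_naive_wald,
    ci_weighted_logistic,
    estimates_from_dataframe,
    estimates_to_dataframe,
)

from conftest import nested_samples

CFG = EstimatorConfig(seed=314)


class TestWorkedExample:
    def test_naive_wald_se(self, toy_sample):
        est = ci_naive_wald(toy_sample, "ppv", CFG)
        assert est.se == pytest.approx(math.sqrt(0.75 * 0.25 / 40), abs=1e-10)
        assert est.se == pytest.approx(0.0685, abs=5e-4)
        assert est.estimate == pytest.approx(30 / 130)
        assert est.lower == pytest.approx(30 / 130 - CFG.z * est.se)

    def test_corrected_wald_se(self, toy_sample):
        est = ci_corrected_wald(toy_sample, "ppv", CFG)
        p = 30 / 130
        assert est.se == pytest.approx(math.sqrt(p * (1 - p) / 40), abs=1e-10)
        assert est.se == pytest.approx(0.0666, abs=5e-4)

    def test_symmetric_maximum_variance_case(self):
        sample = NestedSample(a=50, c=50, b1=50, d1=50, cohort_controls=100,
                              cohort_size=200)
        est = ci_corrected_wald(sample, "ppv", CFG)
        assert est.se == pytest.approx(0.05)

    def test_mercaldo_point_identity(self, toy_sample):
        est = ci_mercaldo(toy_sample, target="ppv", cfg=CFG)
        assert est.estimate == pytest.approx(30 / 130, abs=1e-12)

    def test_mercaldo_logit_se(self, toy_sample):
        est = ci_mercaldo_logit(toy_sample, target="ppv", cfg=CFG)
        expected = math.sqrt(0.25 / (0.75 * 40) + 3 / 40)
        assert est.se == pytest.approx(expected, abs=1e-10)
        assert est.se == pytest.approx(0.2887, abs=5e-4)

    def test_weighted_logistic_point_identity(self, toy_sample):
        est = ci_weighted_logistic(toy_sample, "ppv", CFG)
        assert est.estimate == pytest.approx(30 / 130, abs=1e-10)

    def test_bootstrap_brackets_point_estimate(self, toy_sample):
        est = ci_bootstrap(toy_sample, "ppv", CFG)
        assert est.lower <= 30 / 130 <= est.upper
        assert 0.0 <= est.lower < est.upper <= 1.0
        assert est.se is None


class TestPointEstimateIdentity:
    def test_all_six_identical_on_worked_example(self, toy_sample):
        results = estimate_all(toy_sample, cfg=CFG)
        assert len(results) == 12
        for target, expected in ((Target.PPV, 30 / 130), (Target.NPV, 300 / 310)):
            values = [e.estimate for e in results if e.target is target]
            assert len(values) == 6
            assert all(abs(v - expected) < 1e-10 for v in values)

    @given(nested_samples(min_cell=1, max_cell=80))
    def test_identity_on_random_samples(self, sample):
        cfg = EstimatorConfig(seed=0, bootstrap_reps=10)
        results = estimate_all(sample, cfg=cfg)
        for target in Target:
            values = [e.estimate for e in results if e.target is target]
            spread = max(values) - min(values)
            assert spread < 1e-10


class TestIntervalValidity:
    @given(nested_samples(min_cell=1, max_cell=80))
    def test_bounds_ordered_and_in_unit_interval(self, sample):
        cfg = EstimatorConfig(seed=0, bootstrap_reps=25)
        for est in estimate_all(sample, cfg=cfg):
            assert 0.0 <= est.lower <= est.estimate <= est.upper <= 1.0

    def test_logit_scale_bounds_strictly_interior(self, toy_sample):
        for fn in (ci_weighted_logistic,):
            est = fn(toy_sample, "ppv", CFG)
            assert 0.0 < est.lower < est.upper < 1.0
        est = ci_mercaldo_logit(toy_sample, target="ppv", cfg=CFG)
        assert 0.0 < est.lower < est.upper < 1.0

    def test_truncation_flagged(self, toy_sample):
        est = ci_naive_wald(toy_sample, "npv", CFG)
        assert est.upper == 1.0
        assert est.truncated

    def test_ordering_violation_rejected(self):
        with pytest.raises(ValidationError, match="ordering"):
            nccpv.IntervalEstimate(target="ppv", estimate=0.5, lower=0.6,
                                   upper=0.7, se=0.1, scale="natural",
                                   approach=1, level=0.95)

    def test_zero_variance_boundary_collapses_to_point(self):
        sample = NestedSample(a=0, c=5, b1=4, d1=6, cohort_controls=100,
                              cohort_size=105)
        est = ci_naive_wald(sample, "ppv", CFG)
        assert est.se == 0.0
        assert est.lower == est.estimate == est.upper == 0.0


class TestFullCohortIdentities:
    def test_approach_1_equals_2_at_sf1(self, toy_cohort):
        sample = toy_cohort.as_nested_sample()
        one = ci_naive_wald(sample, "ppv", CFG)
        two = ci_corrected_wald(sample, "ppv", CFG)
        assert one.se == two.se
        assert (one.lower, one.upper) == (two.lower, two.upper)

    def test_weighted_logistic_reproduces_raw_proportion_at_sf1(self, toy_cohort):
        est = ci_weighted_logistic(toy_cohort.as_nested_sample(), "ppv", CFG)
        assert est.estimate == pytest.approx(30 / 130, abs=1e-10)


class TestMercaldo:
    def test_variance_matches_numerical_delta_method(self):
        """Plug-in variance equals propagating the binomial variances of Se
        and Sp through the Bayes formula by numerical differentiation."""
        rng = np.random.default_rng(2718)
        eps = 1e-6
        for _ in range(50):
            a, c, b1, d1 = (int(v) for v in rng.integers(2, 150, size=4))
            extra = int(rng.integers(0, 400))
            sample = NestedSample(a=a, c=c, b1=b1, d1=d1,
                                  cohort_controls=b1 + d1 + extra,
                                  cohort_size=a + c + b1 + d1 + extra)
            p = sample.cohort_prevalence
            se_hat, sp_hat = sample.sensitivity, sample.specificity
            for target in ("ppv", "npv"):
                est = ci_mercaldo(sample, target=target, cfg=CFG)
                d_se = (
                    nccpv.bayes_predictive_value(se_hat + eps, sp_hat, p, target)
                    - nccpv.bayes_predictive_value(se_hat - eps, sp_hat, p, target)
                ) / (2 * eps)
                d_sp = (
                    nccpv.bayes_predictive_value(se_hat, sp_hat + eps, p, target)
                    - nccpv.bayes_predictive_value(se_hat, sp_hat - eps, p, target)
                ) / (2 * eps)
                var = (
                    d_se**2 * se_hat * (1 - se_hat) / sample.n_cases
                    + d_sp**2 * sp_hat * (1 - sp_hat) / sample.n_controls
                )
                assert est.se == pytest.approx(math.sqrt(var), rel=1e-6)

    def test_boundary_sensitivity_raises(self):
        sample = NestedSample(a=5, c=0, b1=3, d1=4, cohort_controls=50,
                              cohort_size=55)
        with pytest.raises(BoundaryError):
            ci_mercaldo(sample, target="ppv", cfg=CFG)
        with pytest.raises(BoundaryError):
            ci_mercaldo_logit(sample, target="ppv", cfg=CFG)
        cc = EstimatorConfig(seed=1, continuity_correction=True)
        assert ci_mercaldo(sample, target="ppv", cfg=cc).se > 0

    def test_vanishing_prevalence_limit(self, toy_sample):
        est = ci_mercaldo(toy_sample, cohort_prevalence=1e-9, target="ppv",
                          cfg=CFG)
        assert est.estimate == pytest.approx(0.0, abs=1e-6)
        assert est.se == pytest.approx(0.0, abs=1e-6)

    def test_width_vanishes_with_sample_size(self):
        small = NestedSample(a=30, c=10, b1=10, d1=30, cohort_controls=400,
                             cohort_size=440)
        big = NestedSample(a=30000, c=10000, b1=10000, d1=30000,
                           cohort_controls=400000, cohort_size=440000)
        w_small = ci_mercaldo_logit(small, target="ppv", cfg=CFG).width
        w_big = ci_mercaldo_logit(big, target="ppv", cfg=CFG).width
        assert w_big < w_small / 20


class TestBootstrap:
    def test_deterministic_under_seed(self, toy_sample):
        a = ci_bootstrap(toy_sample, "ppv", EstimatorConfig(seed=42))
        b = ci_bootstrap(toy_sample, "ppv", EstimatorConfig(seed=42))
        assert (a.lower, a.upper) == (b.lower, b.upper)
        c = ci_bootstrap(toy_sample, "ppv", EstimatorConfig(seed=43))
        assert (a.lower, a.upper) != (c.lower, c.upper)

    def test_percentiles_match_exact_resampling_distribution(self, toy_sample):
        """With many replicates the percentile endpoints agree, within
        Monte-Carlo error, with exact quantiles enumerated over the product
        of the two within-stratum resampling distributions."""
        reps = 10_000
        est = ci_bootstrap(toy_sample, "ppv",
                           EstimatorConfig(seed=7, bootstrap_reps=reps))
        # exact law of the resampled corrected PPV: a* ~ Bin(40, 30/40),
        # b1* ~ Bin(40, 10/40) independent, PPV* = a*/(a* + 10*b1*)
        grid_a = np.arange(41)
        grid_b = np.arange(41)
        pa = binom.pmf(grid_a, 40, 30 / 40)
        pb = binom.pmf(grid_b, 40, 10 / 40)
        values = []
        probs = []
        for i, wa in zip(grid_a, pa):
            for j, wb in zip(grid_b, pb):
                denom = i + 10.0 * j
                v = i / denom if denom > 0 else 0.5 / (0.5 + 5.0)
                values.append(v)
                probs.append(wa * wb)
        order = np.argsort(values)
        values = np.asarray(values)[order]
        cdf = np.cumsum(np.asarray(probs)[order])

        def exact_quantile(q):
            return values[np.searchsorted(cdf, q)]

        tol = 4 * math.sqrt(0.025 * 0.975 / reps)
        assert exact_quantile(0.025 - tol) <= est.lower <= exact_quantile(0.025 + tol)
        assert exact_quantile(0.975 - tol) <= est.upper <= exact_quantile(0.975 + tol)

    def test_empty_denominator_replicates_are_corrected_and_tallied(self):
        sample = NestedSample(a=1, c=30, b1=1, d1=5, cohort_controls=60,
                              cohort_size=91)
        est = ci_bootstrap(sample, "ppv",
                           EstimatorConfig(seed=11, bootstrap_reps=400))
        assert est.diagnostics["empty_denominator_replicates"] > 0
        assert 0.0 <= est.lower <= est.upper <= 1.0

    def test_rejects_single_replicate_config(self):
        with pytest.raises(ValidationError):
            EstimatorConfig(bootstrap_reps=1)


class TestConfigAndSerialization:
    def test_z_follows_level(self, toy_sample):
        assert EstimatorConfig(level=0.9).z == pytest.approx(
            norm.ppf(0.95), abs=1e-12
        )
        narrow = ci_corrected_wald(toy_sample, "ppv", EstimatorConfig(level=0.9))
        wide = ci_corrected_wald(toy_sample, "ppv", EstimatorConfig(level=0.95))
        assert narrow.width < wide.width

    def test_bootstrap_carries_no_se_others_do(self, toy_sample):
        results = estimate_all(toy_sample, cfg=CFG)
        for est in results:
            if est.approach == 3:
                assert est.se is None
            else:
                assert est.se is not None and est.se >= 0

    def test_dataframe_roundtrip(self, toy_sample, tmp_path):
        import pandas as pd

        results = estimate_all(toy_sample, cfg=CFG)
        frame = estimates_to_dataframe(results)
        path = tmp_path / "est.csv"
        frame.to_csv(path, index=False, float_format="%.17g")
        back = estimates_from_dataframe(
            pd.read_csv(path, float_precision="round_trip")
        )
        assert back == results

    def test_width_shrinks_like_root_k(self):
        base = NestedSample(a=30, c=10, b1=10, d1=30, cohort_controls=400,
                            cohort_size=440)
        k = 16
        scaled = NestedSample(a=30 * k, c=10 * k, b1=10 * k, d1=30 * k,
                              cohort_controls=400 * k, cohort_size=440 * k)
        for fn in (ci_naive_wald, ci_corrected_wald):
            ratio = fn(scaled, "ppv", CFG).width / fn(base, "ppv", CFG).width
            assert ratio == pytest.approx(1 / math.sqrt(k), rel=0.05)
        ratio = (
            ci_mercaldo(scaled, target="ppv", cfg=CFG).width
            / ci_mercaldo(base, target="ppv", cfg=CFG).width
        )
        assert ratio == pytest.approx(1 / math.sqrt(k), rel=0.05)
        ratio = (
            ci_mercaldo_logit(scaled, target="ppv", cfg=CFG).width
            / ci_mercaldo_logit(base, target="ppv", cfg=CFG).width
        )
        assert ratio == pytest.approx(1 / math.sqrt(k), rel=0.1)

    def test_weighted_logistic_separation_propagates(self):
        sample = NestedSample(a=5, c=0, b1=3, d1=4, cohort_controls=50,
                              cohort_size=55)
        with pytest.raises(SeparationError):
            ci_weighted_logistic(sample, "ppv", CFG)
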