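"""Binomial criterion, psychometric fitting, thresholds, comparisons."""

import math

import numpy as np
import pandas as pd
import pytest

from ovk import synthetic as syn
from ovk.psychophysics import (
    binomial_criterion,
    bootstrap_ci,
    compare_treatments,
    fit_psychometric,
    interpolate_threshold,
    threshold_with_ci,
)


def brute_force_criterion(n, alpha, p0=0.5):
    """Exact tail by direct summation of binomial pmf terms."""
    for k in range(n + 1):
        tail = sum(math.comb(n, j) * p0 ** j * (1 - p0) ** (n - j)
                   for j in range(k, n + 1))
        if tail < alpha:
            return k
    return None


class TestBinomialCriterion:
    def test_pooled_grating_trials_give_62_percent(self):
        crit = binomial_criterion(110, 0.01)
        assert crit.k == 68
        assert crit.proportion == pytest.approx(68 / 110)
        assert crit.percent_rounded == 62

    def test_single_trial_unattainable(self):
        crit = binomial_criterion(1, 0.01)
        assert not crit.attainable and crit.k is None

    @pytest.mark.parametrize("n,alpha", [(20, 0.05), (110, 0.01), (45, 0.001),
                                         (200, 0.05), (7, 0.05)])
    def test_agrees_with_exhaustive_tail_enumeration(self, n, alpha):
        crit = binomial_criterion(n, alpha)
        expected = brute_force_criterion(n, alpha)
        assert crit.k == expected

    def test_biased_null_probability(self):
        crit = binomial_criterion(50, 0.05, p0=0.7)
        assert crit.k == brute_force_criterion(50, 0.05, 0.7)


class TestFitPsychometric:
    def test_recovers_parameters_on_near_noiseless_data(self):
        # huge trial counts at each level: MLE must land near the truth
        df, ledger = syn.make_trials(3.94, 1.2, np.arange(0.5, 5.01, 0.5),
                                     5000, seed=4)
        fit = fit_psychometric(df["spatial_frequency_cpd"], df["correct"])
        assert fit.alpha == pytest.approx(ledger.truths["alpha"], abs=0.05)
        assert fit.beta == pytest.approx(ledger.truths["slope"], rel=0.05)

    def test_all_correct_sets_separation_flag(self):
        x = np.repeat([1.0, 2.0, 3.0], 20)
        fit = fit_psychometric(x, np.ones_like(x, dtype=int))
        assert "separation" in fit.flags

    def test_step_observer_caps_slope(self):
        x = np.repeat([1.0, 2.0, 3.0, 4.0], 50)
        correct = (x <= 2.0).astype(int)
        # below threshold always right, above at exactly chance
        rng = np.random.default_rng(0)
        correct[x > 2.0] = rng.integers(0, 2, size=(x > 2.0).sum())
        fit = fit_psychometric(x, correct)
        assert "separation" in fit.flags or fit.beta > 5

    def test_rising_performance_flagged_non_monotone(self):
        x = np.repeat([1.0, 2.0, 3.0], 60)
        rng = np.random.default_rng(1)
        p = {1.0: 0.55, 2.0: 0.75, 3.0: 0.95}
        correct = np.array([rng.random() < p[v] for v in x], dtype=int)
        fit = fit_psychometric(x, correct)
        assert "non_monotone" in fit.flags

    def test_deviance_zero_when_model_matches_observed_exactly(self):
        # two levels, fitted curve can pass through both observed points
        x = np.repeat([1.0, 3.0], 100)
        correct = np.r_[np.ones(90), np.zeros(10), np.ones(60), np.zeros(40)]
        fit = fit_psychometric(x, correct)
        assert fit.deviance == pytest.approx(0.0, abs=1e-6)

    def test_needs_two_levels(self):
        with pytest.raises(ValueError, match="2 distinct"):
            fit_psychometric([1.0, 1.0], [1, 0])


class TestInterpolateThreshold:
    @pytest.fixture()
    def fit(self):
        df, _ = syn.make_trials(3.94, 1.2, np.arange(0.5, 5.01, 0.5), 200, seed=8)
        return fit_psychometric(df["spatial_frequency_cpd"], df["correct"])

    def test_criterion_75_percent_returns_location(self, fit):
        est = interpolate_threshold(fit, criterion=0.75)
        assert est.threshold_cpd == pytest.approx(fit.alpha, abs=1e-10)

    def test_inversion_identity(self, fit):
        est = interpolate_threshold(fit, criterion=0.62)
        assert float(fit.psi(est.threshold_cpd)) == pytest.approx(0.62, abs=1e-10)

    def test_criterion_outside_range_errors(self, fit):
        with pytest.raises(ValueError, match="outside attainable"):
            interpolate_threshold(fit, criterion=0.4)

    def test_rescaling_frequency_axis_rescales_threshold(self):
        df, _ = syn.make_trials(2.0, 1.5, np.arange(0.5, 4.01, 0.5), 300, seed=3)
        x = df["spatial_frequency_cpd"].to_numpy()
        c = df["correct"].to_numpy()
        t1 = interpolate_threshold(fit_psychometric(x, c)).threshold_cpd
        k = 3.7
        t2 = interpolate_threshold(fit_psychometric(k * x, c)).threshold_cpd
        assert t2 == pytest.approx(k * t1, rel=1e-6)

    def test_planted_threshold_recovered_within_ci(self):
        df, ledger = syn.simulate("achromatic_acuity", seed=42)
        est = threshold_with_ci(df["spatial_frequency_cpd"], df["correct"],
                                n_boot=400, seed=42)
        assert est.ci_low <= ledger.truths["true_threshold_cpd"] <= est.ci_high
        assert est.ci_low <= est.threshold_cpd <= est.ci_high

    def test_median_recovery_error_below_ten_percent(self):
        # parameter-recovery sweep at study-like trial counts
        errors = []
        for seed in range(60):
            df, ledger = syn.make_trials(3.94, 1.2, np.arange(0.5, 5.01, 0.5),
                                         110, seed=seed)
            fit = fit_psychometric(df["spatial_frequency_cpd"], df["correct"])
            t = interpolate_threshold(fit).threshold_cpd
            errors.append(abs(t - ledger.truths["true_threshold_cpd"]) / 3.94)
        assert np.median(errors) < 0.10

    def test_log_frequency_fit_inverts_on_the_cpd_scale(self):
        df, _ = syn.make_trials(2.0, 1.5, np.arange(0.5, 4.01, 0.5), 400, seed=6)
        fit = fit_psychometric(df["spatial_frequency_cpd"], df["correct"],
                               log_frequency=True)
        est = interpolate_threshold(fit)
        assert 1.5 < est.threshold_cpd < 2.5
        assert float(fit.psi(est.threshold_cpd)) == pytest.approx(0.62, abs=1e-10)


class TestBootstrapCI:
    def test_fixed_seed_is_bit_reproducible(self):
        df, _ = syn.simulate("green_yellow_acuity", seed=2)
        fit = fit_psychometric(df["spatial_frequency_cpd"], df["correct"])
        ci1 = bootstrap_ci(df["spatial_frequency_cpd"], fit, n_boot=100, seed=7)
        ci2 = bootstrap_ci(df["spatial_frequency_cpd"], fit, n_boot=100, seed=7)
        assert ci1 == ci2

    def test_ci_width_shrinks_with_sample_size(self):
        widths = []
        for n in (60, 2000):
            df, _ = syn.make_trials(2.0, 2.0, np.arange(0.5, 3.01, 0.5), n, seed=5)
            fit = fit_psychometric(df["spatial_frequency_cpd"], df["correct"])
            lo, hi = bootstrap_ci(df["spatial_frequency_cpd"], fit,
                                  n_boot=150, seed=5)
            widths.append(hi - lo)
        assert widths[1] < widths[0] / 2


class TestCompareTreatments:
    def _table(self, a_vals, b_vals, paired):
        rows = []
        for i, v in enumerate(a_vals):
            rows.append({"fish_id": f"f{i}", "treatment": "achromatic",
                         "threshold_cpd": v})
        for i, v in enumerate(b_vals):
            fid = f"f{i}" if paired else f"g{i}"
            rows.append({"fish_id": fid, "treatment": "green_yellow",
                         "threshold_cpd": v})
        return pd.DataFrame(rows)

    def test_identical_sets_give_p_one(self):
        t = self._table([3.0, 3.5, 4.0], [3.0, 3.5, 4.0], paired=False)
        res = compare_treatments(t, seed=0)
        assert res["p_value"].iloc[0] == pytest.approx(1.0)

    def test_non_overlapping_sets_reach_minimal_attainable_p(self):
        # exact enumeration: C(4,2)=6 relabellings, only the observed one and
        # its mirror are as extreme -> p = 2/6
        t = self._table([3.8, 4.0], [1.6, 1.8], paired=False)
        res = compare_treatments(t, seed=0)
        assert res["n_permutations"].iloc[0] == 6
        assert res["p_value"].iloc[0] == pytest.approx(2 / 6)

    def test_null_data_p_values_roughly_uniform(self):
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(200):
            vals = rng.normal(3.0, 0.5, 10)
            t = self._table(vals[:5], vals[5:], paired=False)
            ps.append(compare_treatments(t, seed=1)["p_value"].iloc[0])
        ps = np.array(ps)
        # exact permutation p-values are super-uniform: P(p <= x) <= x
        for x in (0.05, 0.25, 0.5):
            assert np.mean(ps <= x) < x + 0.07

    def test_paired_design_uses_sign_flips(self):
        t = self._table([3.8, 4.0, 3.6], [1.6, 1.8, 1.7], paired=True)
        res = compare_treatments(t, seed=0)
        assert bool(res["paired"].iloc[0])
        assert res["n_permutations"].iloc[0] == 8  # 2^3 sign patterns
        assert res["p_value"].iloc[0] == pytest.approx(2 / 8)

    def test_single_treatment_errors(self):
        t = pd.DataFrame([{"fish_id": "f", "treatment": "achromatic",
                           "threshold_cpd": 3.0}])
        with pytest.raises(ValueError, match="at least 2 treatments"):
            compare_treatments(t)
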