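import itertools
import math

import numpy as np
import pytest
from scipy import integrate, special

from ewsignals import (
    GeneratorConfig,
    TrendThreshold,
    ValidationError,
    bayesian_changepoint,
    classify_support,
    compare_slope_to_threshold,
    fit_breakpoint_continuous,
    fit_breakpoint_structural,
    generate_stationary,
    generate_surge,
    scenario_config,
)


def rss_scan_oracle(years, values, continuous, min_segment):
    """Independently coded exhaustive RSS scan over candidate breaks."""
    x = np.asarray(years, float)
    y = np.asarray(values, float)
    n = len(x)
    best = (None, np.inf)
    if continuous:
        for k in range(min_segment - 1, n - min_segment):
            X = np.column_stack((np.ones(n), x, np.maximum(0, x - x[k])))
            beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(((y - X @ beta) ** 2).sum())
            if rss < best[1] - 1e-12:
                best = (int(x[k]), rss)
    else:
        for k in range(min_segment, n - min_segment + 1):
            rss = 0.0
            for xs, ys in ((x[:k], y[:k]), (x[k:], y[k:])):
                c = np.polyfit(xs, ys, 1)
                rss += float(((ys - np.polyval(c, xs)) ** 2).sum())
            if rss < best[1] - 1e-12:
                best = (int(x[k]), rss)
    return best


class TestBreakpointContinuous:
    def test_noiseless_hinge_recovered_exactly(self, years26):
        vals = 9.0 + 0.02 * (years26 - 1987) - 0.02 * np.maximum(0, years26 - 2000)
        bp = fit_breakpoint_continuous(years26, vals)
        assert bp.break_year == 2000
        assert bp.slope_before == pytest.approx(0.02, abs=1e-8)
        assert bp.slope_after == pytest.approx(0.0, abs=1e-8)
        assert bp.rss <= bp.rss_single_line

    def test_pure_line_unsupported(self, years26):
        vals = 1.0 + 0.01 * years26
        bp = fit_breakpoint_continuous(years26, vals)
        assert not bp.supported
        assert bp.improvement_stat == pytest.approx(0.0, abs=1e-3)

    def test_matches_independent_rss_scan(self, years26):
        rng = np.random.default_rng(17)
        for _ in range(20):
            y = rng.normal(0, 1, 26).cumsum() / 5
            bp = fit_breakpoint_continuous(years26, y)
            oy, orss = rss_scan_oracle(years26, y, continuous=True, min_segment=3)
            assert bp.break_year == oy
            assert bp.rss == pytest.approx(orss, rel=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            fit_breakpoint_continuous(np.arange(5), np.arange(5.0))


class TestBreakpointStructural:
    def test_noiseless_step_recovered(self, years26):
        vals = np.where(years26 < 1999, 9.0, 9.5)
        bp = fit_breakpoint_structural(years26, vals)
        assert bp.break_year == 1999
        assert bp.slope_before == pytest.approx(0.0, abs=1e-10)
        assert bp.slope_after == pytest.approx(0.0, abs=1e-10)

    def test_linear_series_improvement_zero(self, years26):
        vals = 2.0 - 0.005 * years26
        bp = fit_breakpoint_structural(years26, vals)
        assert bp.improvement_stat == pytest.approx(0.0, abs=1e-3)
        assert not bp.supported

    def test_matches_independent_rss_scan(self, years26):
        rng = np.random.default_rng(29)
        min_seg = max(3, math.ceil(0.15 * 26))
        for _ in range(20):
            y = rng.normal(0, 1, 26).cumsum() / 5
            bp = fit_breakpoint_structural(years26, y)
            oy, orss = rss_scan_oracle(
                years26, y, continuous=False, min_segment=min_seg
            )
            assert bp.break_year == oy
            assert bp.rss == pytest.approx(orss, rel=1e-9)

    def test_recovery_degrades_monotonically_with_noise(self):
        rates = []
        for sd in (0.02, 0.05, 0.1):
            hits = 0
            for s in range(150):
                ser = generate_surge(
                    GeneratorConfig(seed=s, process_sd=sd, obs_sd=0.02)
                )
                bp = fit_breakpoint_continuous(ser.years, np.log(ser.estimates))
                hits += abs(bp.break_year - 1999) <= 1
            rates.append(hits / 150)
        assert rates[0] >= rates[1] >= rates[2]


class TestSupportCategories:
    @pytest.mark.parametrize(
        "p, label",
        [
            (0.78, "strong"),
            (0.02, "very_weak"),
            (0.0, "very_weak"),
            (0.1, "weak"),
            (0.5, "moderately_strong"),
            (0.7, "strong"),
            (0.9, "very_strong"),
            (1.0, "very_strong"),
            (0.0999999, "very_weak"),
            (0.4999999, "weak"),
            (0.6999999, "moderately_strong"),
            (0.8999999, "strong"),
        ],
    )
    def test_partition(self, p, label):
        assert classify_support(p) == label

    @pytest.mark.parametrize("p", [-0.01, 1.01])
    def test_out_of_range(self, p):
        with pytest.raises(ValidationError):
            classify_support(p)


class TestSlopeThreshold:
    def test_bounds_are_derived_from_25pct_over_25yr(self):
        thr = TrendThreshold()
        assert thr.upper_log_slope == pytest.approx(math.log(1.25) / 25)
        assert thr.lower_log_slope == pytest.approx(math.log(0.75) / 25)
        assert thr.upper_log_slope == pytest.approx(0.008926, abs=1e-6)
        assert thr.lower_log_slope == pytest.approx(-0.011507, abs=1e-6)

    @pytest.mark.parametrize(
        "ci, expected",
        [
            ((0.02, 0.04), "increasing"),
            ((-0.002, 0.003), "negligible"),
            ((-0.02, 0.02), "inconclusive"),
            ((-0.04, -0.02), "declining"),
        ],
    )
    def test_classification(self, ci, expected):
        assert compare_slope_to_threshold(ci) == expected


class TestBayesianChangepoint:
    def test_fixed_seed_bit_identical(self, years26):
        x = np.random.default_rng(2).normal(0, 1, 26)
        a = bayesian_changepoint(years26, x, seed=11)
        b = bayesian_changepoint(years26, x, seed=11)
        assert np.array_equal(a.posterior_prob, b.posterior_prob)
        assert np.array_equal(a.posterior_mean, b.posterior_mean)

    def test_large_step_gets_very_strong_support(self, years26):
        x = np.concatenate([np.zeros(13), np.full(13, 10.0)])
        x += np.random.default_rng(0).normal(0, 1, 26)
        cp = bayesian_changepoint(years26, x, seed=1)
        step_year = years26[13]
        assert cp.posterior_prob[13] >= 0.9
        assert cp.support_at(step_year) == "very_strong"

    def test_location_and_scale_invariance(self, years26):
        x = np.random.default_rng(4).normal(0, 1, 26)
        x[15:] += 2.0
        base = bayesian_changepoint(years26, x, seed=3)
        shifted = bayesian_changepoint(years26, x + 57.0, seed=3)
        scaled = bayesian_changepoint(years26, 3.5 * x, seed=3)
        assert np.allclose(base.posterior_prob, shifted.posterior_prob)
        assert np.allclose(base.posterior_prob, scaled.posterior_prob)

    def test_constant_series_valid_and_very_weak(self, years26):
        cp = bayesian_changepoint(years26, np.full(26, 4.2), seed=0)
        assert np.all(cp.posterior_prob < 0.1)
        assert np.allclose(cp.posterior_mean, 4.2)

    @pytest.mark.parametrize("bad", [{"prior_p0": 0.0}, {"prior_w0": 1.5}])
    def test_invalid_priors_rejected(self, years26, bad):
        with pytest.raises(ValidationError):
            bayesian_changepoint(
                years26, np.random.default_rng(0).normal(size=26), **bad
            )

    def test_gibbs_matches_exact_enumeration(self):
        # exact posterior by summing the product-partition kernel over all
        # 2^(n-1) partitions of a small series
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 8)
        x[4:] += 1.5
        n = len(x)
        p0 = w0 = 0.2

        def kernel(u):
            starts = [0] + [i + 1 for i, ui in enumerate(u) if ui]
            bounds = starts + [n]
            W = Sb = 0.0
            for a, c in zip(bounds[:-1], bounds[1:]):
                seg = x[a:c]
                W += ((seg - seg.mean()) ** 2).sum()
                Sb += len(seg) * seg.mean() ** 2
            B = max(Sb - n * x.mean() ** 2, 0.0)
            b = len(starts)
            pint = special.betainc(b, n - b + 1, p0) * special.beta(b, n - b + 1)
            wint, _ = integrate.quad(
                lambda w: w ** ((b - 1) / 2) * (W + B * w) ** (-(n - 1) / 2),
                0, w0, limit=200,
            )
            return pint * wint

        post = np.zeros(n - 1)
        Z = 0.0
        for u in itertools.product((0, 1), repeat=n - 1):
            k = kernel(u)
            Z += k
            for i, ui in enumerate(u):
                if ui:
                    post[i] += k
        exact = post / Z
        cp = bayesian_changepoint(
            np.arange(n), x, n_burnin=200, n_mcmc=20000, seed=3
        )
        assert np.abs(exact - cp.posterior_prob[1:]).max() < 0.02

    def test_surge_change_mass_sits_in_growth_period(self):
        # a sustained ramp spreads change mass over the rising years (each
        # level shift is real); the flat pre-break period should carry none
        for seed in range(6):
            ser = generate_surge(
                scenario_config("surge", seed=seed), break_year=1999,
                growth_after=0.2,
            )
            cp = bayesian_changepoint(ser.years, np.log(ser.estimates), seed=seed)
            pre = cp.posterior_prob[ser.years <= 1999]
            post = cp.posterior_prob[ser.years > 1999]
            assert pre.max() < 0.5
            assert post.max() > pre.max()
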