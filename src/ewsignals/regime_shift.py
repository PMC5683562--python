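"""Break-point estimation, Bayesian change-point analysis, and slope thresholds.

Three complementary views of a shift in a population trajectory:

* ``fit_breakpoint_continuous`` — a continuous ("hinged") two-segment linear
  fit to log abundance vs year: the slope changes at the break but the line
  is continuous. The break year is chosen by exhaustive RSS minimization over
  all candidate years (series here are short, so the grid search is exact).
* ``fit_breakpoint_structural`` — two fully independent lines (level and
  slope both free on each side), again by exhaustive RSS scan; this is the
  discontinuous structural-change variant.
* ``bayesian_changepoint`` — a Barry–Hartigan product-partition model for a
  shift in mean level, sampled by Gibbs over change-point indicators. It
  returns the per-year posterior probability of a change, read as the weight
  of evidence for a step change at that year, plus posterior mean levels.

Posterior probabilities are mapped onto qualitative support categories
(very_weak < 0.1 <= weak < 0.5 <= moderately_strong < 0.7 <= strong < 0.9
<= very_strong), and segment slopes are compared against a biological
significance threshold of a 25% total change over 25 years, computed on the
log scale (note the asymmetry: +ln(1.25)/25 vs ln(0.75)/25 per year).
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .errors import DegenerateFitError, ValidationError

__all__ = [
    "BreakpointResult",
    "ChangepointResult",
    "TrendThreshold",
    "SUPPORT_CATEGORIES",
    "fit_breakpoint_continuous",
    "fit_breakpoint_structural",
    "bayesian_changepoint",
    "classify_support",
    "compare_slope_to_threshold",
]


# --------------------------------------------------------------------------
# break-point fits
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BreakpointResult:
    """A single estimated break in the slope of log abundance vs year."""

    method: str
    break_year: int
    slope_before: float
    slope_after: float
    ci95_before: tuple
    ci95_after: tuple
    rss: float
    rss_single_line: float
    improvement_stat: float
    supported: bool

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "break_year": self.break_year,
            "slope_before": self.slope_before,
            "slope_after": self.slope_after,
            "ci95_before_low": self.ci95_before[0],
            "ci95_before_high": self.ci95_before[1],
            "ci95_after_low": self.ci95_after[0],
            "ci95_after_high": self.ci95_after[1],
            "rss": self.rss,
            "rss_single_line": self.rss_single_line,
            "improvement_stat": self.improvement_stat,
            "supported": self.supported,
        }
        return d


def _check_xy(years, values):
    x = np.asarray(years, dtype=float).ravel()
    y = np.asarray(values, dtype=float).ravel()
    if len(x) != len(y):
        raise ValidationError("years and values differ in length")
    if np.any(np.diff(x) <= 0):
        raise ValidationError("years must be strictly increasing")
    return x, y


def _ols_rss(X: np.ndarray, y: np.ndarray):
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def _single_line_rss(x, y):
    X = np.column_stack((np.ones_like(x), x))
    return _ols_rss(X, y)[1]


def _f_improvement(
    rss0: float, rss: float, df_extra: int, df_resid: int, tss: float
) -> float:
    """F-type RSS-reduction statistic of the broken fit vs the single line.

    When the single line already fits to numerical precision (rss0
    negligible against the series' total sum of squares) the statistic is 0
    by definition — ratios of roundoff are meaningless.
    """
    if rss0 <= 1e-12 * max(tss, 1e-300):
        return 0.0
    if df_resid <= 0 or rss <= 1e-12 * max(tss, 1e-300):
        return math.inf if rss0 > rss else 0.0
    return max(0.0, (rss0 - rss) / df_extra) / (rss / df_resid)


def fit_breakpoint_continuous(years, values, min_segment: int = 3) -> BreakpointResult:
    """Continuous (hinged) two-segment fit with exhaustive break search.

    Model: y = a + b*year + c*max(0, year - psi); slope is b before the hinge
    year psi and b + c after. Candidate psi runs over observed years with at
    least ``min_segment`` observations at or before and strictly after it;
    the candidate minimizing RSS wins (earliest year on exact ties).
    """
    x, y = _check_xy(years, values)
    n = len(x)
    candidates = [
        k for k in range(n) if (k + 1) >= min_segment and (n - k - 1) >= min_segment
    ]
    if not candidates:
        raise ValidationError(
            f"series of length {n} too short for min_segment={min_segment}"
        )
    rss0 = _single_line_rss(x, y)
    tss = float(((y - y.mean()) ** 2).sum())
    best = None
    for k in candidates:
        psi = x[k]
        hinge = np.maximum(0.0, x - psi)
        X = np.column_stack((np.ones(n), x, hinge))
        beta, rss = _ols_rss(X, y)
        if best is None or rss < best[1] - 1e-14 * max(rss0, 1.0):
            best = (k, rss, beta, X)
    k, rss, beta, X = best
    df = n - 3
    sigma2 = rss / df if df > 0 else 0.0
    cov = sigma2 * np.linalg.pinv(X.T @ X)
    tq = stats.t.ppf(0.975, df) if df > 0 else math.inf
    b_before = float(beta[1])
    b_after = float(beta[1] + beta[2])
    se_before = math.sqrt(max(cov[1, 1], 0.0))
    se_after = math.sqrt(max(cov[1, 1] + cov[2, 2] + 2 * cov[1, 2], 0.0))
    improvement = _f_improvement(rss0, rss, df_extra=2, df_resid=df, tss=tss)
    return BreakpointResult(
        method="piecewise_continuous",
        break_year=int(round(x[k])),
        slope_before=b_before,
        slope_after=b_after,
        ci95_before=(b_before - tq * se_before, b_before + tq * se_before),
        ci95_after=(b_after - tq * se_after, b_after + tq * se_after),
        rss=rss,
        rss_single_line=rss0,
        improvement_stat=improvement,
        supported=improvement > 1e-6,
    )


def fit_breakpoint_structural(
    years, values, min_segment: int | None = None
) -> BreakpointResult:
    """Discontinuous two-line fit: independent OLS lines on each side.

    The break year is the first year of the post-break segment; segments must
    hold at least ``min_segment`` observations (default max(3, ceil(0.15 n))).
    Slope CIs come from each segment's own OLS fit (n_j - 2 df).
    """
    x, y = _check_xy(years, values)
    n = len(x)
    if min_segment is None:
        min_segment = max(3, math.ceil(0.15 * n))
    candidates = range(min_segment, n - min_segment + 1)  # split index: y[:k], y[k:]
    if len(list(candidates)) == 0:
        raise ValidationError(
            f"series of length {n} too short for min_segment={min_segment}"
        )
    rss0 = _single_line_rss(x, y)
    tss = float(((y - y.mean()) ** 2).sum())
    best = None
    for k in range(min_segment, n - min_segment + 1):
        r1 = _single_line_rss(x[:k], y[:k])
        r2 = _single_line_rss(x[k:], y[k:])
        if best is None or r1 + r2 < best[1] - 1e-14 * max(rss0, 1.0):
            best = (k, r1 + r2)
    k, rss = best

    def _segment(xs, ys):
        X = np.column_stack((np.ones_like(xs), xs))
        beta, r = _ols_rss(X, ys)
        df = len(xs) - 2
        if df > 0 and r > 0:
            cov = (r / df) * np.linalg.pinv(X.T @ X)
            se = math.sqrt(max(cov[1, 1], 0.0))
            tq = stats.t.ppf(0.975, df)
        else:
            se, tq = 0.0, 0.0
        return float(beta[1]), (float(beta[1] - tq * se), float(beta[1] + tq * se))

    slope1, ci1 = _segment(x[:k], y[:k])
    slope2, ci2 = _segment(x[k:], y[k:])
    df_resid = n - 4
    improvement = _f_improvement(rss0, rss, df_extra=3, df_resid=df_resid, tss=tss)
    return BreakpointResult(
        method="structural_change",
        break_year=int(round(x[k])),
        slope_before=slope1,
        slope_after=slope2,
        ci95_before=ci1,
        ci95_after=ci2,
        rss=rss,
        rss_single_line=rss0,
        improvement_stat=improvement,
        supported=improvement > 1e-6,
    )


# --------------------------------------------------------------------------
# support categories and slope thresholds
# --------------------------------------------------------------------------

SUPPORT_CATEGORIES = (
    ("very_weak", 0.0, 0.1),
    ("weak", 0.1, 0.5),
    ("moderately_strong", 0.5, 0.7),
    ("strong", 0.7, 0.9),
    ("very_strong", 0.9, 1.0 + 1e-12),  # closed at 1
)


def classify_support(p: float) -> str:
    """Map a posterior change probability onto its qualitative category.

    The partition is half-open: [0, 0.1) very_weak, [0.1, 0.5) weak,
    [0.5, 0.7) moderately_strong, [0.7, 0.9) strong, [0.9, 1] very_strong.
    """
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"posterior probability must be in [0, 1], got {p}")
    for label, lo, hi in SUPPORT_CATEGORIES:
        if lo <= p < hi:
            return label
    return "very_strong"  # p == 1 exactly


@dataclass(frozen=True)
class TrendThreshold:
    """Biological-significance threshold: a total change over a horizon.

    Defaults encode 25% over 25 years. On the log scale the bounds are
    asymmetric: +ln(1 + magnitude)/horizon per year upward and
    ln(1 - magnitude)/horizon downward (both derived, never stored).
    """

    magnitude: float = 0.25
    horizon_years: float = 25.0

    @property
    def upper_log_slope(self) -> float:
        return math.log1p(self.magnitude) / self.horizon_years

    @property
    def lower_log_slope(self) -> float:
        return math.log1p(-self.magnitude) / self.horizon_years


def compare_slope_to_threshold(
    slope_ci, threshold: TrendThreshold | None = None
) -> str:
    """Categorize a slope CI against the 25%-over-25-years threshold.

    ``increasing`` if the CI lies entirely above the upward threshold,
    ``declining`` if entirely below the downward one, ``negligible`` if the
    CI is contained between the two, otherwise ``inconclusive``.
    """
    thr = threshold or TrendThreshold()
    lo, hi = float(slope_ci[0]), float(slope_ci[1])
    if lo > hi:
        raise ValidationError(f"malformed CI ({lo}, {hi})")
    if lo > thr.upper_log_slope:
        return "increasing"
    if hi < thr.lower_log_slope:
        return "declining"
    if lo > thr.lower_log_slope and hi < thr.upper_log_slope:
        return "negligible"
    return "inconclusive"


# --------------------------------------------------------------------------
# Bayesian change-point (product partition model)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ChangepointResult:
    """Per-year posterior change probabilities and mean levels."""

    years: np.ndarray
    posterior_prob: np.ndarray
    posterior_mean: np.ndarray
    n_burnin: int
    n_mcmc: int
    seed: int
    prior_p0: float
    prior_w0: float
    mc_se: np.ndarray = field(default=None, repr=False)

    def support_at(self, year: int) -> str:
        idx = np.flatnonzero(self.years == year)
        if len(idx) == 0:
            raise ValidationError(f"year {year} not in series")
        return classify_support(float(self.posterior_prob[idx[0]]))

    def to_dict(self) -> dict:
        return {
            "years": self.years.tolist(),
            "posterior_prob": self.posterior_prob.tolist(),
            "posterior_mean": self.posterior_mean.tolist(),
            "n_burnin": self.n_burnin,
            "n_mcmc": self.n_mcmc,
            "seed": self.seed,
            "prior_p0": self.prior_p0,
            "prior_w0": self.prior_w0,
        }


class _BlockState:
    """Partition bookkeeping for the Gibbs sampler, O(1) per flip.

    Maintains the set of block start indices, the total within-block sum of
    squares W, and sum_j n_j xbar_j^2 (from which the between-block SS is
    B = sum_j n_j xbar_j^2 - n xbar^2), using prefix sums of x and x^2.
    """

    def __init__(self, x: np.ndarray):
        self.n = len(x)
        self.s1 = np.concatenate(([0.0], np.cumsum(x)))
        self.s2 = np.concatenate(([0.0], np.cumsum(x * x)))
        self.grand = self.s1[-1] ** 2 / self.n
        self.starts = {0}  # block start indices; partition = sorted(starts)
        self.sorted_starts = [0]
        self.W = self._ss(0, self.n)
        self.Sb = self._mean_sq(0, self.n)

    def _ss(self, a: int, b: int) -> float:
        s = self.s1[b] - self.s1[a]
        return (self.s2[b] - self.s2[a]) - s * s / (b - a)

    def _mean_sq(self, a: int, b: int) -> float:
        s = self.s1[b] - self.s1[a]
        return s * s / (b - a)

    def merged_bounds(self, pos: int):
        """Bounds [a, c) of the merged block around candidate boundary pos.

        If pos is currently a boundary, [a, c) spans the two blocks it
        separates; otherwise it is the block containing pos.
        """
        i = bisect.bisect_right(self.sorted_starts, pos) - 1
        c = self.sorted_starts[i + 1] if i + 1 < len(self.sorted_starts) else self.n
        a = self.sorted_starts[i - 1] if self.sorted_starts[i] == pos else self.sorted_starts[i]
        return a, c

    def split_delta(self, a: int, pos: int, c: int):
        """(dW, dSb) from splitting block [a, c) at pos."""
        dW = self._ss(a, pos) + self._ss(pos, c) - self._ss(a, c)
        dSb = self._mean_sq(a, pos) + self._mean_sq(pos, c) - self._mean_sq(a, c)
        return dW, dSb

    def apply_split(self, pos: int, dW: float, dSb: float):
        self.starts.add(pos)
        bisect.insort(self.sorted_starts, pos)
        self.W += dW
        self.Sb += dSb

    def apply_merge(self, pos: int, dW: float, dSb: float):
        self.starts.discard(pos)
        self.sorted_starts.remove(pos)
        self.W -= dW
        self.Sb -= dSb

    @property
    def n_blocks(self) -> int:
        return len(self.sorted_starts)

    def block_means(self) -> np.ndarray:
        out = np.empty(self.n)
        bounds = self.sorted_starts + [self.n]
        for a, c in zip(bounds[:-1], bounds[1:]):
            out[a:c] = (self.s1[c] - self.s1[a]) / (c - a)
        return out


def bayesian_changepoint(
    years,
    values,
    prior_p0: float = 0.2,
    prior_w0: float = 0.2,
    n_burnin: int = 50,
    n_mcmc: int = 500,
    seed: int = 0,
    n_quad: int = 32,
) -> ChangepointResult:
    """Barry–Hartigan product-partition change-point analysis.

    Observations are modeled as Gaussian with a piecewise-constant mean;
    the prior change probability p and the signal fraction w carry
    Uniform(0, p0) and Uniform(0, w0) priors (defaults 0.2 each, the
    published defaults of the standard implementation of this model). A
    Gibbs sweep updates each of the n-1 change indicators from its exact
    conditional odds; the ratio's w-integral, which has no closed form, is
    evaluated by fixed Gauss–Legendre quadrature (``n_quad`` nodes), keeping
    runs deterministic for a fixed seed.

    ``posterior_prob[t]`` is the posterior probability that a new mean level
    begins at year t (position 0 is structurally 0); ``posterior_mean`` is
    the per-year block mean averaged over retained draws.
    """
    x = np.asarray(values, dtype=float).ravel()
    yr = np.asarray(years, dtype=int).ravel()
    n = len(x)
    if len(yr) != n:
        raise ValidationError("years and values differ in length")
    if n < 5:
        raise ValidationError(f"need >= 5 observations, got {n}")
    if n_mcmc < 100:
        raise ValidationError("n_mcmc must be >= 100")
    for name, v in (("prior_p0", prior_p0), ("prior_w0", prior_w0)):
        if not 0.0 < v <= 1.0:
            raise ValidationError(f"{name} must be in (0, 1], got {v}")

    prob = np.zeros(n)
    mean_acc = np.zeros(n)
    if np.ptp(x) == 0.0:
        # constant series: no evidence for any change; sampler not needed
        return ChangepointResult(
            years=yr, posterior_prob=prob, posterior_mean=x.copy(),
            n_burnin=n_burnin, n_mcmc=n_mcmc, seed=seed,
            prior_p0=prior_p0, prior_w0=prior_w0, mc_se=np.zeros(n),
        )

    rng = np.random.default_rng(seed)
    state = _BlockState(x)
    half = 0.5 * (n - 1)

    # prior odds for U=1 vs U=0 given b blocks under U=0:
    # ratio of incomplete beta integrals over p in (0, p0)
    bmax = n - 1
    prior_ratio = np.empty(bmax + 1)
    for b in range(1, bmax + 1):
        num = special.betainc(b + 1, n - b, prior_p0) * special.beta(b + 1, n - b)
        den = special.betainc(b, n - b + 1, prior_p0) * special.beta(b, n - b + 1)
        prior_ratio[b] = num / den

    # Gauss–Legendre nodes on (0, w0); w^{k/2} precomputed for all needed k
    gl_x, gl_w = np.polynomial.legendre.leggauss(n_quad)
    wn = 0.5 * prior_w0 * (gl_x + 1.0)
    wq = 0.5 * prior_w0 * gl_w
    wpow = np.array([wn ** (k / 2.0) for k in range(bmax + 1)])

    def lik_integral(k: int, W: float, B: float) -> float:
        dens = W + B * wn
        np.maximum(dens, 1e-300, out=dens)
        return float(np.dot(wq, wpow[k] * dens ** (-half)))

    accum = np.zeros(n)
    keep = 0
    for sweep in range(n_burnin + n_mcmc):
        u = rng.random(n - 1)
        for pos in range(1, n):
            is_split = pos in state.starts
            a, c = state.merged_bounds(pos)
            dW, dSb = state.split_delta(a, pos, c)
            if is_split:
                W0, Sb0 = state.W - dW, state.Sb - dSb  # merged (U=0) stats
                b0 = state.n_blocks - 1
            else:
                W0, Sb0 = state.W, state.Sb
                b0 = state.n_blocks
            W1, Sb1 = W0 + dW, Sb0 + dSb
            B0 = max(Sb0 - state.grand, 0.0)
            B1 = max(Sb1 - state.grand, 0.0)
            I1 = lik_integral(b0, max(W1, 0.0), B1)
            I0 = lik_integral(b0 - 1, max(W0, 0.0), B0)
            if I0 <= 0.0:
                p1 = 0.0 if I1 <= 0.0 else 1.0
            else:
                odds = prior_ratio[b0] * I1 / I0
                p1 = odds / (1.0 + odds)
            want_split = u[pos - 1] < p1
            if want_split and not is_split:
                state.apply_split(pos, dW, dSb)
            elif not want_split and is_split:
                state.apply_merge(pos, dW, dSb)
        if sweep >= n_burnin:
            keep += 1
            for p_ in state.sorted_starts[1:]:
                accum[p_] += 1.0
            mean_acc += state.block_means()

    prob = accum / keep
    post_mean = mean_acc / keep
    mc_se = np.sqrt(np.maximum(prob * (1.0 - prob), 0.0) / keep)
    return ChangepointResult(
        years=yr, posterior_prob=prob, posterior_mean=post_mean,
        n_burnin=n_burnin, n_mcmc=n_mcmc, seed=seed,
        prior_p0=prior_p0, prior_w0=prior_w0, mc_se=mc_se,
    )
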