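"""Window-level statistics and the rolling-window engine.

Implements the three critical-slowing-down indicators evaluated by the
pipeline — lag-1 autocorrelation, sample variance and L-skewness — plus
ordinary moment skewness for the comparison between the two skewness
estimators. L-moments are computed from the unbiased probability-weighted
moment estimators

    beta_0 = n^-1 sum_j x_(j)
    beta_1 = n^-1 sum_{j>=2} x_(j) (j-1)/(n-1)
    beta_2 = n^-1 sum_{j>=3} x_(j) (j-1)(j-2) / ((n-1)(n-2))

on the ascending order statistics x_(j), from which L1 = beta_0,
L2 = 2*beta_1 - beta_0, L3 = 6*beta_2 - 6*beta_1 + beta_0, and the ratios
t2 = L2/L1 (linear CV) and t3 = L3/L2 (L-skewness, |t3| <= 1). L-skewness
is preferred over ordinary skewness here because the moment coefficient g1
is badly biased at the small window sizes (n <= 13) this analysis uses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedStatisticError, ValidationError
from .timeseries import ProcessedSeries

__all__ = [
    "LMomentSet",
    "RollingWindowSpec",
    "IndicatorSeries",
    "lag1_autocorrelation",
    "sample_variance",
    "compute_l_moments",
    "l_skewness",
    "ordinary_skewness",
    "rolling_apply",
    "INDICATOR_FUNCS",
]


def _check_sample(sample, min_n: int) -> np.ndarray:
    x = np.asarray(sample, dtype=float).ravel()
    if len(x) < min_n:
        raise ValidationError(f"need at least {min_n} observations, got {len(x)}")
    if np.any(~np.isfinite(x)):
        raise ValidationError("sample contains non-finite values")
    return x


def lag1_autocorrelation(sample, estimator: str = "biased") -> float:
    """Sample autocorrelation at lag 1.

    ``estimator='biased'`` (default) uses the standard sample ACF with the
    overall mean and an all-n denominator,
    sum_{t<n}(x_t - xbar)(x_{t+1} - xbar) / sum_t (x_t - xbar)^2 — the
    normalization used by common ACF utilities. ``estimator='pairwise'``
    divides the mean lagged cross-product by the mean square instead
    (n/(n-1) rescaling of the biased form).
    """
    x = _check_sample(sample, 3)
    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    if denom == 0.0:
        raise UndefinedStatisticError("autocorrelation undefined: constant sample")
    num = float(np.dot(xc[:-1], xc[1:]))
    if estimator == "biased":
        return num / denom
    if estimator == "pairwise":
        n = len(x)
        return (num / (n - 1)) / (denom / n)
    raise ValidationError(f"unknown ACF estimator {estimator!r}")


def sample_variance(sample) -> float:
    """Unbiased sample variance, sum (x - xbar)^2 / (n - 1)."""
    x = _check_sample(sample, 2)
    return float(np.var(x, ddof=1))


@dataclass(frozen=True)
class LMomentSet:
    """First three L-moments and their ratios for one sample.

    ``t2``/``t3`` are NaN when undefined (L1 = 0 resp. L2 = 0).
    """

    l1: float
    l2: float
    l3: float
    t2: float
    t3: float
    n: int


def compute_l_moments(sample) -> LMomentSet:
    """L-moments L1..L3 and ratios t2, t3 via probability-weighted moments."""
    x = np.sort(_check_sample(sample, 3))
    n = len(x)
    if x[0] == x[-1]:
        # constant sample: L2 = L3 = 0 exactly (the beta formulas only give
        # this up to roundoff, which would poison the ratios)
        l1 = float(x[0])
        t2 = 0.0 if l1 != 0.0 else math.nan
        return LMomentSet(l1=l1, l2=0.0, l3=0.0, t2=t2, t3=math.nan, n=n)
    j = np.arange(1, n + 1, dtype=float)
    l1 = x.mean()
    # L2 and L3 are location-invariant: evaluate the beta formulas on the
    # centered sample to avoid catastrophic cancellation when the spread is
    # tiny relative to the mean
    xc = x - l1
    b0 = xc.mean()
    b1 = float(np.sum(xc * (j - 1))) / (n * (n - 1))
    b2 = float(np.sum(xc * (j - 1) * (j - 2))) / (n * (n - 1) * (n - 2))
    l2 = 2.0 * b1 - b0
    l3 = 6.0 * b2 - 6.0 * b1 + b0
    # l2 > 0 mathematically for a non-constant sample; guard roundoff
    l2 = max(l2, 0.0)
    t2 = l2 / l1 if l1 != 0.0 else math.nan
    if l2 != 0.0:
        # |t3| <= 1 (Hosking bound); trim roundoff excursions only
        t3 = float(np.clip(l3 / l2, -1.0, 1.0))
    else:
        t3 = math.nan
    return LMomentSet(l1=l1, l2=l2, l3=l3, t2=t2, t3=t3, n=n)


def l_skewness(sample) -> float:
    """L-skewness t3 = L3/L2; raises on a constant sample (L2 = 0)."""
    lm = compute_l_moments(sample)
    if math.isnan(lm.t3):
        raise UndefinedStatisticError("L-skewness undefined: L2 = 0 (constant sample)")
    return lm.t3


def ordinary_skewness(sample, bias_corrected: bool = False) -> float:
    """Moment coefficient of skewness g1 = m3 / m2^(3/2).

    The default uses population moments (divide by n), the biased small-sample
    estimator whose bias motivates L-skewness; ``bias_corrected=True`` gives
    the adjusted Fisher–Pearson G1.
    """
    x = _check_sample(sample, 3)
    if np.ptp(x) == 0.0:
        raise UndefinedStatisticError("skewness undefined: constant sample")
    return float(stats.skew(x, bias=not bias_corrected))


INDICATOR_FUNCS = {
    "acf1": lag1_autocorrelation,
    "variance": sample_variance,
    "l_skewness": l_skewness,
    "ordinary_skewness": ordinary_skewness,
}


@dataclass(frozen=True)
class RollingWindowSpec:
    """Rolling-window geometry: length from a fraction of n or given explicitly.

    Windows cover consecutive observations (1..s, 2..s+1, ...) and are
    labeled by the year of their last observation.
    """

    fraction: float | None = None
    length: int | None = None

    def __post_init__(self) -> None:
        if (self.fraction is None) == (self.length is None):
            raise ValidationError("give exactly one of fraction or length")
        if self.fraction is not None and not (0.0 < self.fraction <= 1.0):
            raise ValidationError(f"fraction must be in (0, 1], got {self.fraction}")
        if self.length is not None and self.length < 3:
            raise ValidationError("window length must be >= 3")

    def window_length(self, n: int) -> int:
        """Window length s for a series of n observations; s = floor(f*n)."""
        s = self.length if self.length is not None else int(self.fraction * n)
        if s < 3:
            raise ValidationError(f"window length {s} < 3 for n={n}")
        if n - s + 1 < 2:
            raise ValidationError(f"fewer than 2 windows for n={n}, s={s}")
        return s

    def label(self) -> str:
        if self.fraction is not None:
            return f"{self.fraction:g}"
        return f"len{self.length}"


@dataclass(frozen=True)
class IndicatorSeries:
    """One indicator evaluated over all rolling windows of a processed series.

    Undefined windows (e.g. constant sample for acf1) hold NaN.
    """

    indicator_name: str
    window_end_years: np.ndarray
    values: np.ndarray
    window_spec: RollingWindowSpec
    source: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        years = np.asarray(self.window_end_years, dtype=int)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "window_end_years", years)
        object.__setattr__(self, "values", values)
        if len(years) != len(values):
            raise ValidationError("window_end_years and values differ in length")
        if np.any(np.diff(years) <= 0):
            raise ValidationError("window_end_years must be strictly increasing")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def truncate_end_year(self, last_end_year: int) -> "IndicatorSeries":
        """Keep only windows ending at or before ``last_end_year``."""
        mask = self.window_end_years <= last_end_year
        if not mask.any():
            raise ValidationError(f"no windows end at or before {last_end_year}")
        return IndicatorSeries(
            indicator_name=self.indicator_name,
            window_end_years=self.window_end_years[mask],
            values=self.values[mask],
            window_spec=self.window_spec,
            source=dict(self.source),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "indicator": self.indicator_name,
                "window_end_year": self.window_end_years,
                "value": self.values,
            }
        )


def rolling_apply(
    series: ProcessedSeries,
    spec: RollingWindowSpec,
    indicator_name: str,
    detrend_window: bool = False,
    **indicator_kwargs,
) -> IndicatorSeries:
    """Evaluate an indicator over all rolling windows of a processed series.

    Window k covers observations k..k+s-1 and is labeled with the year of
    observation k+s-1, giving m = n - s + 1 values. A window on which the
    indicator is undefined yields NaN (with a warning), not an abort.
    ``detrend_window`` re-detrends each window before evaluation (the default
    relies on the global detrend done in preprocessing).
    """
    try:
        func = INDICATOR_FUNCS[indicator_name]
    except KeyError:
        raise ValidationError(
            f"unknown indicator {indicator_name!r}; "
            f"choose from {sorted(INDICATOR_FUNCS)}"
        ) from None
    n = len(series)
    s = spec.window_length(n)
    m = n - s + 1
    out = np.empty(m)
    n_undefined = 0
    for k in range(m):
        window = series.values[k : k + s]
        if detrend_window:
            xw = series.years[k : k + s].astype(float)
            slope, intercept = np.polyfit(xw, window, 1)
            window = window - (intercept + slope * xw)
        try:
            out[k] = func(window, **indicator_kwargs)
        except UndefinedStatisticError:
            out[k] = np.nan
            n_undefined += 1
    if n_undefined:
        warnings.warn(
            f"{indicator_name}: undefined on {n_undefined}/{m} windows "
            "(recorded as missing)",
            stacklevel=2,
        )
    return IndicatorSeries(
        indicator_name=indicator_name,
        window_end_years=series.years[s - 1 :],
        values=out,
        window_spec=spec,
        source=series.provenance(),
    )
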