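"""Data model, CSV I/O and preprocessing for annual abundance series.

The raw analysis input is one abundance estimate per survey year, optionally
with 95% credible bounds (as produced by state-space abundance models).
Preprocessing applies a natural-log transform followed by linear detrending:
the log transform must come first because detrended (mean-zero) data contain
negative values on which a log is undefined.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "AbundanceSeries",
    "ProcessedSeries",
    "read_series_csv",
    "write_series_csv",
    "preprocess",
    "subset_years",
]


def _as_1d(values, dtype=float) -> np.ndarray:
    arr = np.asarray(values, dtype=dtype)
    if arr.ndim != 1:
        raise ValidationError(f"expected a 1-D sequence, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class AbundanceSeries:
    """Ordered annual abundance estimates with optional 95% credible bounds.

    Invariants: years strictly increasing with no duplicates; estimates
    strictly positive (a log transform is applied downstream); bounds, when
    present, satisfy lower95 <= estimate <= upper95.
    """

    years: np.ndarray
    estimates: np.ndarray
    lower95: np.ndarray | None = None
    upper95: np.ndarray | None = None
    species_label: str = ""

    def __post_init__(self) -> None:
        years = _as_1d(self.years, dtype=int)
        estimates = _as_1d(self.estimates)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "estimates", estimates)
        if len(years) != len(estimates):
            raise ValidationError("years and estimates differ in length")
        if len(years) == 0:
            raise ValidationError("empty series")
        diffs = np.diff(years)
        if np.any(diffs <= 0):
            bad = years[1:][diffs <= 0][0]
            raise ValidationError(
                f"years must be strictly increasing; violation at year {bad}"
            )
        if np.any(~np.isfinite(estimates)) or np.any(estimates <= 0):
            idx = int(np.flatnonzero(~(estimates > 0))[0])
            raise ValidationError(
                f"non-positive or non-finite estimate at row {idx} "
                f"(year {years[idx]})"
            )
        for name in ("lower95", "upper95"):
            bound = getattr(self, name)
            if bound is not None:
                bound = _as_1d(bound)
                object.__setattr__(self, name, bound)
                if len(bound) != len(years):
                    raise ValidationError(f"{name} length mismatch")
        if self.lower95 is not None and np.any(self.lower95 > self.estimates):
            raise ValidationError("lower95 exceeds estimate")
        if self.upper95 is not None and np.any(self.upper95 < self.estimates):
            raise ValidationError("upper95 below estimate")

    def __len__(self) -> int:
        return len(self.years)

    def to_frame(self) -> pd.DataFrame:
        data = {"year": self.years, "estimate": self.estimates}
        if self.lower95 is not None:
            data["lower95"] = self.lower95
        if self.upper95 is not None:
            data["upper95"] = self.upper95
        return pd.DataFrame(data)


@dataclass(frozen=True)
class ProcessedSeries:
    """Log-transformed, linearly detrended series ready for window statistics."""

    years: np.ndarray
    values: np.ndarray
    transform_log: bool = True
    detrend_method: str = "linear"
    species_label: str = ""

    def __post_init__(self) -> None:
        years = _as_1d(self.years, dtype=int)
        values = _as_1d(self.values)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)
        if len(years) != len(values):
            raise ValidationError("years and values differ in length")
        if self.detrend_method not in ("linear", "none"):
            raise ValidationError(f"unknown detrend method {self.detrend_method!r}")

    def __len__(self) -> int:
        return len(self.years)

    def provenance(self) -> dict:
        return {
            "transform_log": self.transform_log,
            "detrend_method": self.detrend_method,
            "species_label": self.species_label,
            "n": len(self),
            "first_year": int(self.years[0]),
            "last_year": int(self.years[-1]),
        }


_DEFAULT_COLUMNS = {
    "year": "year",
    "estimate": "estimate",
    "lower95": "lower95",
    "upper95": "upper95",
    "species": "species",
}


def read_series_csv(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    species_label: str | None = None,
) -> AbundanceSeries:
    """Read an annual abundance series from a headed CSV file.

    Parameters
    ----------
    path
        CSV file with at least a year column and an estimate column.
    column_map
        Maps canonical names (``year``, ``estimate``, ``lower95``, ``upper95``,
        ``species``) to the file's actual column names. Unmapped optional
        columns are picked up under their canonical names when present.
    species_label
        Overrides any species column in the file.
    """
    cols = dict(_DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as e:
        raise FormatError(f"cannot parse CSV {path}: {e}") from e
    for required in ("year", "estimate"):
        if cols[required] not in df.columns:
            raise FormatError(
                f"missing required column {cols[required]!r} in {path} "
                f"(have {list(df.columns)})"
            )
    year_raw = pd.to_numeric(df[cols["year"]], errors="coerce")
    est_raw = pd.to_numeric(df[cols["estimate"]], errors="coerce")
    if year_raw.isna().any() or est_raw.isna().any():
        bad = int((year_raw.isna() | est_raw.isna()).idxmax())
        raise FormatError(f"non-numeric year/estimate at row {bad} in {path}")
    df = df.assign(_year=year_raw.astype(int), _est=est_raw).sort_values("_year")
    dup = df["_year"].duplicated()
    if dup.any():
        raise ValidationError(
            f"duplicate survey year {int(df['_year'][dup].iloc[0])} in {path}"
        )
    if (df["_est"] <= 0).any():
        idx = int(np.flatnonzero((df["_est"] <= 0).to_numpy())[0])
        raise ValidationError(
            f"non-positive estimate at sorted row {idx} "
            f"(year {int(df['_year'].iloc[idx])}) in {path}"
        )
    label = species_label
    if label is None and cols["species"] in df.columns:
        label = str(df[cols["species"]].iloc[0])
    kwargs = {}
    for opt in ("lower95", "upper95"):
        if cols[opt] in df.columns:
            kwargs[opt] = pd.to_numeric(df[cols[opt]], errors="coerce").to_numpy()
    return AbundanceSeries(
        years=df["_year"].to_numpy(),
        estimates=df["_est"].to_numpy(),
        species_label=label or "",
        **kwargs,
    )


def write_series_csv(series: AbundanceSeries, path: str | Path) -> None:
    """Write a series back to CSV (inverse of :func:`read_series_csv`)."""
    series.to_frame().to_csv(path, index=False)


def write_processed_csv(
    processed: ProcessedSeries, path: str | Path, sidecar: bool = True
) -> None:
    """Write a processed series plus a JSON sidecar recording the transforms."""
    path = Path(path)
    pd.DataFrame({"year": processed.years, "value": processed.values}).to_csv(
        path, index=False
    )
    if sidecar:
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(processed.provenance(), indent=2, sort_keys=True)
        )


def preprocess(
    series: AbundanceSeries | ProcessedSeries,
    apply_log: bool = True,
    detrend: str = "linear",
) -> ProcessedSeries:
    """Log-transform (first) and linearly detrend (second) a series.

    Detrending removes the OLS line of value on calendar year, so the output
    has zero mean and zero linear trend. Idempotent when re-applied with
    ``apply_log=False``.
    """
    if detrend not in ("linear", "none"):
        raise ValidationError(f"unknown detrend method {detrend!r}")
    if isinstance(series, ProcessedSeries):
        values = series.values.copy()
        label = series.species_label
        was_logged = series.transform_log
    else:
        values = series.estimates.copy()
        label = series.species_label
        was_logged = False
    years = series.years
    if apply_log:
        if np.any(values <= 0):
            idx = int(np.flatnonzero(values <= 0)[0])
            raise ValidationError(
                f"log transform undefined: non-positive value at year {years[idx]}"
            )
        values = np.log(values)
    if detrend == "linear":
        x = years.astype(float)
        slope, intercept = np.polyfit(x, values, 1)
        values = values - (intercept + slope * x)
    return ProcessedSeries(
        years=years.copy(),
        values=values,
        transform_log=apply_log or was_logged,
        detrend_method=detrend,
        species_label=label,
    )


def subset_years(series, first_year: int, last_year: int):
    """Restrict a series to surveys with first_year <= year <= last_year."""
    if first_year > last_year:
        raise ValidationError(f"empty range {first_year}–{last_year}")
    mask = (series.years >= first_year) & (series.years <= last_year)
    if not mask.any():
        raise ValidationError(
            f"no surveys in {first_year}–{last_year} "
            f"(series spans {series.years[0]}–{series.years[-1]})"
        )
    fields = {}
    for f in dataclasses.fields(series):
        v = getattr(series, f.name)
        if isinstance(v, np.ndarray) and v.shape == series.years.shape:
            fields[f.name] = v[mask]
        else:
            fields[f.name] = v
    return dataclasses.replace(series, **fields)
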