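"""Report rendering: tidy CSV tables, JSON reports, optional indicator plots."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

TREND_COLUMNS = [
    "species_label",
    "window_label",
    "indicator_name",
    "kendall_tau",
    "slope",
    "ci95_low",
    "ci95_high",
    "slope_se",
    "t_value",
    "p_value",
    "residual_df",
    "ar1_rho",
    "verdict",
    "n_windows",
    "n_missing",
]


def trend_table(df: pd.DataFrame) -> pd.DataFrame:
    """Order the screening output into the standard report column layout."""
    return df[[c for c in TREND_COLUMNS if c in df.columns]]


def config_hash(config: dict) -> str:
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json_report(path: str | Path, payload: dict) -> None:
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=_jsonable) + "\n"
    )


def plot_indicators(
    processed,
    indicator_series: list,
    taus: dict,
    out_path: str | Path,
    cutoff_year: int | None = 2000,
) -> None:
    """Indicator-vs-end-year panels with tau annotations and a cutoff marker.

    One row per indicator; each window size drawn as its own line. Headless
    backend; import is deferred so non-plotting runs never touch matplotlib.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(dict.fromkeys(s.indicator_name for s in indicator_series))
    fig, axes = plt.subplots(
        len(names) + 1, 1, figsize=(7, 2.2 * (len(names) + 1)), sharex=True
    )
    axes = np.atleast_1d(axes)
    axes[0].plot(processed.years, processed.values, "k.-", lw=0.8)
    axes[0].set_ylabel("processed\nlog abundance")
    for ax, name in zip(axes[1:], names):
        for s in indicator_series:
            if s.indicator_name != name:
                continue
            lbl = f"window {s.window_spec.label()}"
            ax.plot(s.window_end_years, s.values, ".-", lw=0.8, label=lbl)
            tau = taus.get((name, s.window_spec.label()))
            if tau is not None:
                ax.annotate(
                    f"τ={tau:.2f}", xy=(0.02, 0.85), xycoords="axes fraction",
                    fontsize=8,
                )
        ax.set_ylabel(name)
        ax.legend(fontsize=7, loc="lower right")
    if cutoff_year is not None:
        for ax in axes:
            ax.axvline(cutoff_year, color="r", lw=0.8, ls="--")
    axes[-1].set_xlabel("window end year")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
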