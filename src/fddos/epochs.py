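"""Epoch summaries and derived change parameters for one subject.

The analysis reduces each hemodynamic time series to four window means
(half-open windows, [start, end)):

* baseline — the 2 minutes immediately before asphyxia onset;
* asphyxia end — the final 15 s of asphyxia;
* 1-min CPR — the 15 s immediately following 1 min of CPR (chest molding and
  probe-placement delay make earlier CPR data unusable in practice);
* 10-min CPR — the 10th minute of CPR, i.e. CPR time in [540, 600) s.

From these, each parameter's value at 10-min CPR is expressed five ways:
absolute, change from baseline (delta), relative to baseline (%, baseline =
100%), change from 1-min CPR, and relative to 1-min CPR.  The ROSC predictor
is the mean of a parameter (in absolute, delta-from-1-min or
relative-to-1-min form) over CPR time [120, 600) s, and the same quantity is
bin-averaged over the eight 1-min intervals [2,3) ... [9,10) min for the
time-resolved analysis.

A window mean is "missing" (NaN) unless at least half of its samples pass
quality control; means are computed on available samples, never interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PARAMETERS = ("hbo2", "hb", "thc", "sto2")
FORMS = ("absolute", "delta_1min", "relative_1min")

_PARAM_COLS = {
    "hbo2": "hbo2_um",
    "hb": "hb_um",
    "thc": "thc_um",
    "sto2": "sto2_pct",
}


@dataclass(frozen=True)
class PhaseTimeline:
    """Phase boundaries of one experiment, in absolute seconds."""

    asphyxia_start_s: float = 120.0
    cpr_start_s: float = 540.0

    def __post_init__(self) -> None:
        if not 0 < self.asphyxia_start_s < self.cpr_start_s:
            raise ValueError("phase boundaries must be ordered and positive")

    def windows(self) -> dict[str, tuple[float, float]]:
        """Half-open [start, end) windows of the four named epochs."""
        a, c = self.asphyxia_start_s, self.cpr_start_s
        return {
            "baseline": (a - 120.0, a),
            "asphyxia_end": (c - 15.0, c),
            "cpr_1min": (c + 60.0, c + 75.0),
            "cpr_10min": (c + 540.0, c + 600.0),
        }

    def predictor_window(self) -> tuple[float, float]:
        """CPR [120, 600) s — the 2-to-10-min prediction window."""
        return (self.cpr_start_s + 120.0, self.cpr_start_s + 600.0)

    def minute_bins(self) -> list[tuple[float, float]]:
        """Eight half-open 1-min bins over CPR [2, 10) min."""
        c = self.cpr_start_s
        return [(c + 60.0 * m, c + 60.0 * (m + 1)) for m in range(2, 10)]


def window_mean(
    t: np.ndarray, values: np.ndarray, qc: np.ndarray, lo: float, hi: float
) -> tuple[float, int, int]:
    """QC-aware mean over [lo, hi) -> (mean-or-NaN, n_total, n_pass).

    Missing when the window holds no samples or fewer than half pass qc.
    """
    m = (t >= lo) & (t < hi)
    n_total = int(m.sum())
    ok = m & qc & np.isfinite(values)
    n_pass = int(ok.sum())
    if n_total == 0 or n_pass < 0.5 * n_total or n_pass == 0:
        return np.nan, n_total, n_pass
    return float(values[ok].mean()), n_total, n_pass


def summarize_epochs(hemo: pd.DataFrame, timeline: PhaseTimeline) -> pd.DataFrame:
    """Window means of every parameter at the four named epochs.

    Returns a DataFrame indexed by parameter with one column per epoch plus
    ``n_<epoch>`` sample counts.
    """
    t = hemo["t_s"].to_numpy(dtype=float)
    qc = (
        hemo["qc_pass"].to_numpy(dtype=bool)
        if "qc_pass" in hemo.columns
        else np.ones(len(hemo), dtype=bool)
    )
    rows = {}
    counts = {}
    for param, col in _PARAM_COLS.items():
        if col not in hemo.columns:
            continue
        v = hemo[col].to_numpy(dtype=float)
        vals = {}
        for epoch, (lo, hi) in timeline.windows().items():
            mean, n_total, n_pass = window_mean(t, v, qc, lo, hi)
            vals[epoch] = mean
            counts.setdefault(epoch, {})[param] = n_pass
        rows[param] = vals
    out = pd.DataFrame(rows).T
    for epoch in timeline.windows():
        out[f"n_{epoch}"] = pd.Series({p: counts[epoch][p] for p in out.index})
    out.index.name = "parameter"
    return out


def derive_parameters(summary: pd.DataFrame) -> pd.DataFrame:
    """The five-form family at 10-min CPR from an epoch summary table.

    Per parameter: absolute value, delta/relative versus baseline, and
    delta/relative versus 1-min CPR.  Relative forms are 100*(value/ref) and
    are missing (with everything that depends on a missing or zero reference)
    rather than inf.
    """
    val = summary["cpr_10min"]
    base = summary["baseline"]
    one = summary["cpr_1min"]

    def rel(value, ref):
        ref = ref.where(ref != 0)
        return 100.0 * value / ref

    out = pd.DataFrame(
        {
            "absolute": val,
            "delta_baseline": val - base,
            "relative_baseline": rel(val, base),
            "delta_1min": val - one,
            "relative_1min": rel(val, one),
        }
    )
    out.index.name = "parameter"
    return out


def _form_series(
    values: np.ndarray, form: str, ref_1min: float
) -> np.ndarray:
    if form == "absolute":
        return values
    if np.isnan(ref_1min):
        return np.full_like(values, np.nan)
    if form == "delta_1min":
        return values - ref_1min
    if form == "relative_1min":
        if ref_1min == 0:
            return np.full_like(values, np.nan)
        return 100.0 * values / ref_1min
    raise ValueError(f"unknown form {form!r}; expected one of {FORMS}")


def cpr_mean_predictor(
    hemo: pd.DataFrame, timeline: PhaseTimeline, parameter: str, form: str = "delta_1min"
) -> float:
    """Mean of a parameter (in the requested form) over CPR [120, 600) s.

    The 1-min-CPR epoch mean is the reference for delta/relative forms.
    Missing when under half of the window's samples pass qc.
    """
    col = _PARAM_COLS[parameter]
    t = hemo["t_s"].to_numpy(dtype=float)
    qc = (
        hemo["qc_pass"].to_numpy(dtype=bool)
        if "qc_pass" in hemo.columns
        else np.ones(len(hemo), dtype=bool)
    )
    v = hemo[col].to_numpy(dtype=float)
    ref = np.nan
    if form != "absolute":
        lo, hi = timeline.windows()["cpr_1min"]
        ref, _, _ = window_mean(t, v, qc, lo, hi)
    series = _form_series(v, form, ref)
    lo, hi = timeline.predictor_window()
    mean, _, _ = window_mean(t, series, qc, lo, hi)
    return mean


def bin_minutes(
    hemo: pd.DataFrame, timeline: PhaseTimeline, parameter: str, form: str = "delta_1min"
) -> pd.Series:
    """Per-bin qc-aware means over the eight 1-min CPR bins [2,3)...[9,10).

    Indexed by the bin's starting CPR minute (2..9); empty bins are NaN.
    """
    col = _PARAM_COLS[parameter]
    t = hemo["t_s"].to_numpy(dtype=float)
    qc = (
        hemo["qc_pass"].to_numpy(dtype=bool)
        if "qc_pass" in hemo.columns
        else np.ones(len(hemo), dtype=bool)
    )
    v = hemo[col].to_numpy(dtype=float)
    ref = np.nan
    if form != "absolute":
        lo, hi = timeline.windows()["cpr_1min"]
        ref, _, _ = window_mean(t, v, qc, lo, hi)
    series = _form_series(v, form, ref)
    means = {}
    for minute, (lo, hi) in zip(range(2, 10), timeline.minute_bins()):
        mean, _, _ = window_mean(t, series, qc, lo, hi)
        means[minute] = mean
    out = pd.Series(means, name=f"{parameter}_{form}")
    out.index.name = "cpr_minute"
    return out


def subject_predictors(hemo: pd.DataFrame, timeline: PhaseTimeline) -> dict[str, float]:
    """All nine candidate predictors (3 parameters x 3 forms) for a subject.

    The candidate set excludes [Hb] (no group association) and all
    baseline-referenced forms (not measurable after arrest recognition).
    """
    out = {}
    for param in ("hbo2", "sto2", "thc"):
        for form in FORMS:
            out[f"{param}_{form}"] = cpr_mean_predictor(hemo, timeline, param, form)
    return out
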