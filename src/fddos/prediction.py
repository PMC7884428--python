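"""ROSC prediction: specificity-weighted threshold selection and validation.

The decision statistic for each candidate parameter is its mean value over
CPR minutes 2-10.  Prediction quality is scored by the weighted Youden index

    J_w = 2 (w * sensitivity + (1 - w) * specificity) - 1,   0 <= w <= 1,

with w = 0.1 by default: specificity is emphasized because falsely reassuring
predictions in subjects who will not achieve ROSC are the costly error.  Note
the floor this induces: an arbitrarily high threshold (predict no one) gives
specificity 1, sensitivity 0 and hence J_w = 2(1 - w) - 1 = 0.8 at w = 0.1,
so a useful predictor is one whose maximum J_w rises meaningfully above 0.8
toward the ceiling of 1.

Every observed value is evaluated as a candidate decision threshold (rule:
predict ROSC when value >= threshold); ties in J_w break toward higher
specificity and then toward the higher threshold.  Discrimination is also
summarized by the trapezoid ROC AUC (identical to the tie-corrected
Mann-Whitney U divided by n1*n0) with a stratified percentile-bootstrap 95%
CI.  Out-of-sample variability comes from outcome-stratified tenfold
cross-validation, and temporal stability from applying a fixed threshold to
each fold's held-out subjects within 1-min CPR bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "weighted_youden",
    "ThresholdScan",
    "ThresholdResult",
    "threshold_scan",
    "optimal_threshold",
    "roc_and_auc",
    "kfold_cv",
    "time_resolved_performance",
]


def weighted_youden(sensitivity, specificity, w: float = 0.1):
    """J_w = 2(w*sens + (1-w)*spec) - 1; arguments must lie in [0, 1]."""
    sens = np.asarray(sensitivity, dtype=float)
    spec = np.asarray(specificity, dtype=float)
    if np.any((sens < 0) | (sens > 1)) or np.any((spec < 0) | (spec > 1)):
        raise ValueError("sensitivity and specificity must be in [0, 1]")
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must be in [0, 1]")
    out = 2.0 * (w * sens + (1.0 - w) * spec) - 1.0
    return float(out) if out.ndim == 0 else out


def _check_classes(values: np.ndarray, outcomes: np.ndarray) -> None:
    if values.shape != outcomes.shape:
        raise ValueError("values and outcomes must have equal length")
    if outcomes.all() or not outcomes.any():
        raise ValueError("both outcome classes must be present")


@dataclass
class ThresholdScan:
    """Exhaustive scan of observed values as decision thresholds."""

    thresholds: np.ndarray  # ascending; +inf = predict-no-one rule
    sensitivity: np.ndarray
    specificity: np.ndarray
    j_w: np.ndarray
    w: float


@dataclass
class ThresholdResult:
    threshold: float
    sensitivity: float
    specificity: float
    j_w: float
    w: float
    auc: float = np.nan
    auc_ci: tuple[float, float] = (np.nan, np.nan)


def threshold_scan(values, outcomes, w: float = 0.1) -> ThresholdScan:
    """Sensitivity/specificity/J_w at every observed threshold.

    The rule is "predict ROSC when value >= threshold"; a final +inf
    candidate represents the degenerate all-negative rule.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    keep = np.isfinite(v)
    v, y = v[keep], y[keep]
    _check_classes(v, y)
    cand = np.unique(v)
    thresholds = np.append(cand, np.inf)
    pos = v[y]
    neg = v[~y]
    sens = (pos[None, :] >= thresholds[:, None]).mean(axis=1)
    spec = (neg[None, :] < thresholds[:, None]).mean(axis=1)
    return ThresholdScan(thresholds, sens, spec, weighted_youden(sens, spec, w), w)


def optimal_threshold(values, outcomes, w: float = 0.1) -> ThresholdResult:
    """The J_w-maximizing threshold over all observed values.

    Ties in J_w break toward higher specificity, then toward the larger
    threshold.  The returned threshold is +inf when no observed cut beats the
    degenerate all-negative rule.
    """
    scan = threshold_scan(values, outcomes, w)
    best = np.lexsort((scan.thresholds, scan.specificity, scan.j_w))[-1]
    return ThresholdResult(
        threshold=float(scan.thresholds[best]),
        sensitivity=float(scan.sensitivity[best]),
        specificity=float(scan.specificity[best]),
        j_w=float(scan.j_w[best]),
        w=w,
    )


def _auc_mannwhitney(values: np.ndarray, outcomes: np.ndarray) -> float:
    """Tie-corrected AUC via average ranks (equals the trapezoid ROC area)."""
    ranks = rankdata(values)
    n1 = int(outcomes.sum())
    n0 = outcomes.size - n1
    u = ranks[outcomes].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_and_auc(
    values,
    outcomes,
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> dict:
    """ROC curve, trapezoid AUC and stratified percentile-bootstrap CI.

    Returns a dict with ``fpr``/``tpr`` swept over all observed thresholds
    (descending), ``auc``, ``auc_ci`` and the CI method string.  The
    trapezoid AUC equals the tie-corrected Mann-Whitney U / (n1*n0) on every
    input, ties included.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    keep = np.isfinite(v)
    v, y = v[keep], y[keep]
    _check_classes(v, y)

    thresholds = np.unique(v)[::-1]
    pos, neg = v[y], v[~y]
    tpr = np.concatenate([[0.0], (pos[None, :] >= thresholds[:, None]).mean(axis=1)])
    fpr = np.concatenate([[0.0], (neg[None, :] >= thresholds[:, None]).mean(axis=1)])
    auc = float(np.trapezoid(tpr, fpr))

    ci = (np.nan, np.nan)
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        ipos = np.flatnonzero(y)
        ineg = np.flatnonzero(~y)
        aucs = np.empty(n_boot)
        for b in range(n_boot):
            vb = np.concatenate(
                [v[rng.choice(ipos, ipos.size)], v[rng.choice(ineg, ineg.size)]]
            )
            yb = np.concatenate(
                [np.ones(ipos.size, dtype=bool), np.zeros(ineg.size, dtype=bool)]
            )
            aucs[b] = _auc_mannwhitney(vb, yb)
        lo = 100.0 * (1.0 - ci_level) / 2.0
        ci = tuple(np.percentile(aucs, [lo, 100.0 - lo]))
    return {
        "fpr": fpr,
        "tpr": tpr,
        "auc": auc,
        "auc_ci": (float(ci[0]), float(ci[1])),
        "ci_method": f"stratified percentile bootstrap, {n_boot} reps",
    }


def effective_folds(outcomes, k: int) -> int:
    """Largest usable fold count: capped by the minority-class size."""
    y = np.asarray(outcomes, dtype=bool)
    return int(max(2, min(k, y.sum(), (~y).sum())))


def _stratified_folds(outcomes: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Outcome-stratified fold test-index arrays (sklearn StratifiedKFold)."""
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    dummy = np.zeros((outcomes.size, 1))
    return [test for _, test in skf.split(dummy, outcomes.astype(int))]


def kfold_cv(
    values, outcomes, k: int = 10, w: float = 0.1, seed: int = 0
) -> pd.DataFrame:
    """Outcome-stratified k-fold cross-validation of the threshold rule.

    Per fold the threshold is derived on the training 9/10ths by
    :func:`optimal_threshold` and J_w evaluated on the held-out subjects.
    Returns one row per fold: train threshold, test sensitivity/specificity/
    J_w.  Use ``summarize_cv`` for the threshold min/max and J_w median/IQR.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    _check_classes(v, y)
    if v.size < k:
        raise ValueError("need at least k subjects")
    rows = []
    for fold, test_idx in enumerate(_stratified_folds(y, k, seed), start=1):
        train = np.ones(v.size, dtype=bool)
        train[test_idx] = False
        if y[train].all() or not y[train].any():  # cannot happen w/ stratification
            raise RuntimeError("single-class training split")
        res = optimal_threshold(v[train], y[train], w)
        vt, yt = v[test_idx], y[test_idx]
        sens = float((vt[yt] >= res.threshold).mean()) if yt.any() else np.nan
        spec = float((vt[~yt] < res.threshold).mean()) if (~yt).any() else np.nan
        jw = (
            weighted_youden(sens, spec, w)
            if np.isfinite(sens) and np.isfinite(spec)
            else np.nan
        )
        rows.append(
            {
                "fold": fold,
                "threshold": res.threshold,
                "test_sensitivity": sens,
                "test_specificity": spec,
                "test_j_w": jw,
                "n_test": int(test_idx.size),
            }
        )
    return pd.DataFrame(rows)


def summarize_cv(cv: pd.DataFrame) -> dict:
    """Threshold [min, max] and J_w median [IQR] across folds."""
    jw = cv["test_j_w"].dropna().to_numpy()
    q1, med, q3 = np.percentile(jw, [25, 50, 75]) if jw.size else (np.nan,) * 3
    thr = cv["threshold"].replace(np.inf, np.nan).dropna()
    return {
        "threshold_min": float(thr.min()) if len(thr) else np.nan,
        "threshold_max": float(thr.max()) if len(thr) else np.nan,
        "j_w_median": float(med),
        "j_w_q1": float(q1),
        "j_w_q3": float(q3),
    }


def time_resolved_performance(
    binned: pd.DataFrame,
    outcomes,
    threshold: float,
    k: int = 10,
    w: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-bin, per-fold test performance of one fixed decision threshold.

    ``binned`` holds one row per subject and one column per 1-min CPR bin
    (NaN where a bin is missing); ``threshold`` is the globally derived
    optimal cut.  For each bin and each stratified fold's held-out subjects,
    sensitivity, specificity, accuracy and J_w of the fixed rule
    "value >= threshold" are reported; empty cells are NaN.
    """
    y = np.asarray(outcomes, dtype=bool)
    _check_classes(np.zeros(y.size), y)
    rows = []
    for fold, test_idx in enumerate(_stratified_folds(y, k, seed), start=1):
        yt = y[test_idx]
        for bin_name in binned.columns:
            vt = binned[bin_name].to_numpy(dtype=float)[test_idx]
            ok = np.isfinite(vt)
            if not ok.any():
                rows.append(
                    {"fold": fold, "bin": bin_name, "sensitivity": np.nan,
                     "specificity": np.nan, "accuracy": np.nan, "j_w": np.nan}
                )
                continue
            vo, yo = vt[ok], yt[ok]
            pred = vo >= threshold
            sens = float(pred[yo].mean()) if yo.any() else np.nan
            spec = float((~pred[~yo]).mean()) if (~yo).any() else np.nan
            acc = float((pred == yo).mean())
            jw = (
                weighted_youden(sens, spec, w)
                if np.isfinite(sens) and np.isfinite(spec)
                else np.nan
            )
            rows.append(
                {"fold": fold, "bin": bin_name, "sensitivity": sens,
                 "specificity": spec, "accuracy": acc, "j_w": jw}
            )
    return pd.DataFrame(rows)


def bin_medians(perf: pd.DataFrame) -> pd.DataFrame:
    """Across-fold median/IQR/range of J_w per time bin."""
    rows = []
    for bin_name, grp in perf.groupby("bin", sort=False):
        jw = grp["j_w"].dropna().to_numpy()
        if jw.size == 0:
            rows.append({"bin": bin_name, "j_w_median": np.nan})
            continue
        q1, med, q3 = np.percentile(jw, [25, 50, 75])
        rows.append(
            {
                "bin": bin_name,
                "j_w_median": float(med),
                "j_w_q1": float(q1),
                "j_w_q3": float(q3),
                "j_w_min": float(jw.min()),
                "j_w_max": float(jw.max()),
            }
        )
    return pd.DataFrame(rows)
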