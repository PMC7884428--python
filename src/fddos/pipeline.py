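"""End-to-end orchestration: simulate -> invert -> spectroscopy -> epochs ->
stats -> prediction, as a reproducible, configured, logged run.

Every stage writes its outputs as CSV under the run directory and records
itself in ``manifest.json``; a master seed is split deterministically per
stage (SeedSequence over (master, stage-index)) so any stage can be re-run in
isolation and reproduce identical outputs.  Stages communicate through the
files they write, so the command-line interface can also run them one at a
time against an existing run directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    ArtifactSpec,
    Cohort,
    CohortConfig,
    SubjectTruth,
    _config_dict,
    forward_to_optical,
    generate_cohort,
    inject_artifacts,
    synthesize_raw_frames,
    truth_hemodynamics,
    write_cohort,
)
from .diffusion import ProbeGeometry, fit_multidistance, qc_filter
from .epochs import FORMS, PhaseTimeline, bin_minutes, derive_parameters, subject_predictors, summarize_epochs
from .prediction import (
    bin_medians,
    effective_folds,
    kfold_cv,
    optimal_threshold,
    roc_and_auc,
    summarize_cv,
    time_resolved_performance,
)
from .spectroscopy import ExtinctionTable, hemodynamics_series
from .stats import fisher_exact, group_comparison_table, signed_rank_test

STAGES = ("simulate", "spectro", "epochs", "stats", "predict", "report")

#: the nine candidate predictors (Hb and baseline-referenced forms excluded)
CANDIDATE_PREDICTORS = tuple(
    f"{p}_{f}" for p in ("hbo2", "sto2", "thc") for f in FORMS
)


@dataclass(frozen=True)
class RunConfig:
    """One pipeline run: cohort, processing mode, analysis knobs, seed."""

    outdir: str
    cohort: CohortConfig = CohortConfig()
    stages: tuple[str, ...] = STAGES
    input_mode: str = "optical"  # "truth" | "optical" | "frames"
    geometry: ProbeGeometry = ProbeGeometry()
    r2_min: float = 0.97
    w: float = 0.1
    k: int = 10
    bootstrap_reps: int = 2000
    frame_noise_ln_ac: float = 0.0
    frame_noise_phase_rad: float = 0.0
    #: additional subjects carrying a full-CPR artifact (feasibility emulation)
    extra_artifact_subjects: int = 0
    write_timeseries: bool = True
    master_seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if self.input_mode not in ("truth", "optical", "frames"):
            raise ValueError(f"unknown input mode {self.input_mode!r}")

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage child seed, < 2**31."""
        idx = STAGES.index(stage)
        return int(
            np.random.SeedSequence([self.master_seed, idx]).generate_state(1)[0]
            % (2**31)
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _load_manifest(outdir: Path) -> dict:
    p = outdir / "manifest.json"
    if p.exists():
        return json.loads(p.read_text())
    return {"version": __version__, "stages": {}}


def _save_manifest(outdir: Path, manifest: dict) -> None:
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def _log(outdir: Path, stage: str, message: str) -> None:
    with open(outdir / "run.log", "a") as fh:
        fh.write(f"[{stage}] {message}\n")


# ---------------------------------------------------------------- simulate


def stage_simulate(config: RunConfig) -> Cohort:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = replace(config.cohort, seed=config.stage_seed("simulate"))
    cohort = generate_cohort(cfg)

    if config.extra_artifact_subjects > 0:
        # additional monitored animals whose record is lost to motion artifact
        rng = np.random.default_rng(config.stage_seed("simulate") + 1)
        extra_cfg = replace(
            cfg,
            n_per_arm=(config.extra_artifact_subjects,),
            rosc_per_arm=(
                int(
                    np.round(
                        config.extra_artifact_subjects * cfg.n_rosc / cfg.n_subjects
                    )
                ),
            ),
            seed=int(rng.integers(2**31)),
        )
        extra = generate_cohort(extra_cfg)
        for j, s in enumerate(extra.subjects):
            s.id = f"x{j + 1:02d}"
            s.arm = cohort.subjects[j % len(cohort.subjects)].arm
            s.anchors["artifact_subject"] = True
        cohort.subjects.extend(extra.subjects)

    if config.write_timeseries:
        write_cohort(cohort, outdir / "cohort")
    manifest = _load_manifest(outdir)
    manifest["stages"]["simulate"] = {
        "seed": cfg.seed,
        "n_subjects": len(cohort.subjects),
        "config": _config_dict(cfg),
    }
    _save_manifest(outdir, manifest)
    _log(outdir, "simulate", f"generated {len(cohort.subjects)} subjects, seed {cfg.seed}")
    return cohort


def _load_cohort(outdir: Path) -> Cohort:
    cdir = outdir / "cohort"
    subjects_csv = cdir / "subjects.csv"
    if not subjects_csv.exists():
        raise FileNotFoundError(f"no simulated cohort under {cdir}; run simulate first")
    table = pd.read_csv(subjects_csv, float_precision="round_trip")
    truth = json.loads((cdir / "truth.json").read_text())
    cfg_d = truth["config"]
    timeline = PhaseTimeline(
        asphyxia_start_s=cfg_d["baseline_s"],
        cpr_start_s=cfg_d["baseline_s"] + cfg_d["asphyxia_s"],
    )
    subjects = []
    for _, row in table.iterrows():
        series = pd.read_csv(cdir / f"{row['id']}_timeseries.csv", float_precision="round_trip")
        subjects.append(
            SubjectTruth(
                id=row["id"],
                arm=row["arm"],
                rosc=row["outcome"] == "ROSC",
                rosc_time_s=None if pd.isna(row["rosc_time_s"]) else float(row["rosc_time_s"]),
                anchors=truth["anchors"][row["id"]],
                timeline=timeline,
                series=series,
            )
        )
    cohort_cfg = CohortConfig(seed=cfg_d["seed"])  # geometry of phases from timeline
    return Cohort(config=cohort_cfg, subjects=subjects)


# ----------------------------------------------------------------- spectro


def stage_spectro(
    config: RunConfig, cohort: Cohort | None = None
) -> tuple[dict, pd.DataFrame]:
    """Invert (if needed) and convert every subject to hemodynamics.

    Returns ``(hemo_by_id, qc_table)``; hemo CSVs and qc.csv are written.
    """
    outdir = Path(config.outdir)
    cohort = cohort or _load_cohort(outdir)
    ext = ExtinctionTable.default()
    seed = config.stage_seed("spectro")
    hemo_by_id: dict[str, pd.DataFrame] = {}
    qc_rows = []
    hdir = outdir / "hemo"
    if config.write_timeseries:
        hdir.mkdir(parents=True, exist_ok=True)

    for i, s in enumerate(cohort.subjects):
        windows = s.timeline.windows()
        cpr_window = (s.timeline.cpr_start_s, float(s.series["t_s"].iloc[-1]) + 1.0)
        is_artifact_subject = bool(s.anchors.get("artifact_subject", False))
        if config.input_mode == "truth":
            hemo = truth_hemodynamics(s)
            excluded, fail_fraction = False, 0.0
        else:
            optical = forward_to_optical(s, ext)
            if config.input_mode == "frames" or is_artifact_subject:
                rng = np.random.default_rng(
                    np.random.SeedSequence([seed, i]).generate_state(1)[0]
                )
                frames = synthesize_raw_frames(
                    optical,
                    config.geometry,
                    sigma_ln_ac=config.frame_noise_ln_ac,
                    sigma_phase_rad=config.frame_noise_phase_rad,
                    rng=rng,
                )
                if is_artifact_subject:
                    frames, _ = inject_artifacts(
                        frames,
                        replace(config.cohort.artifacts, probability=1.0),
                        seed=rng,
                        force_window=cpr_window,
                    )
                elif config.cohort.artifacts.probability > 0:
                    frames, _ = inject_artifacts(
                        frames, config.cohort.artifacts, seed=rng
                    )
                optical = fit_multidistance(frames, config.geometry)
            optical, report = qc_filter(
                optical, config.r2_min, windows=windows, cpr_window=cpr_window
            )
            excluded = report.subject_excluded
            fail_fraction = report.fail_fraction
            hemo = hemodynamics_series(optical, ext)
        hemo_by_id[s.id] = hemo
        qc_rows.append(
            {
                "id": s.id,
                "fail_fraction": fail_fraction,
                "subject_excluded": excluded,
            }
        )
        if config.write_timeseries:
            hemo.to_csv(hdir / f"{s.id}_hemo.csv", index=False)

    qc_table = pd.DataFrame(qc_rows)
    qc_table.to_csv(outdir / "qc.csv", index=False)
    manifest = _load_manifest(outdir)
    manifest["stages"]["spectro"] = {
        "seed": seed,
        "input_mode": config.input_mode,
        "r2_min": config.r2_min,
        "n_excluded": int(qc_table["subject_excluded"].sum()),
        "inputs": {"subjects.csv": _sha256(outdir / "cohort" / "subjects.csv")}
        if (outdir / "cohort" / "subjects.csv").exists()
        else {},
    }
    _save_manifest(outdir, manifest)
    _log(outdir, "spectro", f"mode={config.input_mode}, excluded={int(qc_table['subject_excluded'].sum())}")
    return hemo_by_id, qc_table


# ------------------------------------------------------------------ epochs


def stage_epochs(
    config: RunConfig,
    cohort: Cohort | None = None,
    hemo_by_id: dict | None = None,
    qc_table: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    outdir = Path(config.outdir)
    cohort = cohort or _load_cohort(outdir)
    if hemo_by_id is None:
        hdir = outdir / "hemo"
        hemo_by_id = {
            s.id: pd.read_csv(hdir / f"{s.id}_hemo.csv", float_precision="round_trip") for s in cohort.subjects
        }
    if qc_table is None:
        qc_path = outdir / "qc.csv"
        qc_table = pd.read_csv(qc_path, float_precision="round_trip") if qc_path.exists() else None
    excluded = (
        set(qc_table.loc[qc_table["subject_excluded"], "id"])
        if qc_table is not None
        else set()
    )

    epoch_rows = []
    pred_rows = []
    for s in cohort.subjects:
        if s.id in excluded:
            continue
        hemo = hemo_by_id[s.id]
        summary = summarize_epochs(hemo, s.timeline)
        derived = derive_parameters(summary)
        for param in summary.index:
            for epoch in s.timeline.windows():
                epoch_rows.append(
                    {"id": s.id, "parameter": param, "epoch": epoch,
                     "value": summary.loc[param, epoch]}
                )
            for form in derived.columns:
                epoch_rows.append(
                    {"id": s.id, "parameter": param, "epoch": f"cpr_10min_{form}",
                     "value": derived.loc[param, form]}
                )
        row = {"id": s.id, "arm": s.arm, "rosc": s.rosc}
        row.update(subject_predictors(hemo, s.timeline))
        pred_rows.append(row)

    epochs_df = pd.DataFrame(epoch_rows)
    predictors = pd.DataFrame(pred_rows)
    epochs_df.to_csv(outdir / "epochs.csv", index=False)
    predictors.to_csv(outdir / "predictors.csv", index=False)
    manifest = _load_manifest(outdir)
    manifest["stages"]["epochs"] = {
        "n_subjects": len(predictors),
        "n_excluded": len(excluded),
    }
    _save_manifest(outdir, manifest)
    _log(outdir, "epochs", f"{len(predictors)} subjects summarized")
    return epochs_df, predictors


# ------------------------------------------------------------------- stats


def stage_stats(
    config: RunConfig,
    cohort: Cohort | None = None,
    epochs_df: pd.DataFrame | None = None,
) -> dict:
    outdir = Path(config.outdir)
    cohort = cohort or _load_cohort(outdir)
    if epochs_df is None:
        epochs_df = pd.read_csv(outdir / "epochs.csv", float_precision="round_trip")
    outcome = {s.id: s.rosc for s in cohort.subjects}
    arm = {s.id: s.arm for s in cohort.subjects}

    wide = epochs_df.pivot_table(
        index="id", columns=["parameter", "epoch"], values="value"
    )
    wide.columns = [f"{p}_{e}" for p, e in wide.columns]
    wide["rosc"] = pd.Series(outcome)

    # paired asphyxia effect, all subjects: baseline vs asphyxia end
    asphyxia_rows = []
    for param in ("hbo2", "hb", "thc", "sto2"):
        b, a = f"{param}_baseline", f"{param}_asphyxia_end"
        if b in wide.columns and a in wide.columns:
            d = (wide[a] - wide[b]).dropna().to_numpy()
            if d.size:
                res = signed_rank_test(d)
                asphyxia_rows.append(
                    {"parameter": param, "n": res.n, "p_value": res.p_value,
                     "test": f"Wilcoxon signed-rank ({res.method})"}
                )
    asphyxia = pd.DataFrame(asphyxia_rows)
    asphyxia.to_csv(outdir / "asphyxia_effect.csv", index=False)

    # 10-min CPR group comparison across the derived parameter family
    value_cols = [
        c
        for c in wide.columns
        if c != "rosc"
        and ("cpr_10min" in c or c.endswith(("baseline", "asphyxia_end")))
    ]
    comparison = group_comparison_table(wide, value_cols)
    comparison.to_csv(outdir / "group_comparison.csv", index=False)

    # CPR strategy x outcome contingency and pairwise Fisher tests vs DG-CPR
    labels = pd.DataFrame(
        {"arm": pd.Series(arm), "rosc": pd.Series(outcome)}
    ).loc[wide.index]
    contingency = labels.groupby("arm")["rosc"].agg(
        rosc="sum", no_rosc=lambda x: int((~x).sum())
    )
    contingency.to_csv(outdir / "contingency.csv")
    fisher_rows = []
    ref = "DG-CPR"
    if ref in contingency.index:
        for other in contingency.index:
            if other == ref:
                continue
            table = [
                [int(contingency.loc[other, "rosc"]), int(contingency.loc[other, "no_rosc"])],
                [int(contingency.loc[ref, "rosc"]), int(contingency.loc[ref, "no_rosc"])],
            ]
            one = fisher_exact(table, "greater")
            two = fisher_exact(table, "two-sided")
            fisher_rows.append(
                {"comparison": f"{other} vs {ref}", "p_one_sided": one.p_value,
                 "p_two_sided": two.p_value, "warning": one.warning or ""}
            )
    fisher_df = pd.DataFrame(fisher_rows)
    fisher_df.to_csv(outdir / "fisher_strategy.csv", index=False)

    manifest = _load_manifest(outdir)
    manifest["stages"]["stats"] = {"n_parameters": len(comparison)}
    _save_manifest(outdir, manifest)
    _log(outdir, "stats", f"{len(comparison)} parameter comparisons")
    return {"asphyxia": asphyxia, "comparison": comparison, "fisher": fisher_df}


# ----------------------------------------------------------------- predict


def stage_predict(
    config: RunConfig,
    cohort: Cohort | None = None,
    predictors: pd.DataFrame | None = None,
    hemo_by_id: dict | None = None,
) -> dict:
    outdir = Path(config.outdir)
    cohort = cohort or _load_cohort(outdir)
    if predictors is None:
        predictors = pd.read_csv(outdir / "predictors.csv", float_precision="round_trip")
    seed = config.stage_seed("predict")
    y = predictors["rosc"].to_numpy(dtype=bool)
    k = effective_folds(y, config.k)  # small cohorts cap the fold count

    rows = []
    results = {}
    for name in CANDIDATE_PREDICTORS:
        v = predictors[name].to_numpy(dtype=float)
        res = optimal_threshold(v, y, config.w)
        roc = roc_and_auc(v, y, n_boot=config.bootstrap_reps, seed=seed)
        cv = kfold_cv(v, y, k=k, w=config.w, seed=seed)
        cv_sum = summarize_cv(cv)
        results[name] = (res, roc, cv)
        rows.append(
            {
                "parameter": name,
                "auc": roc["auc"],
                "auc_ci_lo": roc["auc_ci"][0],
                "auc_ci_hi": roc["auc_ci"][1],
                "max_j_w": res.j_w,
                "threshold": res.threshold,
                "sensitivity": res.sensitivity,
                "specificity": res.specificity,
                "cv_threshold_min": cv_sum["threshold_min"],
                "cv_threshold_max": cv_sum["threshold_max"],
                "cv_j_w_median": cv_sum["j_w_median"],
                "cv_j_w_q1": cv_sum["j_w_q1"],
                "cv_j_w_q3": cv_sum["j_w_q3"],
            }
        )
    table3 = pd.DataFrame(rows).sort_values("max_j_w", ascending=False)
    table3.to_csv(outdir / "prediction_performance.csv", index=False)

    # time-resolved fold performance of the best parameter's global threshold
    best = table3.iloc[0]["parameter"]
    param, form = best.split("_", 1)
    if hemo_by_id is None:
        hdir = outdir / "hemo"
        hemo_by_id = {
            sid: pd.read_csv(hdir / f"{sid}_hemo.csv", float_precision="round_trip") for sid in predictors["id"]
        }
    binned = pd.DataFrame(
        {
            sid: bin_minutes(
                hemo_by_id[sid], tl, param, form
            )
            for sid, tl in (
                (s.id, s.timeline) for s in cohort.subjects if s.id in set(predictors["id"])
            )
        }
    ).T
    binned.columns = [f"cpr_min_{m}" for m in binned.columns]
    binned = binned.loc[predictors["id"].tolist()]
    theta = float(table3.iloc[0]["threshold"])
    perf = time_resolved_performance(
        binned, y, theta, k=k, w=config.w, seed=seed
    )
    perf.insert(0, "parameter", best)
    perf.to_csv(outdir / "fold_performance.csv", index=False)
    per_bin = bin_medians(perf)
    per_bin.to_csv(outdir / "fold_performance_bins.csv", index=False)

    manifest = _load_manifest(outdir)
    manifest["stages"]["predict"] = {
        "seed": seed,
        "w": config.w,
        "k": k,
        "best_parameter": best,
        "threshold": theta,
    }
    _save_manifest(outdir, manifest)
    _log(outdir, "predict", f"best={best}, threshold={theta:.3g}")
    return {"table": table3, "fold_performance": perf, "per_bin": per_bin}


# ------------------------------------------------------------------ report


def stage_report(config: RunConfig) -> str:
    outdir = Path(config.outdir)
    manifest_path = outdir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest in {outdir}; nothing to report")
    manifest = json.loads(manifest_path.read_text())
    lines = ["# Run report", ""]
    warnings = []

    sim = manifest["stages"].get("simulate")
    if sim:
        lines.append(f"- subjects simulated: {sim['n_subjects']} (seed {sim['seed']})")
    qc_path = outdir / "qc.csv"
    if qc_path.exists():
        qc = pd.read_csv(qc_path, float_precision="round_trip")
        n_total = len(qc)
        n_ok = int((~qc["subject_excluded"]).sum())
        lines.append(
            f"- feasibility: {n_ok}/{n_total} subjects with usable CPR records"
        )
    pred_path = outdir / "prediction_performance.csv"
    if pred_path.exists():
        t3 = pd.read_csv(pred_path, float_precision="round_trip")
        lines.append("")
        lines.append("## Predictors ranked by max J_w")
        lines.append("")
        for _, r in t3.iterrows():
            lines.append(
                f"- {r['parameter']}: max J_w = {r['max_j_w']:.2f} at threshold "
                f"{r['threshold']:.3g}, AUC = {r['auc']:.2f} "
                f"({r['auc_ci_lo']:.2f}, {r['auc_ci_hi']:.2f}), "
                f"CV J_w median {r['cv_j_w_median']:.2f}"
            )
    else:
        warnings.append("prediction tables absent")
    bins_path = outdir / "fold_performance_bins.csv"
    if bins_path.exists():
        pb = pd.read_csv(bins_path, float_precision="round_trip")
        lines.append("")
        lines.append("## Time-resolved performance (across-fold median J_w per bin)")
        lines.append("")
        for _, r in pb.iterrows():
            lines.append(f"- {r['bin']}: {r['j_w_median']:.2f}")
    if warnings:
        lines.append("")
        lines.append("## Warnings")
        lines.extend(f"- {wmsg}" for wmsg in warnings)
    text = "\n".join(lines) + "\n"
    (outdir / "report.md").write_text(text)
    _log(outdir, "report", "written")
    return text


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the final manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "run.log").write_text("")
    cohort = hemo = qc = epochs_df = predictors = None
    if "simulate" in config.stages:
        cohort = stage_simulate(config)
    if "spectro" in config.stages:
        hemo, qc = stage_spectro(config, cohort)
    if "epochs" in config.stages:
        epochs_df, predictors = stage_epochs(config, cohort, hemo, qc)
    if "stats" in config.stages:
        stage_stats(config, cohort, epochs_df)
    if "predict" in config.stages:
        stage_predict(config, cohort, predictors, hemo)
    manifest = _load_manifest(outdir)
    manifest["skipped_stages"] = [s for s in STAGES if s not in config.stages]
    _save_manifest(outdir, manifest)
    if "report" in config.stages:
        stage_report(config)
    return _load_manifest(outdir)
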