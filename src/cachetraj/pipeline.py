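"""End-to-end analysis pipeline with file-based artifacts and a manifest.

Stage order: inclusion gating -> baseline scoring (+ outlier fences) ->
severity-sequence encoding -> pairwise DTW -> silhouette-selected k-medoids
-> null (length-based) clustering and ARI -> prevalence curves and
archetype naming -> survival evaluation (KM/log-rank, Cox concordance,
IPCW AUC series for the baseline-cachexia and persistent-cluster markers).

Every intermediate table is written as delimited text with a schema-version
comment header, and a JSON manifest records versions, seeds, the counts at
each inclusion/exclusion gate and the stage reached, so a run can be
re-executed and audited.  On a stage failure the artifacts produced so far
are preserved and the manifest names the failing stage.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .characterize import label_archetypes, prevalence_curves
from .cluster import ClusterSolution, adjusted_rand_index, k_medoids, select_k
from .cohort import ENDPOINTS, ExclusionError, PatientSeries, read_cohort
from .dtw import null_matrix, pairwise_matrix, write_distance_matrix
from .scoring import (baseline_percent_change, classify_consensus,
                      encode_sequence, remove_outliers)
from .survival import auc_series, cox_fit, km_estimate, logrank_test

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Settings for one pipeline run (defaults follow the analysis design)."""

    measurements_path: str | Path | None = None
    outcomes_path: str | Path | None = None
    truth_path: str | Path | None = None
    baseline_window_days: int = 183
    k_min: int = 2
    k_max: int = 10
    horizon_weeks: int = 156
    n_boot: int = 500
    seed: int = 1
    outdir: str | Path | None = None
    write_distances: bool = False   # the n x n matrices can be large

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        for key in ("measurements_path", "outcomes_path", "truth_path", "outdir"):
            if d[key] is not None:
                d[key] = str(d[key])
        return d


@dataclass
class PipelineResult:
    """In-memory artifacts of a pipeline run."""

    config: RunConfig
    patients: list[PatientSeries]
    included_ids: list[str]
    exclusions: pd.DataFrame
    baseline: pd.DataFrame
    sequences: list
    solution: ClusterSolution
    null_solution: ClusterSolution
    ari_null: float
    ari_truth: float | None
    curves: pd.DataFrame
    archetype_map: dict
    survival_records: pd.DataFrame
    evaluation: pd.DataFrame
    auc_tables: pd.DataFrame
    manifest: dict


def _write_table(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#cachetraj-schema={SCHEMA_VERSION}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    """Read a pipeline artifact table (skipping the schema header)."""
    return pd.read_csv(path, comment="#")


def score_cohort(patients: list[PatientSeries], window: int):
    """Gate patients, score baselines and encode severity sequences."""
    exclusions = []
    assessments = {}
    sequences = {}
    for p in patients:
        try:
            a = baseline_percent_change(p, baseline_window_days=window)
            seq = encode_sequence(p, a.reference_weight)
        except ExclusionError as exc:
            exclusions.append((p.patient_id, exc.reason))
            continue
        if "overall" not in p.event_channels:
            exclusions.append((p.patient_id, "no overall-survival channel"))
            continue
        a.category = classify_consensus(a.pct_change, a.baseline_bmi)
        assessments[p.patient_id] = a
        sequences[p.patient_id] = seq
    remove_outliers(list(assessments.values()))
    return assessments, sequences, exclusions


def run_pipeline(config: RunConfig,
                 patients: list[PatientSeries] | None = None) -> PipelineResult:
    """Execute the full analysis.  Pass ``patients`` to skip file input."""
    outdir = Path(config.outdir) if config.outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "cachetraj",
        "version": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "schema": SCHEMA_VERSION,
        "config": config.to_dict(),
        "stage": None,
        "status": "running",
    }

    def checkpoint(stage):
        manifest["stage"] = stage
        if outdir is not None:
            with open(outdir / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=2, default=str)

    try:
        stage = "read"
        if patients is None:
            patients = read_cohort(config.measurements_path, config.outcomes_path,
                                   config.truth_path)
        manifest["n_input_patients"] = len(patients)
        checkpoint(stage)

        stage = "score"
        assessments, sequences, exclusions = score_cohort(
            patients, config.baseline_window_days)
        included = sorted(assessments)
        manifest["n_included"] = len(included)
        manifest["exclusion_counts"] = (
            pd.Series([r for _, r in exclusions]).value_counts().to_dict()
            if exclusions else {})
        excl_df = pd.DataFrame(exclusions, columns=["patient_id", "reason"])
        baseline_df = pd.DataFrame([{
            "patient_id": pid,
            "reference_weight": assessments[pid].reference_weight,
            "anchor_weight": assessments[pid].anchor_weight,
            "pct_change": assessments[pid].pct_change,
            "baseline_bmi": assessments[pid].baseline_bmi,
            "category": int(assessments[pid].category),
            "outlier_flag": assessments[pid].outlier_flag,
        } for pid in included])
        if outdir is not None:
            _write_table(excl_df, outdir / "exclusions.csv")
            _write_table(baseline_df, outdir / "baseline.csv")
            seq_rows = [(pid, int(t), int(v)) for pid in included
                        for t, v in zip(sequences[pid].times, sequences[pid].values)]
            _write_table(pd.DataFrame(
                seq_rows, columns=["patient_id", "time_days", "category"]),
                outdir / "sequences.csv")
        checkpoint(stage)

        stage = "dtw"
        seq_list = [sequences[pid] for pid in included]
        dm = pairwise_matrix(seq_list)
        nm = null_matrix(seq_list)
        if outdir is not None and config.write_distances:
            write_distance_matrix(dm, outdir / "distances_dtw.csv")
            write_distance_matrix(nm, outdir / "distances_null.csv")
        checkpoint(stage)

        stage = "cluster"
        solution = select_k(dm, config.k_min, config.k_max, seed=config.seed)
        null_solution = k_medoids(nm, solution.k, seed=config.seed)
        ari_null = adjusted_rand_index(solution.labels, null_solution.labels)
        by_id = {p.patient_id: p for p in patients}
        truth = [by_id[pid].true_archetype for pid in included]
        ari_truth = (adjusted_rand_index(solution.labels, truth)
                     if all(t is not None for t in truth) else None)
        manifest.update(chosen_k=solution.k,
                        avg_silhouette=solution.avg_silhouette,
                        silhouette_trace=solution.sil_trace,
                        ari_null=ari_null, ari_truth=ari_truth)
        if outdir is not None:
            from .cluster import silhouette
            widths, _ = silhouette(dm, solution.labels)
            _write_table(pd.DataFrame({
                "patient_id": included,
                "cluster": solution.labels,
                "medoid_flag": [i in set(solution.medoids)
                                for i in range(len(included))],
                "silhouette": widths,
            }), outdir / "clusters.csv")
        checkpoint(stage)

        stage = "characterize"
        followup = np.array([by_id[pid].followup_days() for pid in included])
        curves = prevalence_curves(seq_list, followup, solution.labels,
                                   config.horizon_weeks)
        archetype_map = label_archetypes(curves)
        manifest["archetype_map"] = {str(k): v for k, v in archetype_map.items()}
        if outdir is not None:
            _write_table(curves, outdir / "prevalence.csv")
        checkpoint(stage)

        stage = "survival"
        persistent_clusters = {c for c, name in archetype_map.items()
                               if name == "persistent"}
        rec_rows = []
        for pos, pid in enumerate(included):
            p = by_id[pid]
            a = assessments[pid]
            for ep in ENDPOINTS:
                if ep not in p.event_channels:
                    continue
                t, e = p.event_channels[ep]
                rec_rows.append({
                    "patient_id": pid, "endpoint": ep, "time": t, "event": e,
                    "marker_baseline": int(a.category == 2),
                    "marker_temporal": int(solution.labels[pos]
                                           in persistent_clusters),
                    "cluster": int(solution.labels[pos]),
                    "baseline_category": int(a.category),
                    "outlier_flag": a.outlier_flag,
                })
        records = pd.DataFrame(rec_rows)
        # baseline-outlier patients are excluded from the survival comparison
        # so both markers are evaluated on the same risk set
        eval_records = records[~records["outlier_flag"]]

        os_rec = eval_records[eval_records["endpoint"] == "overall"]
        km_os = km_estimate(os_rec["time"], os_rec["event"])
        manifest["median_os_days"] = km_os.median

        eval_rows, auc_frames = [], []
        for ep in ENDPOINTS:
            r = eval_records[eval_records["endpoint"] == ep]
            if r.empty:
                continue
            for marker in ("marker_baseline", "marker_temporal"):
                chi2, dfree, p = logrank_test(r["time"], r["event"], r[marker])
                cox = cox_fit(r[["time", "event", marker]], covariates=[marker])
                eval_rows.append({
                    "endpoint": ep, "marker": marker,
                    "logrank_chi2": chi2, "logrank_df": dfree, "logrank_p": p,
                    "hazard_ratio": cox.hazard_ratio(marker),
                    "hr_ci_lower": cox.summary.loc[marker, "hr_ci_lower"],
                    "hr_ci_upper": cox.summary.loc[marker, "hr_ci_upper"],
                    "concordance": cox.concordance,
                    "n": len(r), "n_events": cox.n_events,
                })
                if np.isfinite(km_os.median):
                    s = auc_series(r["time"], r["event"], r[marker],
                                   km_os.median, endpoint=ep, marker_name=marker,
                                   n_boot=config.n_boot, seed=config.seed)
                    auc_frames.append(s.to_frame())
            chi2, dfree, p = logrank_test(r["time"], r["event"], r["cluster"])
            eval_rows.append({
                "endpoint": ep, "marker": "cluster", "logrank_chi2": chi2,
                "logrank_df": dfree, "logrank_p": p, "hazard_ratio": np.nan,
                "hr_ci_lower": np.nan, "hr_ci_upper": np.nan,
                "concordance": np.nan, "n": len(r), "n_events": int(r["event"].sum()),
            })
        evaluation = pd.DataFrame(eval_rows)
        auc_tables = (pd.concat(auc_frames, ignore_index=True)
                      if auc_frames else pd.DataFrame())
        if outdir is not None:
            _write_table(records, outdir / "survival_records.csv")
            _write_table(evaluation, outdir / "evaluation.csv")
            if not auc_tables.empty:
                _write_table(auc_tables, outdir / "auc_series.csv")
        manifest["status"] = "ok"
        checkpoint("done")
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = repr(exc)
        checkpoint(stage)
        raise

    return PipelineResult(
        config=config, patients=patients, included_ids=included,
        exclusions=excl_df, baseline=baseline_df, sequences=seq_list,
        solution=solution, null_solution=null_solution, ari_null=ari_null,
        ari_truth=ari_truth, curves=curves, archetype_map=archetype_map,
        survival_records=records, evaluation=evaluation, auc_tables=auc_tables,
        manifest=manifest)
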