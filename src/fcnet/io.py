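"""On-disk formats: plain-text TSV/CSV plus a JSON manifest.

Layout written by :func:`write_cohort` (and read back by
:func:`read_cohort_dir`):

    DIR/
      cohort.csv                     one row per subject (clinical table)
      manifest.json                  seeds, parameters, file list
      sub-XXX_timeseries.tsv         rows = ROIs (label in first column),
                                     columns = volumes
      sub-XXX_motion.tsv             rows = volumes; tx ty tz rx ry rz
      sub-XXX_confounds.tsv          rows = volumes; one column per confound
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import MotionTrace, ROITimeSeries
from .synth import SubjectData, SyntheticCohort

MOTION_COLUMNS = ("trans_x_mm", "trans_y_mm", "trans_z_mm",
                  "rot_x_deg", "rot_y_deg", "rot_z_deg")


def write_timeseries_tsv(path, ts: ROITimeSeries) -> None:
    df = pd.DataFrame(ts.data, index=list(ts.roi_labels))
    df.index.name = "roi"
    df.to_csv(path, sep="\t", float_format="%.8g")


def read_timeseries_tsv(path, tr: float) -> ROITimeSeries:
    df = pd.read_csv(path, sep="\t", index_col="roi")
    return ROITimeSeries(data=df.to_numpy(dtype=float), tr=tr,
                         roi_labels=tuple(df.index))


def write_motion_tsv(path, motion: MotionTrace) -> None:
    df = pd.DataFrame(motion.as_matrix(), columns=list(MOTION_COLUMNS))
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_motion_tsv(path) -> MotionTrace:
    df = pd.read_csv(path, sep="\t")
    m = df[list(MOTION_COLUMNS)].to_numpy(dtype=float)
    return MotionTrace(translations=m[:, :3], rotations=m[:, 3:])


def write_matrix_tsv(path, matrix: np.ndarray,
                     labels: tuple[str, ...]) -> None:
    """Square matrix with ROI labels on both axes (z-matrices etc.)."""
    df = pd.DataFrame(matrix, index=list(labels), columns=list(labels))
    df.index.name = "roi"
    df.to_csv(path, sep="\t", float_format="%.8g")


def read_matrix_tsv(path) -> tuple[np.ndarray, tuple[str, ...]]:
    df = pd.read_csv(path, sep="\t", index_col="roi")
    return df.to_numpy(dtype=float), tuple(df.index)


def write_cohort(cohort: SyntheticCohort, outdir) -> Path:
    """Write a synthetic cohort to ``outdir``; returns the manifest path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, dict[str, str]] = {}
    for subj in cohort.subjects:
        sid = subj.subject_id
        ts_f = f"{sid}_timeseries.tsv"
        mot_f = f"{sid}_motion.tsv"
        conf_f = f"{sid}_confounds.tsv"
        write_timeseries_tsv(out / ts_f, subj.timeseries)
        write_motion_tsv(out / mot_f, subj.motion)
        pd.DataFrame(
            subj.confounds,
            columns=[f"confound_{i + 1}"
                     for i in range(subj.confounds.shape[1])],
        ).to_csv(out / conf_f, sep="\t", index=False, float_format="%.8g")
        files[sid] = {"timeseries": ts_f, "motion": mot_f,
                      "confounds": conf_f}
    cohort.cohort.to_csv(out / "cohort.csv", index=False)
    cfg = dataclasses.asdict(cohort.config)
    for key in ("weaken", "strengthen"):  # EffectSpec -> plain dict
        cfg[key] = {k: list(v) if isinstance(v, tuple) else v
                    for k, v in cfg[key].items()}
    manifest = {
        "seed": cohort.seed,
        "tr_seconds": cohort.config.tr_seconds,
        "config": json.loads(json.dumps(cfg, default=list)),
        "files": files,
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return mpath


def read_cohort_dir(path) -> tuple[list[SubjectData], pd.DataFrame]:
    """Read a cohort directory back into in-memory subject data."""
    root = Path(path)
    manifest = json.loads((root / "manifest.json").read_text())
    tr = float(manifest["tr_seconds"])
    cohort = pd.read_csv(root / "cohort.csv")
    subjects = []
    for sid, entry in manifest["files"].items():
        ts = read_timeseries_tsv(root / entry["timeseries"], tr=tr)
        motion = read_motion_tsv(root / entry["motion"])
        conf = pd.read_csv(root / entry["confounds"], sep="\t") \
            .to_numpy(dtype=float)
        subjects.append(SubjectData(subject_id=sid, timeseries=ts,
                                    motion=motion, confounds=conf))
    return subjects, cohort


def save_results_tables(results, outdir) -> list[Path]:
    """Write the four result tables plus exclusions and run metadata."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    tables = {
        "table1.tsv": results.table1,
        "global_tests.tsv": results.global_tests,
        "nodal_permutation.tsv": results.nodal_permutation,
        "score_correlations.tsv": results.score_correlations,
    }
    for name, df in tables.items():
        p = out / name
        df.to_csv(p, sep="\t", index=False, float_format="%.10g")
        written.append(p)
    excl = pd.DataFrame([
        {"subject_id": r.subject_id, "excluded": r.excluded,
         "reasons": ";".join(r.reasons),
         "kept_fraction": r.kept_fraction,
         "max_translation_mm": r.max_translation_mm,
         "max_rotation_deg": r.max_rotation_deg}
        for r in results.exclusions
    ])
    p = out / "exclusions.csv"
    excl.to_csv(p, index=False, float_format="%.10g")
    written.append(p)
    meta = out / "run_metadata.json"
    meta.write_text(json.dumps(results.metadata, indent=2, default=str))
    written.append(meta)
    return written


def save_metric_tables(results, outdir) -> list[Path]:
    """Long-format per-subject metric and AUC tables."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ids = results.cohort["subject_id"].tolist()
    rows = []
    for sid, sm in zip(ids, results.subject_metrics):
        for name, vals in sm.global_curves.items():
            for t, v in zip(sm.grid, vals):
                rows.append({"subject_id": sid, "metric": name, "node": "",
                             "sparsity": t, "value": v})
    curves = pd.DataFrame(rows)
    auc_rows = []
    for sid, sm in zip(ids, results.subject_metrics):
        for name, v in sm.global_auc.items():
            auc_rows.append({"subject_id": sid, "metric": name,
                             "node": "", "auc": v})
        for name, vec in sm.nodal_auc.items():
            for node, v in enumerate(vec):
                auc_rows.append({"subject_id": sid, "metric": name,
                                 "node": results.roi_labels[node], "auc": v})
    aucs = pd.DataFrame(auc_rows)
    p1 = out / "global_curves.tsv"
    p2 = out / "auc.tsv"
    curves.to_csv(p1, sep="\t", index=False, float_format="%.10g")
    aucs.to_csv(p2, sep="\t", index=False, float_format="%.10g")
    return [p1, p2]
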