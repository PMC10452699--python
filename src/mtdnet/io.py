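"""Plain-text persistence for cohorts, networks, curves, features and reports.

Subjects are tab-separated M x P matrices without headers; a comma-separated
manifest lists (subject_id, path, label).  Curves travel as a long table
(subject_id, metric, threshold, value); features as a headered subjects x
features table.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortManifest, TimeSeriesSubject
from .networks import DynamicNetwork
from .topology import METRICS, MetricCurveSet, ThresholdGrid


def write_cohort(cohort: CohortManifest, outdir) -> Path:
    """Write one TSV per subject plus ``manifest.csv``; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort.subjects:
        path = outdir / f"{s.subject_id}.tsv"
        np.savetxt(path, s.data, delimiter="\t", fmt="%.10g")
        rows.append({"subject_id": s.subject_id, "path": path.name, "label": s.label})
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path) -> CohortManifest:
    """Load a cohort written by :func:`write_cohort` (or matching the same layout)."""
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path)
    subjects = []
    for _, row in table.iterrows():
        data = np.loadtxt(manifest_path.parent / row["path"], delimiter="\t")
        subjects.append(TimeSeriesSubject(data=data, label=row["label"],
                                          subject_id=str(row["subject_id"])))
    labels = [s.label for s in subjects]
    return CohortManifest(subjects=subjects,
                          n_positive=labels.count("positive"),
                          n_control=labels.count("control"), seed=-1)


def write_dbfn(net: DynamicNetwork, outdir) -> Path:
    """One delimited matrix per window plus an ``index.csv`` sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for d in range(net.n_windows):
        path = outdir / f"window_{d + 1:03d}.tsv"
        np.savetxt(path, net.windows[d], delimiter="\t", fmt="%.10g")
        rows.append({"window": d + 1, "path": path.name,
                     "subject_id": net.subject_id, "fisher_applied": net.fisher_applied})
    index = outdir / "index.csv"
    pd.DataFrame(rows).to_csv(index, index=False)
    return index


def read_dbfn(index_path) -> DynamicNetwork:
    index_path = Path(index_path)
    table = pd.read_csv(index_path).sort_values("window")
    mats = [np.loadtxt(index_path.parent / p, delimiter="\t") for p in table["path"]]
    return DynamicNetwork(subject_id=str(table["subject_id"].iloc[0]),
                          windows=np.stack(mats),
                          fisher_applied=bool(table["fisher_applied"].iloc[0]))


def write_curves(curve_sets, path) -> Path:
    """Long-format cohort table: subject_id, metric, threshold, value."""
    rows = []
    for cs in curve_sets:
        for metric in METRICS:
            for thr, val in zip(cs.grid.values, cs.curves[metric]):
                rows.append({"subject_id": cs.subject_id, "metric": metric,
                             "threshold": thr, "value": val})
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_curves(path) -> list:
    """Rebuild window-mean curve sets (and their grid) from the long table."""
    table = pd.read_csv(path)
    thr = np.sort(table["threshold"].unique())
    step = float(np.round(np.diff(thr).mean(), 10)) if len(thr) > 1 else float(thr[0])
    grid = ThresholdGrid(low=float(thr[0]), high=float(thr[-1]) + step / 2, step=step)
    out = []
    for sid, sub in table.groupby("subject_id", sort=False):
        curves = {}
        for metric in METRICS:
            block = sub[sub["metric"] == metric].sort_values("threshold")
            curves[metric] = block["value"].to_numpy()
        out.append(MetricCurveSet(subject_id=str(sid), grid=grid, curves=curves))
    return out


def write_features(x, subject_ids, feature_names, path, hyperparams: dict | None = None) -> Path:
    """Headered subjects x features TSV; hyperparameters go to a YAML sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(np.asarray(x), index=list(subject_ids), columns=list(feature_names))
    frame.index.name = "subject_id"
    frame.to_csv(path, sep="\t")
    if hyperparams is not None:
        with open(path.with_suffix(".params.yaml"), "w") as fh:
            yaml.safe_dump(hyperparams, fh)
    return path


def read_features(path):
    frame = pd.read_csv(path, sep="\t", index_col="subject_id")
    return frame.to_numpy(), list(frame.index.astype(str)), list(frame.columns)


def write_report(report, path) -> Path:
    """Per-fold rows plus one aggregate summary row per metric."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records = report.records.copy()
    agg = report.aggregate()
    summary = {col: "" for col in records.columns}
    summary.update(repeat="aggregate", fold="mean+/-sd")
    for m, (mean, sd) in agg.items():
        summary[m] = f"{mean:.4f}+/-{sd:.4f}"
    table = pd.concat([records, pd.DataFrame([summary])], ignore_index=True)
    table.to_csv(path, index=False)
    return path
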