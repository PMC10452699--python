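"""Feature-recipe comparisons and parameter sweeps.

Puts the derivative-curve (MTD) features side by side with the simpler
representations they are meant to improve on — area-under-the-curve
summaries of the same threshold curves, the four topological metrics at a
single threshold ("traditional"), and raw edge connectivity — under a
paired design: every recipe in one run is evaluated on identical
cross-validation folds.  Also sweeps the sliding-window (L, s) grid and the
threshold-range choices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import cross_validate
from .cohort import CohortManifest
from .features import extract_mtd, fuse_features
from .networks import DynamicNetwork, build_dbfn, make_window_scheme
from .topology import METRICS, MetricCurveSet, ThresholdGrid, binarize, metric_curves, _METRIC_FN

log = logging.getLogger("mtdnet")

RECIPE_NAMES = ("mtd_fused", "mtd_cc", "mtd_Eglobal", "mtd_Elocal", "mtd_Lp",
                "area", "traditional", "edges")


@dataclass(frozen=True)
class FeatureRecipe:
    """A named mapping from a cohort to a subjects x features matrix."""

    name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in RECIPE_NAMES:
            raise ValueError(f"unknown recipe {self.name!r}; choose from {RECIPE_NAMES}")


def area_features(curves: MetricCurveSet) -> np.ndarray:
    """Trapezoidal integral of each metric curve over the threshold grid."""
    t = curves.grid.values
    return np.array([np.trapezoid(curves.curves[m], t) for m in METRICS])


def traditional_features(net: DynamicNetwork, pr: float, use_absolute: bool = True) -> np.ndarray:
    """Window-mean (cc, Eglobal, Elocal, Lp) at one fixed threshold."""
    vals = np.empty((net.n_windows, len(METRICS)))
    for d in range(net.n_windows):
        g = binarize(net.windows[d], pr, use_absolute=use_absolute)
        vals[d] = [_METRIC_FN[m](g) for m in METRICS]
    return vals.mean(axis=0)


def edge_features(net: DynamicNetwork) -> np.ndarray:
    """Upper triangle (i < j) of the window-mean weighted matrix."""
    mean_w = net.mean_weighted()
    iu = np.triu_indices(net.n_regions, k=1)
    return mean_w[iu]


def build_networks(cohort: CohortManifest, window_length: int = 85, step: int = 3,
                   apply_fisher: bool = True) -> list:
    """One dynamic network per subject under a shared window scheme."""
    scheme = make_window_scheme(cohort.subjects[0].n_timepoints, window_length, step)
    return [build_dbfn(s, scheme, apply_fisher=apply_fisher) for s in cohort.subjects]


def build_curves(nets, grid: ThresholdGrid) -> list:
    return [metric_curves(net, grid) for net in nets]


def feature_matrix(recipe: FeatureRecipe, nets, curves, grid: ThresholdGrid,
                   n_basis: int = 10, penalty="gcv") -> np.ndarray:
    """Realize one recipe as a subjects x features matrix (subject order preserved)."""
    if recipe.name.startswith("mtd"):
        mtd = extract_mtd(curves, n_basis=n_basis, penalty=penalty)
        if recipe.name == "mtd_fused":
            return np.vstack([
                fuse_features([mtd[c.subject_id][m] for m in METRICS]).values
                for c in curves
            ])
        metric = recipe.name.split("_", 1)[1]
        return np.vstack([mtd[c.subject_id][metric].values for c in curves])
    if recipe.name == "area":
        return np.vstack([area_features(c) for c in curves])
    if recipe.name == "traditional":
        pr = recipe.params.get("pr", float((grid.low + grid.high) / 2))
        return np.vstack([traditional_features(net, pr) for net in nets])
    if recipe.name == "edges":
        return np.vstack([edge_features(net) for net in nets])
    raise ValueError(f"unhandled recipe {recipe.name!r}")


def run_comparison(cohort: CohortManifest, recipes, *, window_length: int = 85,
                   step: int = 3, grid: ThresholdGrid | None = None,
                   n_basis: int = 10, penalty="gcv", seed: int = 0,
                   cv_kwargs: dict | None = None) -> dict:
    """Evaluate several feature recipes on identical cross-validation folds.

    Networks and curves are computed once and shared; the same seed drives
    every recipe's fold assignment, so the comparison is paired.  Returns
    ``{recipe name: ClassificationReport}``.
    """
    grid = grid or ThresholdGrid()
    cv_kwargs = dict(cv_kwargs or {})
    recipes = [r if isinstance(r, FeatureRecipe) else FeatureRecipe(r) for r in recipes]
    nets = build_networks(cohort, window_length, step)
    needs_curves = any(r.name.startswith(("mtd", "area")) for r in recipes)
    curves = build_curves(nets, grid) if needs_curves else None
    y = cohort.labels
    reports, checksums = {}, None
    for recipe in recipes:
        x = feature_matrix(recipe, nets, curves, grid, n_basis=n_basis, penalty=penalty)
        report = cross_validate(x, y, seed=seed, **cv_kwargs)
        if checksums is None:
            checksums = report.fold_checksums()
        elif report.fold_checksums() != checksums:
            raise RuntimeError(f"recipe {recipe.name}: fold assignment diverged from the paired design")
        reports[recipe.name] = report
        log.info("recipe=%s n=%d %r", recipe.name, len(y), report)
    return reports


def comparison_table(reports: dict) -> pd.DataFrame:
    """Long-format table of aggregate metrics per recipe."""
    rows = []
    for name, rep in reports.items():
        agg = rep.aggregate()
        for metric, (mean, sd) in agg.items():
            rows.append({"recipe": name, "metric": metric, "mean": mean, "sd": sd})
    return pd.DataFrame(rows)


def parameter_sweep(cohort: CohortManifest, window_lengths, steps,
                    threshold_ranges=((0.01, 0.35),), *, threshold_step: float = 0.01,
                    recipe: str = "mtd_fused", n_basis: int = 10, penalty="gcv",
                    seed: int = 0, cv_kwargs: dict | None = None,
                    full_grid: bool = False) -> pd.DataFrame:
    """Sweep sliding-window (L, s) pairs and threshold ranges.

    Each configuration re-runs the full pipeline (network construction,
    curves, features, inner selection and tuning).  Configurations with
    L > M are skipped with a warning.  By default only the best step per
    (L, range) row — ranked by mean ACC — is reported; ``full_grid=True``
    returns every combination.
    """
    m = cohort.subjects[0].n_timepoints
    rows = []
    for low, high in threshold_ranges:
        grid = ThresholdGrid(low=low, high=high, step=threshold_step)
        for length in window_lengths:
            if length > m:
                log.warning("skipping L=%d: exceeds the %d available timepoints", length, m)
                continue
            for s in steps:
                reports = run_comparison(
                    cohort, [recipe], window_length=length, step=s, grid=grid,
                    n_basis=n_basis, penalty=penalty, seed=seed, cv_kwargs=cv_kwargs)
                agg = reports[recipe].aggregate()
                row = {"L": length, "s": s, "thr_low": low, "thr_high": high}
                for metric, (mean, sd) in agg.items():
                    row[f"{metric}_mean"] = mean
                    row[f"{metric}_sd"] = sd
                rows.append(row)
    table = pd.DataFrame(rows)
    if table.empty or full_grid:
        return table
    idx = table.groupby(["L", "thr_low", "thr_high"])["ACC_mean"].idxmax()
    return table.loc[sorted(idx)].reset_index(drop=True)
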