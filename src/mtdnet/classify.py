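"""Feature selection, SSA-optimized SVM, and cross-validated evaluation.

The classifier for each fold is assembled strictly from the training
portion: features are standardized with training statistics, an L1 (lasso)
path with internal cross-validation selects a sparse support, and the
sparrow search tunes the RBF-SVM hyperparameters (C, Gamma) in log10 space
by minimizing 1 - inner-CV accuracy.  The held-out fold is touched only to
produce confusion counts and decision scores; sensitivity treats the
patient-analog ("positive") group as the positive class.  AUC is computed
from decision scores by rank statistics (ties share average ranks).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC

from .ssa import SSAConfig, ssa_optimize

#: (C, Gamma) search box in log10 space
DEFAULT_LOG10_BOUNDS = np.array([[-2.0, 3.0], [-4.0, 1.0]])

METRIC_NAMES = ("ACC", "SEN", "SPE", "AUC")


def _as_binary(y) -> np.ndarray:
    """Map labels to {0, 1} with 'positive' (or 1) as the positive class."""
    arr = np.asarray(y)
    if arr.dtype.kind in "UO":
        return (arr == "positive").astype(int)
    return arr.astype(int)


def lasso_select(x: np.ndarray, y, cv: int = 5, seed: int = 0, alphas=None):
    """L1-regularized selection: indices with nonzero coefficient at the
    regularization strength chosen by internal cross-validation.

    ``x`` is expected to be standardized already (training statistics only).
    Constant columns are dropped with a warning before fitting.  Returns
    ``(indices, coefficients)`` where ``coefficients`` spans all input
    columns (zeros for dropped/unselected ones); an empty selection is a
    valid outcome, not an error.
    """
    x = np.asarray(x, dtype=float)
    yb = _as_binary(y).astype(float)
    if np.unique(yb).size < 2 or min(np.bincount(yb.astype(int))) < 2:
        raise ValueError("lasso selection needs at least 2 subjects per class")
    keep = np.flatnonzero(x.std(axis=0) > 0)
    if keep.size < x.shape[1]:
        warnings.warn(f"dropping {x.shape[1] - keep.size} constant feature column(s)", stacklevel=2)
    coefs = np.zeros(x.shape[1])
    if keep.size == 0:
        return np.array([], dtype=int), coefs
    folds = KFold(n_splits=min(cv, len(yb)), shuffle=True, random_state=seed)
    model = LassoCV(alphas=100 if alphas is None else alphas, cv=folds, max_iter=5000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(x[:, keep], yb)
    coefs[keep] = model.coef_
    return np.flatnonzero(coefs != 0), coefs


def auc_from_scores(y, scores) -> float:
    """Rank-based AUC: probability a random positive outscores a random negative."""
    yb = _as_binary(y)
    n1, n0 = int(yb.sum()), int((1 - yb).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)
    return float((ranks[yb == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> dict:
    total = tp + fp + tn + fn
    return {
        "ACC": (tp + tn) / total,
        "SEN": tp / (tp + fn) if tp + fn else np.nan,
        "SPE": tn / (tn + fp) if tn + fp else np.nan,
    }


def train_eval_svm(x_train, y_train, x_test, y_test, c: float, gamma: float) -> dict:
    """Train an RBF-kernel SVM and evaluate on the held-out samples.

    Returns confusion counts, ACC/SEN/SPE, and the continuous decision
    scores that feed AUC.  Features must already be standardized with
    training-set statistics.
    """
    if c <= 0 or gamma <= 0:
        raise ValueError(f"need C > 0 and Gamma > 0, got C={c}, Gamma={gamma}")
    ytr, yte = _as_binary(y_train), _as_binary(y_test)
    if np.unique(ytr).size < 2:
        raise ValueError(
            f"training fold contains a single class (n={len(ytr)}, positives={int(ytr.sum())})"
        )
    clf = SVC(C=c, gamma=gamma, kernel="rbf")
    clf.fit(np.asarray(x_train, dtype=float), ytr)
    pred = clf.predict(np.asarray(x_test, dtype=float))
    scores = clf.decision_function(np.asarray(x_test, dtype=float))
    tp = int(np.sum((pred == 1) & (yte == 1)))
    fp = int(np.sum((pred == 1) & (yte == 0)))
    tn = int(np.sum((pred == 0) & (yte == 0)))
    fn = int(np.sum((pred == 0) & (yte == 1)))
    out = {"TP": tp, "FP": fp, "TN": tn, "FN": fn, "scores": scores}
    out.update(confusion_metrics(tp, fp, tn, fn))
    return out


def _default_pipeline_ssa(seed: int) -> SSAConfig:
    # desk-scale hyperparameter search: 8 sparrows x 12 iterations per fold
    return SSAConfig(bounds=DEFAULT_LOG10_BOUNDS, n_sparrows=8, max_iter=12, seed=seed)


@dataclass
class FoldModel:
    """Everything fitted on one training fold (never sees test labels)."""

    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    selected: np.ndarray
    lasso_coefs: np.ndarray
    c: float
    gamma: float
    svm: SVC
    used_all_features: bool

    def transform(self, x: np.ndarray) -> np.ndarray:
        z = (np.asarray(x, dtype=float) - self.scaler_mean) / self.scaler_scale
        return z[:, self.selected]

    def checksum(self) -> str:
        """Digest of the training-fold artifacts (selection + hyperparameters)."""
        h = hashlib.sha256()
        h.update(self.scaler_mean.tobytes())
        h.update(self.scaler_scale.tobytes())
        h.update(np.asarray(self.selected, dtype=np.int64).tobytes())
        h.update(np.array([self.c, self.gamma]).tobytes())
        return h.hexdigest()


def fit_fold(x_train, y_train, *, ssa_cfg: SSAConfig | None = None, seed: int = 0,
             inner_cv: int = 5, use_lasso: bool = True) -> FoldModel:
    """Fit one fold's full pipeline from training data alone."""
    x_train = np.asarray(x_train, dtype=float)
    ytr = _as_binary(y_train)
    mean = x_train.mean(axis=0)
    scale = x_train.std(axis=0)
    scale[scale == 0] = 1.0
    z = (x_train - mean) / scale

    if use_lasso:
        selected, coefs = lasso_select(z, ytr, seed=seed)
        used_all = selected.size == 0
        if used_all:  # empty selection: fall back to the full feature set
            selected = np.arange(z.shape[1])
    else:
        selected, coefs = np.arange(z.shape[1]), np.zeros(z.shape[1])
        used_all = True
    zs = z[:, selected]

    k_inner = min(inner_cv, int(np.bincount(ytr).min()))
    inner = StratifiedKFold(n_splits=max(2, k_inner), shuffle=True, random_state=seed)
    splits = list(inner.split(zs, ytr))

    def neg_inner_accuracy(pos):
        c, gamma = 10.0 ** pos[0], 10.0 ** pos[1]
        accs = []
        for tr, va in splits:
            clf = SVC(C=c, gamma=gamma, kernel="rbf")
            clf.fit(zs[tr], ytr[tr])
            accs.append(float(np.mean(clf.predict(zs[va]) == ytr[va])))
        return 1.0 - float(np.mean(accs))

    cfg = ssa_cfg if ssa_cfg is not None else _default_pipeline_ssa(seed)
    if not np.array_equal(cfg.bounds.shape, (2, 2)):
        raise ValueError("SSA config for (C, Gamma) tuning must be 2-dimensional")
    result = ssa_optimize(neg_inner_accuracy, cfg)
    c, gamma = 10.0 ** result.best_position[0], 10.0 ** result.best_position[1]

    svm = SVC(C=c, gamma=gamma, kernel="rbf")
    svm.fit(zs, ytr)
    return FoldModel(scaler_mean=mean, scaler_scale=scale, selected=selected,
                     lasso_coefs=coefs, c=float(c), gamma=float(gamma), svm=svm,
                     used_all_features=used_all)


def eval_fold(model: FoldModel, x_test, y_test) -> dict:
    """Confusion counts, ACC/SEN/SPE/AUC and scores for one held-out fold."""
    yte = _as_binary(y_test)
    zs = model.transform(x_test)
    pred = model.svm.predict(zs)
    scores = model.svm.decision_function(zs)
    tp = int(np.sum((pred == 1) & (yte == 1)))
    fp = int(np.sum((pred == 1) & (yte == 0)))
    tn = int(np.sum((pred == 0) & (yte == 0)))
    fn = int(np.sum((pred == 0) & (yte == 1)))
    rec = {"TP": tp, "FP": fp, "TN": tn, "FN": fn, "scores": scores}
    rec.update(confusion_metrics(tp, fp, tn, fn))
    rec["AUC"] = auc_from_scores(yte, scores) if 0 < yte.sum() < len(yte) else np.nan
    return rec


@dataclass
class ClassificationReport:
    """Fold-wise records plus mean +/- sd aggregates of ACC/SEN/SPE/AUC."""

    records: pd.DataFrame
    n_subjects: int
    seed: int

    def aggregate(self) -> dict:
        out = {}
        for m in METRIC_NAMES:
            vals = self.records[m].astype(float)
            out[m] = (float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0)
        return out

    def summary_frame(self) -> pd.DataFrame:
        agg = self.aggregate()
        return pd.DataFrame({m: {"mean": agg[m][0], "sd": agg[m][1]} for m in METRIC_NAMES}).T

    def fold_checksums(self) -> list:
        return list(self.records["fold_checksum"])

    def __repr__(self):
        agg = self.aggregate()
        parts = ", ".join(f"{m}={agg[m][0]:.3f}+/-{agg[m][1]:.3f}" for m in METRIC_NAMES)
        return f"ClassificationReport(n={self.n_subjects}, {parts})"


def cross_validate(x, y, k: int = 10, *, ssa_cfg: SSAConfig | None = None,
                   repeats: int = 10, seed: int = 0, inner_cv: int = 5,
                   use_lasso: bool = True) -> ClassificationReport:
    """Repeated stratified k-fold cross-validation of the full fold pipeline.

    Standardization, lasso selection, and the (C, Gamma) search are fit on
    each training fold only.  Metrics are aggregated as mean +/- sd over
    folds x repeats.  Identical inputs and seed give identical reports.
    """
    x = np.asarray(x, dtype=float)
    yb = _as_binary(y)
    if min(np.bincount(yb)) < k:
        k = max(2, int(min(np.bincount(yb))))  # keep both classes in every fold
    base = np.random.default_rng(seed)
    rows = []
    for rep in range(repeats):
        fold_seed = int(base.integers(2 ** 31 - 1))
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=fold_seed)
        for fold_i, (tr, te) in enumerate(skf.split(x, yb)):
            if np.unique(yb[te]).size < 2 or np.unique(yb[tr]).size < 2:
                raise ValueError(f"fold {fold_i} lost a class despite stratification")
            model = fit_fold(x[tr], yb[tr], ssa_cfg=ssa_cfg, seed=fold_seed + fold_i,
                             inner_cv=inner_cv, use_lasso=use_lasso)
            rec = eval_fold(model, x[te], yb[te])
            rec.pop("scores")
            rec.update(repeat=rep, fold=fold_i, C=model.c, Gamma=model.gamma,
                       n_selected=int(model.selected.size),
                       fold_checksum=hashlib.sha256(np.sort(te).astype(np.int64).tobytes()).hexdigest()[:16],
                       model_checksum=model.checksum()[:16])
            rows.append(rec)
    records = pd.DataFrame(rows)
    return ClassificationReport(records=records, n_subjects=len(yb), seed=seed)


def feature_weight_percentages(weights, blocks: dict) -> dict:
    """Share of total absolute weight carried by each feature block.

    ``blocks`` maps a name (e.g. a metric) to the indices of its features in
    the fused layout.  Percentages sum to 100; an all-zero weight vector has
    no defined shares and is reported as NaN for every block.
    """
    w = np.abs(np.asarray(weights, dtype=float))
    total = w.sum()
    if total == 0:
        return {name: float("nan") for name in blocks}
    return {name: 100.0 * float(w[np.asarray(idx, dtype=int)].sum()) / total
            for name, idx in blocks.items()}
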