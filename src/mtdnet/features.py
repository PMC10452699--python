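"""Multi-threshold derivative (MTD) features via penalized B-spline smoothing.

A subject's metric-vs-threshold curve is treated as noisy samples of a smooth
function y(t).  In the functional-data-analysis style the function is
expanded in a cubic B-spline basis, y(t) = c' phi(t), and the coefficients
minimize

    sum_j (y_j - c' phi(t_j))^2  +  lambda * integral (c' phi''(t))^2 dt,

i.e. squared residuals plus an integrated-squared-second-derivative
roughness penalty.  As lambda grows the fit tends to a straight line.  The
MTD feature is the first derivative of the fitted curve sampled back on the
threshold grid; the four per-metric derivative vectors can be concatenated
("linearly fused") into one feature vector per subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.interpolate import BSpline

from .topology import METRICS, WINDOW_MEAN, MetricCurveSet, ThresholdGrid

FUSED = "fused"
DEFAULT_LAMBDA_LADDER = np.logspace(-6, 2, 9)


@dataclass
class SplineFit:
    """A fitted penalized B-spline curve.

    ``knots`` is the full clamped knot vector; ``basis_order`` is the spline
    order (degree + 1, so 4 = cubic).  The fit is evaluable anywhere inside
    ``fit_domain``.
    """

    basis_order: int
    n_basis: int
    coefficients: np.ndarray
    penalty: float
    knots: np.ndarray
    fit_domain: tuple

    @property
    def degree(self) -> int:
        return self.basis_order - 1

    def _bspline(self) -> BSpline:
        return BSpline(self.knots, self.coefficients, self.degree, extrapolate=False)

    def __call__(self, t) -> np.ndarray:
        return np.asarray(self._bspline()(t), dtype=float)

    def derivative(self, t, order: int = 1) -> np.ndarray:
        return np.asarray(self._bspline().derivative(order)(t), dtype=float)


def _knot_vector(grid: np.ndarray, n_basis: int, order: int) -> np.ndarray:
    """Clamped knot vector with interior knots at equally spaced quantiles of the grid."""
    degree = order - 1
    n_interior = n_basis - order
    low, high = float(grid[0]), float(grid[-1])
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(grid, qs)
    else:
        interior = np.array([])
    return np.concatenate([np.full(degree + 1, low), interior, np.full(degree + 1, high)])


def _basis_matrix(x: np.ndarray, knots: np.ndarray, n_basis: int, degree: int,
                  deriv: int = 0) -> np.ndarray:
    spl = BSpline(knots, np.eye(n_basis), degree, extrapolate=False)
    if deriv:
        spl = spl.derivative(deriv)
    out = np.asarray(spl(x), dtype=float)
    return np.nan_to_num(out)


def penalty_matrix(knots: np.ndarray, n_basis: int, order: int) -> np.ndarray:
    """Exact Gram matrix of basis second derivatives, R_ab = int phi_a'' phi_b'' dt.

    The second derivative of an order-``order`` spline is piecewise
    polynomial of degree order-3 on each knot span, so fixed-order
    Gauss-Legendre quadrature per span is exact.
    """
    degree = order - 1
    npts = max(degree, 2)
    gx, gw = np.polynomial.legendre.leggauss(npts)
    spans = np.unique(knots)
    r = np.zeros((n_basis, n_basis))
    for a, b in zip(spans[:-1], spans[1:]):
        half = (b - a) / 2.0
        pts = a + half * (gx + 1.0)
        d2 = _basis_matrix(pts, knots, n_basis, degree, deriv=2)
        r += half * (d2 * gw[:, None]).T @ d2
    return r


def fit_penalized_spline(grid, y, n_basis: int = 10, penalty: float = 0.0,
                         basis_order: int = 4) -> SplineFit:
    """Fit c to minimize ||y - B c||^2 + penalty * c' R c.

    Solved as an augmented least-squares system for numerical stability.  At
    ``penalty = 0`` the system must be exactly or over-determined; an excess
    basis is rejected with guidance.
    """
    t = np.asarray(grid, dtype=float)
    yv = np.asarray(y, dtype=float)
    if t.ndim != 1 or yv.shape != t.shape:
        raise ValueError("grid and y must be 1-D arrays of equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("grid must be strictly increasing")
    if penalty < 0:
        raise ValueError(f"penalty must be >= 0, got {penalty}")
    if n_basis < basis_order:
        raise ValueError(f"n_basis ({n_basis}) must be >= basis_order ({basis_order})")
    knots = _knot_vector(t, n_basis, basis_order)
    bmat = _basis_matrix(t, knots, n_basis, basis_order - 1)
    if penalty == 0.0:
        if n_basis > len(t) or np.linalg.matrix_rank(bmat) < n_basis:
            raise ValueError(
                f"unpenalized fit with {n_basis} basis functions on {len(t)} points is "
                "singular; raise the penalty or lower n_basis"
            )
        design, target = bmat, yv
    else:
        r = penalty_matrix(knots, n_basis, basis_order)
        evals, evecs = np.linalg.eigh(r)
        root = evecs * np.sqrt(np.clip(evals, 0.0, None))
        design = np.vstack([bmat, np.sqrt(penalty) * root.T])
        target = np.concatenate([yv, np.zeros(n_basis)])
    coef, *_ = np.linalg.lstsq(design, target, rcond=None)
    return SplineFit(basis_order=basis_order, n_basis=n_basis, coefficients=coef,
                     penalty=penalty, knots=knots, fit_domain=(float(t[0]), float(t[-1])))


def roughness(fit: SplineFit) -> float:
    """Integrated squared second derivative of the fitted curve."""
    r = penalty_matrix(fit.knots, fit.n_basis, fit.basis_order)
    return float(fit.coefficients @ r @ fit.coefficients)


def select_penalty_gcv(grid, y, n_basis: int = 10,
                       ladder: Sequence[float] = DEFAULT_LAMBDA_LADDER,
                       basis_order: int = 4) -> float:
    """Pick the roughness penalty by generalized cross-validation over a ladder.

    GCV(lambda) = n * RSS / (n - tr(H))^2 with H the smoother matrix.
    """
    t = np.asarray(grid, dtype=float)
    yv = np.asarray(y, dtype=float)
    knots = _knot_vector(t, n_basis, basis_order)
    bmat = _basis_matrix(t, knots, n_basis, basis_order - 1)
    r = penalty_matrix(knots, n_basis, basis_order)
    btb, bty = bmat.T @ bmat, bmat.T @ yv
    n = len(t)
    best_lam, best_score = None, np.inf
    for lam in ladder:
        try:
            coef = np.linalg.solve(btb + lam * r, bty)
        except np.linalg.LinAlgError:
            continue
        fitted = bmat @ coef
        rss = float(((yv - fitted) ** 2).sum())
        edf = float(np.trace(np.linalg.solve(btb + lam * r, btb)))
        if n - edf <= 0:
            continue
        score = n * rss / (n - edf) ** 2
        if score < best_score:
            best_lam, best_score = float(lam), score
    if best_lam is None:
        raise ValueError("GCV failed for every penalty on the ladder")
    return best_lam


@dataclass
class MTDFeature:
    """Derivative-curve feature vector for one subject and one metric."""

    subject_id: str
    metric: str
    values: np.ndarray
    grid_ref: ThresholdGrid

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("MTD feature values must be finite")
        if self.metric not in METRICS + (FUSED,):
            raise ValueError(f"unknown metric {self.metric!r}")
        expected = len(self.grid_ref) * (len(METRICS) if self.metric == FUSED else 1)
        if self.values.shape != (expected,):
            raise ValueError(
                f"feature length {self.values.shape} does not match the grid "
                f"({expected} expected for metric {self.metric!r})"
            )


def derivative_curve(fit: SplineFit, grid) -> np.ndarray:
    """First derivative of the fitted curve evaluated on ``grid`` (inside the domain)."""
    t = np.asarray(grid, dtype=float)
    low, high = fit.fit_domain
    if t.min() < low - 1e-12 or t.max() > high + 1e-12:
        raise ValueError(f"grid extends outside the fit domain [{low}, {high}]")
    return fit.derivative(np.clip(t, low, high))


def extract_mtd(curve_sets: Sequence[MetricCurveSet], n_basis: int = 10,
                penalty="gcv", basis_order: int = 4) -> dict:
    """Fit-then-differentiate every subject's four metric curves.

    ``penalty`` is either a fixed non-negative value or ``"gcv"`` (pick the
    roughness penalty per curve by generalized cross-validation — an
    unsupervised choice, so no label information is involved).  Returns
    ``{subject_id: {metric: MTDFeature}}``; the output is independent of the
    order in which subjects are supplied.
    """
    if not curve_sets:
        raise ValueError("no curve sets supplied")
    grid = curve_sets[0].grid
    for cs in curve_sets:
        if not np.allclose(cs.grid.values, grid.values):
            raise ValueError(f"subject {cs.subject_id}: threshold grid differs from the cohort grid")
        if cs.aggregation != WINDOW_MEAN:
            raise ValueError("extract_mtd expects window-mean aggregated curves")
    out = {}
    for cs in curve_sets:
        feats = {}
        for metric in METRICS:
            y = cs.curves[metric]
            try:
                lam = select_penalty_gcv(grid.values, y, n_basis, basis_order=basis_order) \
                    if penalty == "gcv" else float(penalty)
                fit = fit_penalized_spline(grid.values, y, n_basis, lam, basis_order)
                deriv = derivative_curve(fit, grid.values)
            except ValueError as err:
                raise ValueError(f"subject {cs.subject_id}, metric {metric}: {err}") from err
            feats[metric] = MTDFeature(subject_id=cs.subject_id, metric=metric,
                                       values=deriv, grid_ref=grid)
        out[cs.subject_id] = feats
    return out


def fuse_features(features: Sequence[MTDFeature]) -> MTDFeature:
    """Linearly fuse one subject's four MTD vectors by concatenation.

    The order is part of the contract: cc, Eglobal, Elocal, Lp.
    """
    if len(features) != len(METRICS):
        raise ValueError(f"fusion requires exactly {len(METRICS)} features, got {len(features)}")
    sids = {f.subject_id for f in features}
    if len(sids) != 1:
        raise ValueError(f"fusion requires features from a single subject, got {sorted(sids)}")
    order = tuple(f.metric for f in features)
    if order != METRICS:
        raise ValueError(f"features must be ordered {METRICS}, got {order}")
    return MTDFeature(subject_id=features[0].subject_id, metric=FUSED,
                      values=np.concatenate([f.values for f in features]),
                      grid_ref=features[0].grid_ref)


def fused_block_slices(grid: ThresholdGrid) -> dict:
    """Index blocks of each metric inside a fused feature vector."""
    n = len(grid)
    return {m: np.arange(i * n, (i + 1) * n) for i, m in enumerate(METRICS)}


@dataclass
class GroupTestResult:
    """Independent-samples t-test on a scalar summary of per-subject features."""

    metric: str
    t_statistic: float
    p_value: float
    group_means: tuple

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def group_difference_test(features: Sequence[MTDFeature], labels: Sequence[str],
                          summary: str = "mean") -> GroupTestResult:
    """Two-sided two-sample t-test between the positive and control groups.

    Each subject's feature vector is reduced to a scalar — its mean by
    default, or its first principal-component score (``summary="pc1"``).
    ``group_means`` holds the mean feature vector of each group
    (positive first).
    """
    if len(features) != len(labels):
        raise ValueError("features and labels must align")
    mat = np.vstack([f.values for f in features])
    lab = np.asarray(labels)
    pos, ctl = mat[lab == "positive"], mat[lab == "control"]
    if len(pos) < 2 or len(ctl) < 2:
        raise ValueError("each group needs at least 2 subjects")
    if summary == "mean":
        scalar = mat.mean(axis=1)
    elif summary == "pc1":
        centered = mat - mat.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        scalar = centered @ vt[0]
    else:
        raise ValueError(f"unknown summary {summary!r}")
    s_pos, s_ctl = scalar[lab == "positive"], scalar[lab == "control"]
    if np.ptp(scalar) == 0:
        tstat, pval = 0.0, 1.0  # identical samples: no evidence of a difference
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            tstat, pval = stats.ttest_ind(s_pos, s_ctl)
        if not np.isfinite(pval):
            tstat, pval = 0.0, 1.0
    return GroupTestResult(metric=features[0].metric, t_statistic=float(tstat),
                           p_value=float(pval),
                           group_means=(pos.mean(axis=0), ctl.mean(axis=0)))
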