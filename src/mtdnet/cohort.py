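"""Synthetic two-group cohorts of ROI time series with modular covariance.

Real resting-state fMRI cohorts for cognitive-impairment studies are rarely
shareable, so this module generates surrogate data with the one property the
downstream pipeline actually consumes: a known inter-regional correlation
structure.  Regions are grouped into modules; within-module correlation is
higher than between-module correlation, and the "patient" group is emulated
by weakening within-module correlations by a configurable amount (reduced
functional integration/segregation).

Time series are stationary multivariate Gaussian draws.  No hemodynamic
response, scanner drift or head motion is simulated; an optional AR(1)
temporal-smoothing coefficient is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

POSITIVE = "positive"
CONTROL = "control"
LABELS = (POSITIVE, CONTROL)

_SEED_MASK = 0x7FFFFFFF  # keep derived seeds in int32 range


def equal_modules(n_regions: int, n_modules: int) -> np.ndarray:
    """Assign ``n_regions`` regions to ``n_modules`` near-equal contiguous modules."""
    if n_modules < 1 or n_modules > n_regions:
        raise ValueError(f"need 1 <= n_modules <= n_regions, got {n_modules} for {n_regions} regions")
    return np.repeat(np.arange(n_modules), np.diff(np.linspace(0, n_regions, n_modules + 1).astype(int)))


@dataclass(frozen=True)
class CovarianceSpec:
    """Block-structured correlation model for one group of subjects.

    Parameters
    ----------
    n_regions
        Number of ROIs (P).
    module_assignment
        Integer module id per region, length ``n_regions``.
    intra_corr
        Correlation between regions in the same module, in [0, 1).
    inter_corr
        Correlation between regions in different modules, in [0, 1);
        must not exceed ``intra_corr``.
    noise_sd
        Marginal standard deviation of every region's signal (> 0).  The
        correlation structure is unaffected by this scale.
    """

    n_regions: int
    module_assignment: np.ndarray
    intra_corr: float = 0.6
    inter_corr: float = 0.1
    noise_sd: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "module_assignment", np.asarray(self.module_assignment, dtype=int))
        if self.n_regions < 2:
            raise ValueError(f"n_regions must be >= 2, got {self.n_regions}")
        if self.module_assignment.shape != (self.n_regions,):
            raise ValueError("module_assignment must have one entry per region")
        if not (0.0 <= self.inter_corr <= self.intra_corr < 1.0):
            raise ValueError(
                f"need 0 <= inter_corr <= intra_corr < 1, got inter={self.inter_corr}, intra={self.intra_corr}"
            )
        if not self.noise_sd > 0:
            raise ValueError(f"noise_sd must be > 0, got {self.noise_sd}")


def default_spec(n_regions: int = 20, n_modules: int = 4,
                 intra_corr: float = 0.6, inter_corr: float = 0.1,
                 noise_sd: float = 1.0) -> CovarianceSpec:
    """Desk-scale default: 20 regions in 4 modules (90 regions mirrors a
    whole-brain AAL-style parcellation when needed)."""
    return CovarianceSpec(n_regions, equal_modules(n_regions, n_modules),
                          intra_corr, inter_corr, noise_sd)


def build_covariance(spec: CovarianceSpec) -> np.ndarray:
    """Construct the P x P covariance implied by ``spec``.

    Entry (i, j) is ``intra_corr`` when i and j share a module,
    ``inter_corr`` otherwise, with a unit diagonal, all scaled by
    ``noise_sd**2``.  Raises if the result is not positive definite.
    """
    same = spec.module_assignment[:, None] == spec.module_assignment[None, :]
    corr = np.where(same, spec.intra_corr, spec.inter_corr)
    np.fill_diagonal(corr, 1.0)
    eigmin = float(np.linalg.eigvalsh(corr).min())
    if eigmin <= 0:
        raise ValueError(
            f"correlation model is not positive definite (smallest eigenvalue {eigmin:.3e}); "
            "reduce inter_corr or module imbalance"
        )
    return spec.noise_sd ** 2 * corr


@dataclass
class TimeSeriesSubject:
    """One subject's ROI time-series matrix (M timepoints x P regions)."""

    data: np.ndarray
    label: str
    subject_id: str

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (timepoints x regions) matrix")
        m, p = self.data.shape
        if m < 2 or p < 2:
            raise ValueError(f"need at least 2 timepoints and 2 regions, got {m} x {p}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if np.any(self.data.std(axis=0) <= 0):
            raise ValueError("every region must have positive variance")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


def sample_subject(cov: np.ndarray, n_timepoints: int, label: str, seed: int,
                   subject_id: str = "subject", ar_coef: float = 0.0) -> TimeSeriesSubject:
    """Draw one subject from a zero-mean multivariate normal with covariance ``cov``.

    ``ar_coef`` in [0, 1) optionally applies stationary AR(1) temporal
    smoothing to the innovations before imposing the spatial covariance.
    """
    cov = np.asarray(cov, dtype=float)
    if n_timepoints < 2:
        raise ValueError(f"n_timepoints must be >= 2, got {n_timepoints}")
    if not 0.0 <= ar_coef < 1.0:
        raise ValueError(f"ar_coef must be in [0, 1), got {ar_coef}")
    chol = np.linalg.cholesky(cov)  # raises on non-PD input
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_timepoints, cov.shape[0]))
    if ar_coef > 0.0:
        scale = np.sqrt(1.0 - ar_coef ** 2)
        for t in range(1, n_timepoints):
            z[t] = ar_coef * z[t - 1] + scale * z[t]
    return TimeSeriesSubject(data=z @ chol.T, label=label, subject_id=subject_id)


@dataclass
class CohortManifest:
    """A labelled cohort of subjects plus the seed that generated it."""

    subjects: list
    n_positive: int
    n_control: int
    seed: int

    def __post_init__(self):
        n_pos = sum(1 for s in self.subjects if s.label == POSITIVE)
        n_ctl = sum(1 for s in self.subjects if s.label == CONTROL)
        if (n_pos, n_ctl) != (self.n_positive, self.n_control):
            raise ValueError(
                f"label counts ({n_pos} positive, {n_ctl} control) disagree with "
                f"declared ({self.n_positive}, {self.n_control})"
            )

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.subjects])


def generate_cohort(n_pos: int, n_ctrl: int, n_timepoints: int,
                    base_spec: CovarianceSpec, effect: float, seed: int,
                    ar_coef: float = 0.0) -> CohortManifest:
    """Generate a two-group cohort with a known group difference.

    Controls are drawn from ``base_spec``; positives from the same model with
    ``intra_corr`` reduced by ``effect`` (weakened within-module coupling).
    ``effect = 0`` yields two groups from one distribution (the null).
    Per-subject seeds are derived deterministically from ``seed``.
    """
    if effect < 0:
        raise ValueError(f"effect must be >= 0, got {effect}")
    if base_spec.intra_corr - effect < base_spec.inter_corr:
        raise ValueError(
            f"effect={effect} would push positive-group intra_corr "
            f"({base_spec.intra_corr - effect:.3f}) below inter_corr ({base_spec.inter_corr})"
        )
    pos_spec = replace(base_spec, intra_corr=base_spec.intra_corr - effect)
    cov_ctl = build_covariance(base_spec)
    cov_pos = build_covariance(pos_spec)

    child_seeds = np.random.SeedSequence(seed).generate_state(n_pos + n_ctrl) & _SEED_MASK
    subjects = []
    for i in range(n_pos):
        subjects.append(sample_subject(cov_pos, n_timepoints, POSITIVE,
                                       int(child_seeds[i]), f"pos_{i:03d}", ar_coef))
    for i in range(n_ctrl):
        subjects.append(sample_subject(cov_ctl, n_timepoints, CONTROL,
                                       int(child_seeds[n_pos + i]), f"ctl_{i:03d}", ar_coef))
    return CohortManifest(subjects=subjects, n_positive=n_pos, n_control=n_ctrl, seed=seed)
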