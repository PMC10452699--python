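"""Dynamic brain functional network construction.

A subject's M x P ROI time-series matrix is cut into D = floor((M-L)/s) + 1
overlapping windows of length L advancing by step s.  Within each window the
P x P Pearson correlation matrix is computed (nodes = regions, edge weights =
pairwise correlations); the Fisher R-Z transform z = atanh(r) is applied by
default to stabilize the variance of the correlation estimates.  Diagonals
are fixed at zero: self-connections carry no information and would map to
infinity under the Fisher transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import TimeSeriesSubject


@dataclass(frozen=True)
class WindowScheme:
    """Sliding-window layout: length L, step s, window count D over M timepoints.

    Window d (1-based) covers timepoints [(d-1)*s + 1, (d-1)*s + L]
    inclusive, so the last window always fits inside [1, M].
    """

    window_length: int
    step: int
    n_windows: int
    n_timepoints: int

    def slices(self):
        """0-based half-open slices for each window."""
        return [slice(d * self.step, d * self.step + self.window_length)
                for d in range(self.n_windows)]


def make_window_scheme(n_timepoints: int, window_length: int, step: int) -> WindowScheme:
    """Build a :class:`WindowScheme`; D = floor((M - L)/s) + 1."""
    m, length, s = n_timepoints, window_length, step
    if length < 2:
        raise ValueError(f"window_length must be >= 2, got {length}")
    if length > m:
        raise ValueError(f"window_length ({length}) exceeds the series length ({m})")
    if s < 1:
        raise ValueError(f"step must be >= 1, got {s}")
    d = (m - length) // s + 1
    return WindowScheme(window_length=length, step=s, n_windows=d, n_timepoints=m)


def window_correlation(x_window: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of the columns of an L x P window.

    Computed as the cross-product of the column-standardized matrix (the
    closed-form minimizer of || Z - X^T X ||_F over symmetric Z given
    standardized X).  The diagonal is set to 0 and the result is exactly
    symmetric.  A zero-variance column is rejected with its region index.
    """
    x = np.asarray(x_window, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("window must be a 2-D matrix with at least 2 rows")
    centered = x - x.mean(axis=0)
    norms = np.sqrt((centered ** 2).sum(axis=0))
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise ValueError(f"region {bad[0]} has zero variance within the window")
    std = centered / norms
    corr = std.T @ std
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 0.0)
    return corr


def fisher_z(r):
    """Fisher R-Z transform z = 0.5 * ln((1+r)/(1-r)) = atanh(r).

    Odd and strictly increasing; |r| >= 1 is rejected (infinite image).
    Accepts scalars or arrays.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) >= 1.0):
        raise ValueError("Fisher R-Z transform requires |r| < 1")
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) or arr.ndim == 0 else out


@dataclass
class DynamicNetwork:
    """Per-window weighted correlation matrices for one subject.

    ``windows`` is a D x P x P array; each slice is symmetric with a zero
    diagonal.  When ``fisher_applied`` is False off-diagonal weights lie in
    [-1, 1]; when True they are the Fisher-transformed correlations.
    """

    subject_id: str
    windows: np.ndarray
    fisher_applied: bool

    def __post_init__(self):
        self.windows = np.asarray(self.windows, dtype=float)
        if self.windows.ndim != 3 or self.windows.shape[1] != self.windows.shape[2]:
            raise ValueError("windows must be a D x P x P array")
        if not np.all(np.isfinite(self.windows)):
            raise ValueError("network weights must be finite")

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def n_regions(self) -> int:
        return self.windows.shape[1]

    def mean_weighted(self) -> np.ndarray:
        """Across-window mean weighted matrix."""
        return self.windows.mean(axis=0)


def build_dbfn(subject: TimeSeriesSubject, scheme: WindowScheme,
               apply_fisher: bool = True) -> DynamicNetwork:
    """Build the dynamic network: one weighted matrix per sliding window."""
    if scheme.n_timepoints != subject.n_timepoints:
        raise ValueError(
            f"window scheme was built for {scheme.n_timepoints} timepoints but the "
            f"subject has {subject.n_timepoints}"
        )
    mats = []
    for d, sl in enumerate(scheme.slices()):
        try:
            corr = window_correlation(subject.data[sl])
            if apply_fisher:
                corr = fisher_z(corr)  # diagonal is 0, maps to 0
        except ValueError as err:
            raise ValueError(f"window {d + 1}: {err}") from err
        mats.append(corr)
    return DynamicNetwork(subject_id=subject.subject_id,
                          windows=np.stack(mats), fisher_applied=apply_fisher)
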