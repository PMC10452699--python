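"""Threshold filtration and binary-graph topological properties.

Each weighted network window is converted to a family of binary undirected
graphs over an increasing threshold grid (edge present iff |weight| exceeds
the threshold), and four standard measures of network integration and
segregation are computed on each binary graph:

- ``cc``      mean clustering coefficient (segregation),
- ``Eglobal`` global efficiency (integration),
- ``Elocal``  local efficiency (fault tolerance / segregation),
- ``Lp``      characteristic path length (integration).

Conventions follow the Brain Connectivity Toolbox: nodes with degree < 2
contribute 0 to cc and Elocal; Lp averages shortest paths over mutually
reachable pairs only and returns 0 for a fully disconnected graph;
unreachable pairs contribute 0 to Eglobal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .networks import DynamicNetwork

METRICS = ("cc", "Eglobal", "Elocal", "Lp")

WINDOW_MEAN = "window-mean"
PER_WINDOW = "per-window"


@dataclass(frozen=True)
class ThresholdGrid:
    """Evenly spaced positive thresholds low, low+step, ..., <= high."""

    low: float = 0.01
    high: float = 0.35
    step: float = 0.01
    values: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if self.low <= 0 or self.step <= 0 or self.high < self.low:
            raise ValueError(
                f"need 0 < low <= high and step > 0, got low={self.low}, "
                f"high={self.high}, step={self.step}"
            )
        n = int(np.floor((self.high - self.low) / self.step + 1e-9)) + 1
        object.__setattr__(self, "values", self.low + self.step * np.arange(n))

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class BinaryGraph:
    """Undirected binary graph as a symmetric hollow 0/1 adjacency matrix."""

    adjacency: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        self.adjacency = a.astype(np.uint8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


def binarize(weighted: np.ndarray, pr: float, use_absolute: bool = True) -> BinaryGraph:
    """Threshold a weighted matrix: edge iff |w| > pr (or w > pr in signed mode).

    Fisher-transformed correlations are signed and the absolute-value rule is
    the dominant convention for binary brain networks; signed mode is kept as
    an option.
    """
    w = np.asarray(weighted, dtype=float)
    if pr <= 0:
        raise ValueError(f"threshold must be > 0, got {pr}")
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weighted matrix must be square")
    if not np.allclose(w, w.T, atol=1e-10):
        raise ValueError("weighted matrix must be symmetric")
    vals = np.abs(w) if use_absolute else w
    adj = (vals > pr).astype(np.uint8)
    np.fill_diagonal(adj, 0)
    return BinaryGraph(adjacency=adj)


def _adj(graph) -> np.ndarray:
    a = graph.adjacency if isinstance(graph, BinaryGraph) else np.asarray(graph)
    return a.astype(bool)


_EYE_CACHE: dict = {}


def _offdiag(p: int) -> np.ndarray:
    mask = _EYE_CACHE.get(p)
    if mask is None:
        mask = _EYE_CACHE[p] = ~np.eye(p, dtype=bool)
    return mask


def _pairwise_distances(b: np.ndarray) -> np.ndarray:
    """All-pairs unweighted shortest-path lengths by breadth-first expansion.

    Takes a boolean adjacency; returns inf for unreachable pairs, 0 on the
    diagonal.
    """
    p = b.shape[0]
    dist = np.where(b, 1.0, np.inf)
    np.fill_diagonal(dist, 0.0)
    au = b.astype(np.uint8)
    reach = b | ~_offdiag(p)
    d = 1
    while True:
        nxt = ((reach @ au) > 0) & ~reach
        if not nxt.any():
            return dist
        d += 1
        dist[nxt] = d
        reach |= nxt


def _clustering_from_bool(b: np.ndarray) -> float:
    au = b.astype(np.int64)
    deg = au.sum(axis=1)
    triangles = (au @ au * au).sum(axis=1) / 2.0  # = diag(A^3) / 2
    denom = deg * (deg - 1)
    ci = np.where(denom > 0, 2.0 * triangles / np.maximum(denom, 1), 0.0)
    return float(ci.mean())


def _efficiency_from_dist(dist: np.ndarray) -> float:
    p = dist.shape[0]
    off = _offdiag(p)
    vals = dist[off]
    finite = np.isfinite(vals)
    return float((1.0 / vals[finite]).sum() / (p * (p - 1)))


def _path_length_from_dist(dist: np.ndarray) -> float:
    vals = dist[_offdiag(dist.shape[0])]
    finite = vals[np.isfinite(vals)]
    return float(finite.mean()) if finite.size else 0.0


def _local_efficiency_from_bool(b: np.ndarray) -> float:
    p = b.shape[0]
    total = 0.0
    for i in range(p):
        nb = b[i]
        if int(nb.sum()) >= 2:
            sub = b[nb][:, nb]
            total += _efficiency_from_dist(_pairwise_distances(sub))
    return total / p


def clustering_coefficient(graph) -> float:
    """Mean over nodes of C_i = 2 t_i / (k_i (k_i - 1)); C_i = 0 when k_i < 2."""
    b = _adj(graph)
    if b.shape[0] < 1:
        raise ValueError("graph must have at least one node")
    return _clustering_from_bool(b)


def global_efficiency(graph) -> float:
    """Mean inverse shortest-path length over ordered pairs; unreachable pairs count 0."""
    b = _adj(graph)
    if b.shape[0] < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    return _efficiency_from_dist(_pairwise_distances(b))


def characteristic_path_length(graph) -> float:
    """Mean shortest-path length over mutually reachable ordered pairs.

    Returns 0 when no pair is reachable (the efficiency-style reciprocal
    handling of disconnection is already provided by global efficiency).
    """
    b = _adj(graph)
    if b.shape[0] < 2:
        raise ValueError("characteristic path length needs at least 2 nodes")
    return _path_length_from_dist(_pairwise_distances(b))


def local_efficiency(graph) -> float:
    """Mean over nodes of the global efficiency of each node's neighborhood subgraph.

    Nodes with fewer than 2 neighbors contribute 0.
    """
    b = _adj(graph)
    if b.shape[0] < 1:
        raise ValueError("graph must have at least one node")
    return _local_efficiency_from_bool(b)


_METRIC_FN = {
    "cc": clustering_coefficient,
    "Eglobal": global_efficiency,
    "Elocal": local_efficiency,
    "Lp": characteristic_path_length,
}


@dataclass
class MetricCurveSet:
    """Per-metric values over the threshold grid for one subject.

    Under ``window-mean`` aggregation each metric maps to a 1-D curve (the
    across-window average at each threshold); under ``per-window`` each maps
    to a D x n_thresholds matrix.
    """

    subject_id: str
    grid: ThresholdGrid
    curves: dict
    aggregation: str = WINDOW_MEAN

    def __post_init__(self):
        if self.aggregation not in (WINDOW_MEAN, PER_WINDOW):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")
        for name in METRICS:
            if name not in self.curves:
                raise ValueError(f"missing curve for metric {name!r}")
            arr = np.asarray(self.curves[name], dtype=float)
            if arr.shape[-1] != len(self.grid):
                raise ValueError(f"curve length for {name!r} does not match the grid")
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"curve for {name!r} must be finite and non-negative")
            self.curves[name] = arr


def metric_curves(net: DynamicNetwork, grid: ThresholdGrid,
                  aggregation: str = WINDOW_MEAN,
                  use_absolute: bool = True) -> MetricCurveSet:
    """Binarize every window at every threshold and evaluate the four metrics.

    Default aggregation averages across windows, giving one curve per metric
    per subject.
    """
    if net.n_windows < 1:
        raise ValueError("network must contain at least one window")
    n_thr = len(grid)
    per_window = {m: np.empty((net.n_windows, n_thr)) for m in METRICS}
    for d in range(net.n_windows):
        w = net.windows[d]
        try:
            # validate the weighted matrix once; per-threshold cuts reuse it
            binarize(w, float(grid.values[0]), use_absolute=use_absolute)
        except ValueError as err:
            raise ValueError(f"window {d + 1}, threshold {grid.values[0]:.4f}: {err}") from err
        vals = np.abs(w) if use_absolute else w
        for j, pr in enumerate(grid.values):
            b = vals > pr
            np.fill_diagonal(b, False)
            dist = _pairwise_distances(b)
            per_window["cc"][d, j] = _clustering_from_bool(b)
            per_window["Eglobal"][d, j] = _efficiency_from_dist(dist)
            per_window["Elocal"][d, j] = _local_efficiency_from_bool(b)
            per_window["Lp"][d, j] = _path_length_from_dist(dist)
    if aggregation == PER_WINDOW:
        curves = per_window
    else:
        curves = {m: per_window[m].mean(axis=0) for m in METRICS}
    return MetricCurveSet(subject_id=net.subject_id, grid=grid,
                          curves=curves, aggregation=aggregation)
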