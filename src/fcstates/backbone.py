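"""Adaptive disparity-filter thresholding of windowed connectivity graphs.

Pipeline: (1) pool every edge weight from every windowed graph, (2)
bootstrap the median of the absolute pooled weights (10,000 resamples
by default) to obtain a robust normalizer M, (3) for a candidate
threshold alpha, retain edge (u, v) of a window iff its squared
M-normalized weight is at least an alpha fraction of the node's total
squared normalized strength at either endpoint,

    s_u(v) = (|w_uv| / M)^2 / sum_k (|w_uk| / M)^2  >=  alpha,

and (4) choose alpha by golden-section search (cross-checked against a
coarse grid) minimizing the mean absolute difference in average
retained connectivity between consecutive windows.  Weights keep their
sign; only magnitudes enter the filter.

Windows are plain symmetric weight matrices (zero diagonal); helpers
convert to/from networkx graphs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "WeightedGraphSet",
    "BootstrapResult",
    "AlphaSearch",
    "aggregate_edges",
    "bootstrap_median",
    "disparity_scores",
    "disparity_retention",
    "objective",
    "optimize_alpha",
    "apply_backbone",
    "matrix_to_graph",
    "graph_to_matrix",
]

_INVPHI = (math.sqrt(5.0) - 1.0) / 2.0


@dataclass
class WeightedGraphSet:
    """Ordered windowed graphs on a common node set.

    ``matrices`` is windows x N x N, symmetric with zero diagonal;
    entries are signed edge weights (zero = absent edge).
    """

    matrices: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrices, dtype=float)
        if m.ndim != 3 or m.shape[1] != m.shape[2]:
            raise ValueError("matrices must be windows x N x N")
        if not np.isfinite(m).all():
            raise ValueError("weights must be finite")
        if not np.allclose(m, m.transpose(0, 2, 1)):
            raise ValueError("window matrices must be symmetric")
        if np.abs(np.diagonal(m, axis1=1, axis2=2)).max(initial=0.0) > 0:
            raise ValueError("self-loops are not allowed")
        self.matrices = m

    @property
    def n_windows(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.matrices.shape[1]


@dataclass
class BootstrapResult:
    M: float
    n_iter: int
    seed: int


@dataclass
class AlphaSearch:
    alpha_start: float = 0.001
    alpha_end: float = 0.10
    tolerance: float = 1e-4
    grid_step: float = 0.001

    def __post_init__(self) -> None:
        if not 0 < self.alpha_start < self.alpha_end <= 1:
            raise ValueError("need 0 < alpha_start < alpha_end <= 1")


def matrix_to_graph(matrix: np.ndarray) -> nx.Graph:
    """Symmetric weight matrix -> undirected weighted networkx graph."""
    g = nx.Graph()
    n = matrix.shape[0]
    g.add_nodes_from(range(n))
    iu, ju = np.triu_indices(n, k=1)
    for i, j in zip(iu, ju):
        w = matrix[i, j]
        if w != 0:
            g.add_edge(int(i), int(j), weight=float(w))
    return g


def graph_to_matrix(g: nx.Graph, n_nodes: int | None = None) -> np.ndarray:
    """Undirected weighted graph -> symmetric weight matrix."""
    n = n_nodes if n_nodes is not None else g.number_of_nodes()
    m = np.zeros((n, n))
    for u, v, d in g.edges(data=True):
        m[u, v] = m[v, u] = d.get("weight", 1.0)
    return m


def aggregate_edges(graphs: WeightedGraphSet) -> np.ndarray:
    """Pool every (upper-triangle, nonzero) edge weight of every window."""
    iu, ju = np.triu_indices(graphs.n_nodes, k=1)
    pool = graphs.matrices[:, iu, ju].ravel()
    return pool[pool != 0]


def bootstrap_median(
    pool: np.ndarray, n_iter: int = 10_000, seed: int = 0
) -> BootstrapResult:
    """Median of bootstrap medians of the absolute pooled weights.

    Each of ``n_iter`` resamples draws n = len(pool) absolute weights
    with replacement and takes its median; M is the median of those
    medians.  Raises if the pool is empty or all zero (M must be a
    positive normalizer).
    """
    pool = np.abs(np.asarray(pool, dtype=float))
    n = pool.size
    if n == 0:
        raise ValueError("edge pool is empty")
    if pool.max() == 0:
        raise ValueError("all pooled weights are zero; M would not be positive")
    rng = np.random.default_rng(seed)
    medians = np.empty(n_iter)
    # chunk to bound memory at ~32 MB regardless of pool size
    chunk = max(1, int(4_000_000 // max(n, 1)))
    done = 0
    while done < n_iter:
        b = min(chunk, n_iter - done)
        idx = rng.integers(0, n, size=(b, n))
        medians[done : done + b] = np.median(pool[idx], axis=1)
        done += b
    m = float(np.median(medians))
    if m <= 0:
        raise ValueError("bootstrap median of |weights| is zero")
    return BootstrapResult(M=m, n_iter=n_iter, seed=seed)


def disparity_scores(matrix: np.ndarray, M: float) -> np.ndarray:
    """Per-direction disparity scores s_u(v) for one window.

    Entry (u, v) holds the fraction of node u's total squared
    M-normalized strength carried by edge (u, v); rows of isolated
    nodes are zero.
    """
    if M <= 0:
        raise ValueError("M must be positive")
    w2 = (np.abs(matrix) / M) ** 2
    totals = w2.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(totals > 0, w2 / totals, 0.0)
    return s


def disparity_retention(matrix: np.ndarray, M: float, alpha: float) -> np.ndarray:
    """Filter one window: keep (u, v) iff s_u(v) >= alpha or s_v(u) >= alpha.

    The inclusive either-endpoint rule means a degree-1 node's only
    edge (score exactly 1) is always retained.  Retained edges keep
    their signed weight.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    s = disparity_scores(matrix, M)
    keep = (s >= alpha) | (s.T >= alpha)
    keep &= matrix != 0
    return np.where(keep, matrix, 0.0)


def _mean_retained(matrix: np.ndarray, M: float, alpha: float) -> float:
    """Mean signed weight of retained edges (0 if none survive)."""
    filt = disparity_retention(matrix, M, alpha)
    iu, ju = np.triu_indices(matrix.shape[0], k=1)
    vals = filt[iu, ju]
    kept = vals[vals != 0]
    return float(kept.mean()) if kept.size else 0.0


def objective(graphs: WeightedGraphSet, M: float, alpha: float) -> float:
    """Mean |difference| of average retained connectivity between
    consecutive windows at the given alpha."""
    means = np.array([_mean_retained(m, M, alpha) for m in graphs.matrices])
    return float(np.abs(np.diff(means)).mean())


def optimize_alpha(
    graphs: WeightedGraphSet, M: float, search: AlphaSearch | None = None
) -> tuple[float, dict]:
    """Golden-section minimization of the stability objective.

    The golden-section result is cross-checked against a coarse grid
    (default step 0.001) because the objective is piecewise constant in
    alpha and need not be unimodal; the better of the two optima is
    returned.  A flat objective returns ``alpha_start`` with a warning
    flag in the log.
    """
    if graphs.n_windows < 2:
        raise ValueError("need >= 2 windows to compare consecutive connectivity")
    search = search or AlphaSearch()
    a, b = search.alpha_start, search.alpha_end

    evaluations: dict[float, float] = {}

    def J(alpha: float) -> float:
        if alpha not in evaluations:
            evaluations[alpha] = objective(graphs, M, alpha)
        return evaluations[alpha]

    c = b - _INVPHI * (b - a)
    d = a + _INVPHI * (b - a)
    fc, fd = J(c), J(d)
    while (b - a) > search.tolerance:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - _INVPHI * (b - a)
            fc = J(c)
        else:
            a, c, fc = c, d, fd
            d = a + _INVPHI * (b - a)
            fd = J(d)
    alpha_gs = (a + b) / 2.0
    j_gs = J(alpha_gs)

    grid = np.arange(search.alpha_start, search.alpha_end + 1e-12, search.grid_step)
    j_grid = np.array([J(float(g)) for g in grid])
    i_best = int(np.argmin(j_grid))
    # J is piecewise constant in alpha, so a narrow optimum can sit
    # between coarse points; refine at grid_step/10 around the best
    # coarse point (and around the golden-section result)
    for center in (float(grid[i_best]), alpha_gs):
        lo = max(search.alpha_start, center - search.grid_step)
        hi = min(search.alpha_end, center + search.grid_step)
        for g in np.arange(lo, hi + 1e-12, search.grid_step / 10.0):
            J(float(g))
    best_alpha = min(evaluations, key=evaluations.get)
    alpha_grid, j_best_grid = float(best_alpha), float(evaluations[best_alpha])

    flat = np.ptp(j_grid) == 0 and j_gs == j_grid[0]
    if flat:
        log = {"flat_objective": True, "alpha": search.alpha_start}
        return search.alpha_start, log
    if j_best_grid < j_gs:
        alpha_opt, j_opt, source = alpha_grid, j_best_grid, "grid"
    else:
        alpha_opt, j_opt, source = alpha_gs, j_gs, "golden-section"
    log = {
        "flat_objective": False,
        "alpha": alpha_opt,
        "objective": j_opt,
        "source": source,
        "n_evaluations": len(evaluations),
    }
    return alpha_opt, log


def apply_backbone(
    graphs: WeightedGraphSet, M: float, alpha: float
) -> tuple[WeightedGraphSet, dict]:
    """Filter every window with one shared alpha.

    Returns the filtered graph set and a log with per-window retained
    edge counts.
    """
    filtered = np.stack(
        [disparity_retention(m, M, alpha) for m in graphs.matrices]
    )
    iu, ju = np.triu_indices(graphs.n_nodes, k=1)
    counts = [int(np.count_nonzero(f[iu, ju])) for f in filtered]
    log = {"alpha": alpha, "M": M, "retained_edges": counts}
    return WeightedGraphSet(filtered), log
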