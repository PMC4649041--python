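"""Proximity/distance graphs, metric closure and semi-metric edge classification.

A functional connectome is a weighted graph whose edge weights ("proximities",
here non-negative correlations) live in [0, 1].  The isomorphism

    d_ij = 1 / w_ij - 1

maps proximities to distances: a full-strength connection (w = 1) has zero
distance, vanishing connections recede to infinity.  Replacing every pairwise
distance with its all-pairs shortest-path value — the *metric closure* — then
splits direct edges into two classes:

* **metric**: the direct edge already is the shortest path;
* **semi-metric**: some indirect path is strictly shorter, i.e. the triangle
  inequality is violated at that edge.

The semi-metric percentage (SMP) of an edge subset is the fraction of its
present edges that are semi-metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.sparse.csgraph import csgraph_from_dense, johnson

__all__ = [
    "ABSENT",
    "METRIC",
    "SEMI_METRIC",
    "LABEL_NAMES",
    "DEFAULT_REL_TOL",
    "GraphValidationError",
    "UndefinedSMPError",
    "ProximityGraph",
    "DistanceGraph",
    "ClosureResult",
    "proximity_to_distance",
    "distance_to_proximity",
    "metric_closure",
    "brute_force_closure",
    "smp",
]

# edge-label codes used throughout the package
ABSENT = 0
METRIC = 1
SEMI_METRIC = 2
LABEL_NAMES = {ABSENT: "absent", METRIC: "metric", SEMI_METRIC: "semi-metric"}

#: relative tolerance below which a closed distance counts as a genuine
#: shortcut: an edge is semi-metric iff D_ij < d_ij * (1 - DEFAULT_REL_TOL)
DEFAULT_REL_TOL = 1e-9


class GraphValidationError(ValueError):
    """Raised when a graph violates its structural invariants."""


class UndefinedSMPError(ValueError):
    """Raised when an SMP is requested over a subset with no present edges."""


def _default_node_ids(n: int) -> tuple[str, ...]:
    return tuple(f"n{i}" for i in range(n))


def _check_square_symmetric(mat: np.ndarray, what: str) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise GraphValidationError(f"{what} matrix must be square, got shape {mat.shape}")
    finite = np.isfinite(mat)
    both = finite & finite.T
    with np.errstate(invalid="ignore"):
        asym = np.abs(np.where(both, mat - mat.T, 0.0))
    if (finite != finite.T).any() or (asym > 1e-8 * np.maximum(1.0, np.abs(mat))).any():
        i, j = np.unravel_index(np.argmax(np.where(both, asym, np.inf)), mat.shape)
        raise GraphValidationError(
            f"{what} matrix not symmetric (max asymmetry {asym.max():.3g} at ({i},{j}))"
        )
    return 0.5 * (mat + mat.T) if finite.all() else mat


@dataclass(frozen=True)
class ProximityGraph:
    """Symmetric weighted graph with proximities in [0, 1]; 0 means absent.

    The diagonal is ignored (self-proximity never enters any computation) and
    stored as 0.
    """

    weights: np.ndarray
    node_ids: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        w = _check_square_symmetric(self.weights, "proximity").copy()
        if not np.isfinite(w).all():
            raise GraphValidationError("proximity matrix must be finite")
        off = ~np.eye(w.shape[0], dtype=bool)
        bad = off & ((w < 0) | (w > 1))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise GraphValidationError(
                f"proximity w[{i},{j}] = {w[i, j]:.6g} outside [0, 1]"
            )
        np.fill_diagonal(w, 0.0)
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)
        ids = self.node_ids
        ids = _default_node_ids(w.shape[0]) if ids is None else tuple(ids)
        if len(ids) != w.shape[0]:
            raise GraphValidationError("node_ids length does not match matrix size")
        if len(set(ids)) != len(ids):
            raise GraphValidationError("node_ids must be unique")
        object.__setattr__(self, "node_ids", ids)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class DistanceGraph:
    """Symmetric distance graph; ``np.inf`` is the explicit absent-edge sentinel.

    Distances are never approximated by a large finite value, so shortest
    paths can never sneak through absent edges.
    """

    distances: np.ndarray
    node_ids: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        d = _check_square_symmetric(self.distances, "distance").copy()
        off = ~np.eye(d.shape[0], dtype=bool)
        if (d[off] < 0).any() or np.isnan(d).any():
            raise GraphValidationError("distances must be >= 0 (inf allowed), no NaN")
        np.fill_diagonal(d, 0.0)
        d.setflags(write=False)
        object.__setattr__(self, "distances", d)
        ids = self.node_ids
        ids = _default_node_ids(d.shape[0]) if ids is None else tuple(ids)
        if len(ids) != d.shape[0] or len(set(ids)) != len(ids):
            raise GraphValidationError("node_ids must be unique and match matrix size")
        object.__setattr__(self, "node_ids", ids)

    @property
    def n_nodes(self) -> int:
        return self.distances.shape[0]


@dataclass(frozen=True)
class ClosureResult:
    """Metric closure of a distance graph plus per-edge classification.

    Attributes
    ----------
    direct_distances
        The input distances d_ij (inf where the edge is absent).
    closed_distances
        All-pairs shortest-path distances D_ij; D_ij <= d_ij everywhere the
        direct edge exists, and inf only for pairs in different components.
    labels
        Integer matrix with codes :data:`ABSENT`, :data:`METRIC`,
        :data:`SEMI_METRIC`; the diagonal is coded absent.
    distortion
        s_ij = d_ij / D_ij for present direct edges (1 for metric edges,
        > 1 for semi-metric ones, inf if a zero-cost indirect path exists);
        NaN for absent pairs.
    """

    direct_distances: np.ndarray
    closed_distances: np.ndarray
    labels: np.ndarray
    distortion: np.ndarray
    node_ids: tuple[str, ...]

    @property
    def n_nodes(self) -> int:
        return self.closed_distances.shape[0]

    def label_name(self, i: int, j: int) -> str:
        return LABEL_NAMES[int(self.labels[i, j])]

    def semi_metric_pairs(self) -> list[tuple[int, int]]:
        """Unordered node pairs (i < j) labelled semi-metric."""
        i, j = np.where(np.triu(self.labels == SEMI_METRIC, k=1))
        return list(zip(i.tolist(), j.tolist()))


def proximity_to_distance(p: ProximityGraph) -> DistanceGraph:
    """Map proximities to distances via d = 1/w - 1; w = 0 becomes infinite.

    Strong connections become short distances (w = 1 -> d = 0); absent edges
    are represented by the explicit ``inf`` sentinel.
    """
    w = p.weights
    with np.errstate(divide="ignore"):
        d = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0) - 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    return DistanceGraph(distances=d, node_ids=p.node_ids)


def distance_to_proximity(d: DistanceGraph) -> ProximityGraph:
    """Inverse isomorphism w = 1/(d + 1); infinite distance maps to 0."""
    dist = d.distances
    w = np.where(np.isinf(dist), 0.0, 1.0 / (dist + 1.0))
    np.fill_diagonal(w, 0.0)
    return ProximityGraph(weights=w, node_ids=d.node_ids)


def _classify(
    direct: np.ndarray, closed: np.ndarray, rel_tol: float, node_ids: tuple[str, ...]
) -> ClosureResult:
    """Label each pair and compute distortions from direct vs closed distances."""
    n = direct.shape[0]
    off = ~np.eye(n, dtype=bool)
    present = off & np.isfinite(direct)
    semi = present & (closed < direct * (1.0 - rel_tol))
    labels = np.full((n, n), ABSENT, dtype=np.int8)
    labels[present] = METRIC
    labels[semi] = SEMI_METRIC
    # a metric edge's closed distance IS its direct distance; snapping removes
    # sub-tolerance floating-point undershoot from path summation and makes
    # the closure an exact fixed point
    metric_edges = present & ~semi
    closed = np.where(metric_edges, direct, closed)

    distortion = np.full((n, n), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = direct / closed
    # zero-distance direct edge whose closure is also zero is metric: ratio 1
    zero_zero = present & (direct == 0) & (closed == 0)
    ratio = np.where(zero_zero, 1.0, ratio)
    distortion[present] = ratio[present]
    distortion[labels == METRIC] = 1.0

    return ClosureResult(
        direct_distances=direct.copy(),
        closed_distances=closed,
        labels=labels,
        distortion=distortion,
        node_ids=node_ids,
    )


def metric_closure(d: DistanceGraph, rel_tol: float = DEFAULT_REL_TOL) -> ClosureResult:
    """All-pairs shortest paths (Johnson's algorithm) and edge classification.

    An edge is semi-metric iff its closed distance undercuts the direct one by
    more than the relative tolerance ``rel_tol``; pairs in different connected
    components get infinite closed distance and the ``absent`` label.
    """
    mat = d.distances.copy()
    np.fill_diagonal(mat, np.inf)  # keep self-loops out of the edge set
    graph = csgraph_from_dense(mat, null_value=np.inf)
    closed = johnson(graph, directed=False)
    np.fill_diagonal(closed, 0.0)
    # per-source Dijkstra runs can disagree by one ulp across the diagonal;
    # the graph is undirected, so take the elementwise minimum
    closed = np.minimum(closed, closed.T)
    # shortest paths can only undercut the direct edge; enforce exactly so the
    # closure is a true fixed point even under floating-point path summation
    finite = np.isfinite(d.distances)
    closed[finite] = np.minimum(closed[finite], d.distances[finite])
    return _classify(d.distances, closed, rel_tol, d.node_ids)


def brute_force_closure(
    d: DistanceGraph, rel_tol: float = DEFAULT_REL_TOL
) -> ClosureResult:
    """Cubic dynamic-programming closure (Floyd–Warshall recurrence).

    Test oracle with the same contract as :func:`metric_closure`; intended for
    graphs up to a few hundred nodes.
    """
    n = d.n_nodes
    if n > 512:
        raise GraphValidationError("brute_force_closure is limited to n <= 512")
    closed = d.distances.copy()
    np.fill_diagonal(closed, 0.0)
    for k in range(n):
        via_k = closed[:, k, None] + closed[None, k, :]
        closed = np.minimum(closed, via_k)
    finite = np.isfinite(d.distances)
    closed[finite] = np.minimum(closed[finite], d.distances[finite])
    return _classify(d.distances, closed, rel_tol, d.node_ids)


PairSubset = Iterable[tuple[int, int]]


def _normalize_pairs(subset: PairSubset, n: int) -> tuple[np.ndarray, np.ndarray]:
    pairs = {(min(i, j), max(i, j)) for i, j in subset}
    for i, j in pairs:
        if i == j:
            raise GraphValidationError(f"self-pair ({i},{j}) not allowed in SMP subset")
        if not (0 <= i < n and 0 <= j < n):
            raise GraphValidationError(f"pair ({i},{j}) out of range for {n} nodes")
    if not pairs:
        raise UndefinedSMPError("empty subset: SMP undefined")
    idx = np.array(sorted(pairs))
    return idx[:, 0], idx[:, 1]


def smp(closure: ClosureResult, subset: PairSubset | str = "all") -> float:
    """Semi-metric percentage over an edge subset.

    The SMP is the ratio of semi-metric edges to present (finite-distance)
    edges within ``subset`` ("all" = every unordered node pair).  Absent pairs
    are excluded from numerator and denominator; a subset with no present edge
    raises :class:`UndefinedSMPError` (undefined, not 0).
    """
    if isinstance(subset, str):
        if subset != "all":
            raise GraphValidationError(f"unknown subset spec {subset!r}")
        tri = np.triu_indices(closure.n_nodes, k=1)
        lab = closure.labels[tri]
        n_semi = int((lab == SEMI_METRIC).sum())
        n_present = int((lab != ABSENT).sum())
    else:
        ii, jj = _normalize_pairs(subset, closure.n_nodes)
        lab = closure.labels[ii, jj]
        n_semi = int((lab == SEMI_METRIC).sum())
        n_present = int((lab != ABSENT).sum())
    if n_present == 0:
        raise UndefinedSMPError("subset has no present edges: SMP undefined")
    return n_semi / n_present
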