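"""Greedy multi-objective tree construction and the Pareto-front analysis.

The joint objective over a tree G spanning the base v0 and terminals
v1..vn is

    alpha * Travel(G) + (1 - alpha) * Length(G),       alpha in [0, 1],

whose two endpoints are the Satellite tree (alpha = 1, minimum travel) and
the Euclidean Steiner tree (alpha = 0, minimum length; NP-hard, approximated
greedily).  The greedy construction starts from the base alone and, at each
of n steps, adds the edge from an unconnected terminal u to an in-tree point
w (existing subdivision points included) that minimizes the exact increment
of the joint objective,

    alpha * (dist_to_root[w] + |u - w|) + (1 - alpha) * |u - w|,

then subdivides the new edge with k equidistant interior points that later
steps may attach to.  Sweeping alpha over a grid yields the per-plant Pareto
front; the scaled distance epsilon, the closest-alpha feature, and the
Pareto trade-off ratio are computed against that front.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .reference import ConstructedTree, bipartite_reference, satellite_travel
from .skeleton import (
    FLOWER_LABELS,
    LEAF_LABELS,
    FeatureRecord,
    NoTerminalsError,
    ObjectivePair,
    PlantSkeleton,
    TerminalSet,
    extract_terminals,
    morphological_features,
    prune_skeleton,
    total_length,
    travel_distance,
)

__all__ = [
    "DEFAULT_ALPHA_GRID",
    "GreedyConfig",
    "ParetoFront",
    "TradeoffSummary",
    "AnalysisResult",
    "GreedyGrower",
    "greedy_tree",
    "quick_tradeoff",
    "build_front",
    "epsilon_distance",
    "closest_alpha",
    "tradeoff_ratio",
    "sugar_transport_comparison",
    "analyze_plant",
]

#: 101 weights, 0.00 to 1.00 in steps of 0.01
DEFAULT_ALPHA_GRID: np.ndarray = np.round(np.linspace(0.0, 1.0, 101), 2)


@dataclass(frozen=True)
class GreedyConfig:
    """Greedy construction parameters.

    alpha  — weight on travel distance (1 = pure travel, 0 = pure length).
    k      — equidistant subdivision points added along each new edge;
             they act as candidate branch points for later attachments.
    """

    alpha: float = 0.0
    k: int = 10

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.k < 0 or int(self.k) != self.k:
            raise ValueError(f"k must be a non-negative integer, got {self.k}")


@dataclass
class ParetoFront:
    """Objectives of the greedy trees over an alpha grid, for one plant."""

    entries: list[tuple[float, float, float]]  # (alpha, length, travel)
    grid: np.ndarray
    terminal_set: TerminalSet | None = None

    def __post_init__(self) -> None:
        if len(self.entries) != len(self.grid):
            raise ValueError("one entry per grid value required")

    def lengths(self) -> np.ndarray:
        return np.asarray([e[1] for e in self.entries])

    def travels(self) -> np.ndarray:
        return np.asarray([e[2] for e in self.entries])

    def alphas(self) -> np.ndarray:
        return np.asarray([e[0] for e in self.entries])

    def nondominated(self) -> np.ndarray:
        """(m, 2) array of non-dominated (length, travel) points.

        Sorted by increasing length with strictly decreasing travel: the
        staircase used for the epsilon geometry.
        """
        pts = np.column_stack([self.lengths(), self.travels()])
        order = np.lexsort((pts[:, 1], pts[:, 0]))
        keep: list[np.ndarray] = []
        best_travel: float | None = None
        for i in order:
            if best_travel is None or pts[i, 1] < best_travel:
                keep.append(pts[i])
                best_travel = float(pts[i, 1])
        return np.asarray(keep)

    def steiner_length(self) -> float:
        """Length of the alpha = 0 entry (the greedy Steiner proxy)."""
        i = int(np.argmin(self.alphas()))
        return self.entries[i][1]

    def satellite_travel_entry(self) -> float:
        """Travel of the alpha = 1 entry (the Satellite end of the front)."""
        i = int(np.argmax(self.alphas()))
        return self.entries[i][2]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.entries, columns=["alpha", "total_length", "travel_distance"]
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass(frozen=True)
class TradeoffSummary:
    """Scalar summary of one plant against its own front."""

    epsilon: float
    alpha_closest: float
    tradeoff: float
    plant_objectives: ObjectivePair
    steiner_length: float
    satellite_travel: float


@dataclass
class AnalysisResult:
    """Everything the per-plant pipeline produces."""

    features: FeatureRecord
    summary: TradeoffSummary
    front: ParetoFront
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# greedy construction
# ---------------------------------------------------------------------------

class GreedyGrower:
    """Stateful greedy construction supporting staged terminal arrival.

    In-tree points are kept in creation order (root first) so that
    ``argmin`` tie-breaking prefers the earliest-created attachment point —
    the root on exact ties, which makes alpha = 1 return the Satellite star
    deterministically.  Terminals within one ``add_terminals`` call are
    tried in ascending input order on ties.
    """

    def __init__(self, root, alpha: float, k: int):
        self.alpha = float(alpha)
        self.k = int(k)
        self._coords = np.empty((64, 3))
        self._droot = np.empty(64)
        self._parent = np.empty(64, dtype=int)
        self._coords[0] = np.asarray(root, dtype=float)
        self._droot[0] = 0.0
        self._parent[0] = -1
        self.m = 1  # in-tree node count
        self.terminal_rows: list[int] = []  # row per terminal, arrival order

    def _ensure(self, extra: int) -> None:
        need = self.m + extra
        if need <= len(self._coords):
            return
        cap = max(need, 2 * len(self._coords))
        self._coords = np.resize(self._coords, (cap, 3))
        self._droot = np.resize(self._droot, cap)
        self._parent = np.resize(self._parent, cap)

    def add_terminals(self, pts) -> list[int]:
        """Insert the given terminals one greedy step each; return their rows."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        n_new = len(pts)
        self._ensure(n_new * (self.k + 1))
        remaining = list(range(n_new))
        rows = [-1] * n_new
        for _ in range(n_new):
            m = self.m
            u_pts = pts[remaining]
            # incremental joint objective: alpha*droot[w] + |u - w|
            d = np.linalg.norm(
                u_pts[:, None, :] - self._coords[None, :m, :], axis=2
            )
            cost = d + self.alpha * self._droot[:m]
            flat = int(np.argmin(cost))  # row-major: terminal, then creation
            ui, w = divmod(flat, m)
            u_idx = remaining.pop(ui)
            u = pts[u_idx]
            edge = float(d[ui, w])
            base = self._droot[w]
            # k equidistant subdivision points, then the terminal itself
            prev = w
            for j in range(1, self.k + 1):
                frac = j / (self.k + 1)
                self._coords[m] = self._coords[w] + frac * (u - self._coords[w])
                self._droot[m] = base + frac * edge
                self._parent[m] = prev
                prev = m
                m += 1
            self._coords[m] = u
            self._droot[m] = base + edge
            self._parent[m] = prev
            rows[u_idx] = m
            self.m = m + 1
        self.terminal_rows.extend(rows)
        return rows

    def snapshot(
        self, provenance: str = "greedy", meta: dict | None = None
    ) -> ConstructedTree:
        m = self.m
        return ConstructedTree(
            coords=self._coords[:m].copy(),
            parent=self._parent[:m].copy(),
            dist_to_root=self._droot[:m].copy(),
            terminal_rows=np.asarray(self.terminal_rows, dtype=int),
            provenance=provenance,
            meta=dict(meta or {}, alpha=self.alpha, k=self.k),
        )


def greedy_tree(ts: TerminalSet, cfg: GreedyConfig = GreedyConfig()) -> ConstructedTree:
    """Greedy near-minimizer of the joint objective for the given alpha.

    Ties between equal-cost attachments are broken toward the
    smallest-index unconnected terminal and then the earliest-created
    in-tree point (the root first), so alpha = 1 yields the Satellite tree
    even with collinear subdivision points.
    """
    grower = GreedyGrower(ts.root, cfg.alpha, cfg.k)
    grower.add_terminals(ts.coords())
    return grower.snapshot(
        provenance="steiner_greedy" if cfg.alpha == 0.0 else "greedy"
    )


def build_front(
    ts: TerminalSet,
    grid: np.ndarray | None = None,
    k: int = 10,
) -> ParetoFront:
    """One greedy tree per alpha on the grid (default 0.00..1.00, 101 values)."""
    grid = DEFAULT_ALPHA_GRID if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0 or grid.min() < 0 or grid.max() > 1:
        raise ValueError("alpha grid must be non-empty and within [0, 1]")
    entries = []
    for alpha in grid:
        t = greedy_tree(ts, GreedyConfig(alpha=float(alpha), k=k))
        entries.append((float(alpha), t.total_length(), t.travel_distance()))
    return ParetoFront(entries=entries, grid=grid, terminal_set=ts)


# ---------------------------------------------------------------------------
# distance to the front, closest alpha, trade-off
# ---------------------------------------------------------------------------

def epsilon_distance(front: ParetoFront, plant: ObjectivePair) -> float:
    """Scale factor at which the front, inflated about the origin, meets the plant.

    The non-dominated front points are joined piecewise-linearly and extended
    by a vertical ray above the minimum-length end and a horizontal ray
    beyond the minimum-travel end, so the ray from the origin through the
    plant point always intersects the curve.  epsilon = 1 means on-front;
    values below 1 (the plant beats the greedy approximation) are returned
    unclamped.
    """
    px, py = plant.total_length, plant.travel_distance
    if px <= 0 or py <= 0:
        raise ValueError("plant objectives must be positive")
    pts = front.nondominated()
    # t parametrizes the ray q = t * (px, py); epsilon = 1 / t
    best_t = None

    def consider(t: float) -> None:
        nonlocal best_t
        if t > 0 and (best_t is None or t < best_t):
            best_t = t

    # vertical extension above the min-length end: x = x_first, y >= y_first
    x0, y0 = pts[0]
    if px > 0:
        t = x0 / px
        if t * py >= y0 - 1e-12 * max(1.0, y0):
            consider(t)
    # horizontal extension beyond the min-travel end: y = y_last, x >= x_last
    xl, yl = pts[-1]
    if py > 0:
        t = yl / py
        if t * px >= xl - 1e-12 * max(1.0, xl):
            consider(t)
    for (x1, y1), (x2, y2) in zip(pts[:-1], pts[1:]):
        # solve p1 + s*(p2 - p1) = t*(px, py), s in [0, 1]
        det = (x2 - x1) * py - (y2 - y1) * px
        if det == 0.0:
            continue
        s = (y1 * px - x1 * py) / det
        if -1e-12 <= s <= 1 + 1e-12:
            s = min(max(s, 0.0), 1.0)
            x = x1 + s * (x2 - x1)
            consider(x / px if px else (y1 + s * (y2 - y1)) / py)
    if best_t is None:  # unreachable with the axis extensions in place
        raise RuntimeError("front/ray intersection not found")
    return 1.0 / best_t


def closest_alpha(
    front: ParetoFront, plant: ObjectivePair, normalize: bool = True
) -> float:
    """Alpha of the front entry nearest the plant's objective pair.

    With ``normalize`` (default) the length axis is divided by the alpha = 0
    entry's length and the travel axis by the alpha = 1 entry's travel, so
    both axes are measured relative to their individual optima.  Ties go to
    the smaller alpha.
    """
    lengths = front.lengths()
    travels = front.travels()
    alphas = front.alphas()
    if normalize:
        lx = front.steiner_length()
        ty = front.satellite_travel_entry()
    else:
        lx = ty = 1.0
    d2 = (lengths / lx - plant.total_length / lx) ** 2 + (
        travels / ty - plant.travel_distance / ty
    ) ** 2
    order = np.lexsort((alphas, d2))  # min distance, then min alpha
    return float(alphas[order[0]])


def tradeoff_ratio(
    plant: ObjectivePair, steiner_length: float, satellite_travel: float
) -> float:
    """Pareto trade-off feature:
    (length / Steiner length) / (travel / Satellite travel).

    High values mean the plant prioritizes transport performance (it spends
    excess length); low values mean it prioritizes construction cost.
    """
    if steiner_length <= 0 or satellite_travel <= 0:
        raise ValueError("reference objectives must be positive")
    return (plant.total_length / steiner_length) / (
        plant.travel_distance / satellite_travel
    )


def sugar_transport_comparison(
    plant: PlantSkeleton, aggregate: str = "sum"
) -> tuple[float, float]:
    """Leaf-to-flower transport vs. the complete-bipartite optimum.

    Returns ``(pct_worse_performance, pct_lower_cost)``: the plant's summed
    leaf-to-flower tree-path distance exceeds the bipartite straight-line
    optimum by the first percentage, while the bipartite graph's construction
    cost exceeds the plant's by the second (as a percentage of plant cost).
    """
    ts = extract_terminals(plant)
    bip_dist, bip_len = bipartite_reference(ts, aggregate=aggregate)
    leaves = [
        nid
        for nid in plant.terminal_ids()
        if plant.nodes[nid].label in LEAF_LABELS
    ]
    flowers = [
        nid
        for nid in plant.terminal_ids()
        if plant.nodes[nid].label in FLOWER_LABELS
    ]
    if not leaves or not flowers:
        raise NoTerminalsError("need at least one leaf and one flower/silique")
    pair_dists = []
    for leaf in leaves:
        # one BFS per leaf gives distances to every flower
        dist = _single_source_lengths(plant, leaf)
        pair_dists.extend(dist[f] for f in flowers)
    plant_pairsum = (
        float(np.sum(pair_dists))
        if aggregate == "sum"
        else float(np.mean(pair_dists))
    )
    plant_len = total_length(plant)
    pct_worse = 100.0 * (plant_pairsum - bip_dist) / bip_dist
    pct_lower_cost = 100.0 * (bip_len - plant_len) / plant_len
    return pct_worse, pct_lower_cost


def _single_source_lengths(skeleton: PlantSkeleton, source: str) -> dict[str, float]:
    from collections import deque

    dist = {source: 0.0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v, w in skeleton._adj[u]:
            if v not in dist:
                dist[v] = dist[u] + w
                queue.append(v)
    return dist


def quick_tradeoff(
    skeleton: PlantSkeleton, k: int = 10, exclude_labels: Iterable[str] = ()
) -> float:
    """Pareto trade-off ratio without building the full alpha sweep.

    Only the two reference optima enter the ratio — the greedy Steiner proxy
    (one alpha = 0 construction) and the closed-form Satellite travel — so
    this is the cheap path for large ensemble statistics on the trade-off
    feature alone.
    """
    if exclude_labels:
        skeleton = prune_skeleton(skeleton, exclude_labels)
    ts = extract_terminals(skeleton)
    plant = ObjectivePair(
        total_length=total_length(skeleton),
        travel_distance=travel_distance(skeleton),
    )
    steiner_len = greedy_tree(ts, GreedyConfig(alpha=0.0, k=k)).total_length()
    return tradeoff_ratio(plant, steiner_len, satellite_travel(ts))


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

def analyze_plant(
    skeleton: PlantSkeleton,
    grid: np.ndarray | None = None,
    k: int = 10,
    exclude_labels: Iterable[str] = (),
) -> AnalysisResult:
    """Full per-plant pipeline.

    Extracts the base and terminal points, builds the alpha-swept front over
    them, measures the plant's own objectives on the full skeleton (bend
    curvature included), and derives epsilon, the closest alpha, the Pareto
    trade-off ratio (Steiner length from the alpha = 0 front entry, Satellite
    travel in closed form), and the morphological features.

    ``exclude_labels`` re-runs the pipeline on a pruned skeleton (e.g.
    ``{"rosette_leaf"}`` for the inflorescence-only analysis).
    """
    if exclude_labels:
        skeleton = prune_skeleton(skeleton, exclude_labels)
    ts = extract_terminals(skeleton)
    front = build_front(ts, grid=grid, k=k)
    plant = ObjectivePair(
        total_length=total_length(skeleton),
        travel_distance=travel_distance(skeleton),
    )
    eps = epsilon_distance(front, plant)
    alpha_c = closest_alpha(front, plant)
    sat_travel = satellite_travel(ts)
    steiner_len = front.steiner_length()
    trade = tradeoff_ratio(plant, steiner_len, sat_travel)
    n_rosette, n_branch, hull_vol = morphological_features(skeleton)
    features = FeatureRecord(
        tradeoff=trade,
        epsilon=eps,
        alpha_closest=alpha_c,
        total_length=plant.total_length,
        travel_distance=plant.travel_distance,
        n_rosette=n_rosette,
        n_branch_points=n_branch,
        hull_volume=hull_vol,
    )
    summary = TradeoffSummary(
        epsilon=eps,
        alpha_closest=alpha_c,
        tradeoff=trade,
        plant_objectives=plant,
        steiner_length=steiner_len,
        satellite_travel=sat_travel,
    )
    return AnalysisResult(
        features=features,
        summary=summary,
        front=front,
        meta=dict(skeleton.meta),
    )
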