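"""Closed-form optimal trees and stochastic baseline architectures.

All constructors take the same input a plant defines — its base point plus
its terminal organs — and return a :class:`ConstructedTree` whose objectives
can be compared against the plant's:

* ``satellite_tree`` — straight edge from the base to every terminal; the
  global minimizer of travel distance.
* ``stable_tree`` — one central hub at the terminal centroid ("stem" from the
  base, spokes to each terminal); a structurally stable reference.
* ``pref_attach_tree`` — Barabási–Albert preferential-attachment tree (m = 1)
  over the same points, arrival order a uniform shuffle.
* ``random_spanning_tree`` — a uniform labeled spanning tree on the points,
  sampled with Wilson's loop-erased random walk.
* ``bipartite_reference`` — the leaf-to-flower complete bipartite graph,
  the sugar-transport optimum used as a cost/performance foil.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .skeleton import (
    FLOWER_LABELS,
    LEAF_LABELS,
    NoTerminalsError,
    TerminalSet,
)

__all__ = [
    "ConstructedTree",
    "cayley_count",
    "satellite_tree",
    "stable_tree",
    "pref_attach_tree",
    "random_spanning_tree",
    "bipartite_reference",
    "satellite_travel",
]

# node coincidence tolerance for the stable tree's degenerate centroid, mm
_MERGE_TOL = 1e-9


def cayley_count(n_vertices: int) -> int:
    """Number of labeled spanning trees on n vertices: n^(n-2) (Cayley).

    The size of the phenotype space the uniform Random baseline samples
    from; exact integer arithmetic.
    """
    if n_vertices < 2:
        raise ValueError("need at least two vertices")
    if n_vertices == 2:
        return 1
    return n_vertices ** (n_vertices - 2)


@dataclass
class ConstructedTree:
    """A rooted tree built over a terminal set, possibly with extra points.

    ``coords`` holds every node (row 0 is the root); ``parent[i]`` is the
    parent row of node ``i`` in the tree rooted at the base (``-1`` for the
    root); ``dist_to_root`` the path length from the base; ``terminal_rows``
    the rows holding the original terminals, in input order.
    """

    coords: np.ndarray
    parent: np.ndarray
    dist_to_root: np.ndarray
    terminal_rows: np.ndarray
    provenance: str
    root_row: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.parent = np.asarray(self.parent, dtype=int)
        self.dist_to_root = np.asarray(self.dist_to_root, dtype=float)
        self.terminal_rows = np.asarray(self.terminal_rows, dtype=int)

    @property
    def n_nodes(self) -> int:
        return len(self.coords)

    def edge_lengths(self) -> np.ndarray:
        rows = np.arange(self.n_nodes) != self.root_row
        return np.linalg.norm(
            self.coords[rows] - self.coords[self.parent[rows]], axis=1
        )

    def total_length(self) -> float:
        """Summed edge length (construction cost, mm)."""
        return float(self.edge_lengths().sum())

    def travel_distance(self) -> float:
        """Summed root-to-terminal path length (mm)."""
        return float(self.dist_to_root[self.terminal_rows].sum())

    def to_skeleton(self, terminal_labels: list[str] | None = None):
        """Serialize as a :class:`~shootpareto.skeleton.PlantSkeleton`.

        Terminal organs stay on leaves: any child of a terminal node is
        re-attached to the terminal's nearest non-terminal ancestor (this
        can occur for stochastic baselines and greedy trees).  Provenance
        and construction metadata land in the skeleton's ``meta``.
        """
        from .synth import tree_to_skeleton

        labels = terminal_labels or ["flower"] * len(self.terminal_rows)
        return tree_to_skeleton(
            self,
            labels,
            meta=dict(self.meta, provenance=self.provenance),
        )

    def validate(self) -> None:
        """Check the tree and root-distance invariants; raise on violation."""
        if self.parent[self.root_row] != -1:
            raise ValueError("root must have parent -1")
        if abs(self.dist_to_root[self.root_row]) > 1e-12:
            raise ValueError("root distance must be 0")
        for i in range(self.n_nodes):
            if i == self.root_row:
                continue
            p = self.parent[i]
            edge = float(np.linalg.norm(self.coords[i] - self.coords[p]))
            gap = abs(self.dist_to_root[i] - self.dist_to_root[p]) - edge
            if abs(gap) > 1e-6 * max(1.0, edge):
                raise ValueError(
                    f"node {i}: |Δdist_to_root| = "
                    f"{abs(self.dist_to_root[i] - self.dist_to_root[p]):.9g} "
                    f"!= edge length {edge:.9g}"
                )
        # parent pointers must reach the root from every node (acyclicity)
        for i in range(self.n_nodes):
            seen = set()
            j = i
            while j != self.root_row:
                if j in seen:
                    raise ValueError("cycle in parent pointers")
                seen.add(j)
                j = int(self.parent[j])


def _tree_from_adjacency(
    points: np.ndarray,
    adj: list[list[int]],
    provenance: str,
    meta: dict | None = None,
) -> ConstructedTree:
    """Root an undirected tree (over rows of ``points``) at row 0."""
    n = len(points)
    parent = np.full(n, -1, dtype=int)
    dist = np.zeros(n)
    order = [0]
    seen = np.zeros(n, dtype=bool)
    seen[0] = True
    head = 0
    while head < len(order):
        u = order[head]
        head += 1
        for v in adj[u]:
            if not seen[v]:
                seen[v] = True
                parent[v] = u
                dist[v] = dist[u] + float(np.linalg.norm(points[v] - points[u]))
                order.append(v)
    if not seen.all():
        raise ValueError("adjacency does not span all points")
    return ConstructedTree(
        coords=points,
        parent=parent,
        dist_to_root=dist,
        terminal_rows=np.arange(1, n),
        provenance=provenance,
        meta=meta or {},
    )


def satellite_travel(ts: TerminalSet) -> float:
    """Closed-form minimum travel distance: Σ‖v0 − v_i‖."""
    root = np.asarray(ts.root, dtype=float)
    return float(np.linalg.norm(ts.coords() - root, axis=1).sum())


def satellite_tree(ts: TerminalSet) -> ConstructedTree:
    """Star from the base to every terminal; minimizes travel distance."""
    pts = ts.all_points()
    n = ts.n
    dist = np.concatenate(
        [[0.0], np.linalg.norm(pts[1:] - pts[0], axis=1)]
    )
    return ConstructedTree(
        coords=pts,
        parent=np.concatenate([[-1], np.zeros(n, dtype=int)]),
        dist_to_root=dist,
        terminal_rows=np.arange(1, n + 1),
        provenance="satellite",
    )


def stable_tree(ts: TerminalSet) -> ConstructedTree:
    """Stem from the base to the terminal centroid, spokes to each terminal.

    If the centroid coincides with the base or with a terminal (within
    1e-9 mm) the coincident nodes are merged rather than creating a
    zero-length edge.
    """
    pts = ts.all_points()
    root = pts[0]
    terms = pts[1:]
    centroid = terms.mean(axis=0)
    n = ts.n
    if np.linalg.norm(centroid - root) < _MERGE_TOL:
        # centroid sits on the base: the stable tree degenerates to the star
        t = satellite_tree(ts)
        t.provenance = "stable"
        return t
    hit = np.flatnonzero(np.linalg.norm(terms - centroid, axis=1) < _MERGE_TOL)
    if hit.size:
        # a terminal sits at the centroid: reuse it as the hub
        hub_row = 1 + int(hit[0])
        coords = pts
        parent = np.full(n + 1, hub_row, dtype=int)
        parent[0] = -1
        parent[hub_row] = 0
    else:
        coords = np.vstack([pts, centroid])
        hub_row = n + 1
        parent = np.full(n + 2, hub_row, dtype=int)
        parent[0] = -1
        parent[hub_row] = 0
    dist = np.zeros(len(coords))
    stem = float(np.linalg.norm(coords[hub_row] - root))
    dist[hub_row] = stem
    spokes = np.flatnonzero((parent == hub_row))
    dist[spokes] = stem + np.linalg.norm(
        coords[spokes] - coords[hub_row], axis=1
    )
    return ConstructedTree(
        coords=coords,
        parent=parent,
        dist_to_root=dist,
        terminal_rows=np.arange(1, n + 1),
        provenance="stable",
    )


def pref_attach_tree(ts: TerminalSet, rng_seed: int) -> ConstructedTree:
    """Barabási–Albert tree (m = 1) over the base plus terminals.

    All |V| = n + 1 points, the base included, arrive in a uniformly random
    order; the first two are joined, and each later arrival attaches to an
    existing node with probability proportional to its current degree
    (sampled via the repeated-endpoint trick).  Distances are then measured
    from wherever the base landed in the tree.
    """
    rng = np.random.default_rng(rng_seed)
    pts = ts.all_points()
    nv = len(pts)
    order = rng.permutation(nv)
    adj: list[list[int]] = [[] for _ in range(nv)]
    if nv < 2:
        raise ValueError("need at least two points")
    a, b = int(order[0]), int(order[1])
    adj[a].append(b)
    adj[b].append(a)
    endpoints = [a, b]  # each node appears once per unit of degree
    for newcomer in order[2:]:
        target = endpoints[rng.integers(len(endpoints))]
        u = int(newcomer)
        adj[u].append(target)
        adj[target].append(u)
        endpoints.extend((u, target))
    return _tree_from_adjacency(pts, adj, "pref_attach", {"seed": rng_seed})


def random_spanning_tree(ts: TerminalSet, rng_seed: int) -> ConstructedTree:
    """Uniform random labeled spanning tree over the base plus terminals.

    Wilson's loop-erased random walk on the (unweighted) complete graph:
    each unattached vertex walks uniformly over all other vertices until it
    hits the growing tree, and the loop-erased path is grafted on.  The
    result is uniform over all |V|^(|V|−2) labeled trees; edge lengths enter
    only the objectives afterwards.
    """
    rng = np.random.default_rng(rng_seed)
    pts = ts.all_points()
    nv = len(pts)
    if nv < 2:
        raise ValueError("need at least two points")
    in_tree = np.zeros(nv, dtype=bool)
    in_tree[0] = True
    nxt = np.full(nv, -1, dtype=int)
    for start in range(1, nv):
        if in_tree[start]:
            continue
        u = start
        while not in_tree[u]:  # random walk, recording successors
            step = int(rng.integers(nv - 1))
            if step >= u:
                step += 1  # uniform over the other nv-1 vertices
            nxt[u] = step
            u = step
        u = start  # retrace the loop-erased path into the tree
        while not in_tree[u]:
            in_tree[u] = True
            u = nxt[u]
    adj: list[list[int]] = [[] for _ in range(nv)]
    for v in range(1, nv):
        w = int(nxt[v])
        adj[v].append(w)
        adj[w].append(v)
    return _tree_from_adjacency(pts, adj, "random", {"seed": rng_seed})


def bipartite_reference(
    ts: TerminalSet, aggregate: str = "sum"
) -> tuple[float, float]:
    """Sugar-transport optimum: the complete leaf-to-flower bipartite graph.

    Returns ``(sugar_distance, length)`` where both equal the aggregated
    straight-line distance over all (leaf, flower-or-silique) pairs — every
    pair is served by its own direct edge.  ``aggregate`` is ``"sum"``
    (default, consistent with the travel objective) or ``"mean"``.
    """
    from scipy.spatial.distance import cdist

    coords = ts.coords()
    labels = np.asarray(ts.labels())
    leaf_mask = np.isin(labels, sorted(LEAF_LABELS))
    flower_mask = np.isin(labels, sorted(FLOWER_LABELS))
    if not leaf_mask.any() or not flower_mask.any():
        raise NoTerminalsError(
            "bipartite reference needs at least one leaf and one flower/silique"
        )
    d = cdist(coords[leaf_mask], coords[flower_mask])
    agg = float(d.sum()) if aggregate == "sum" else float(d.mean())
    return agg, agg
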