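"""Rooted 3D plant-skeleton graphs and the two architecture objectives.

A skeleton is a geometric tree: nodes sit at 3D positions (mm) at the plant
base, at branch/bend points along stems, and at terminal organs (rosette
leaves, cauline leaves, flowers, siliques); edges are straight segments whose
length is the Euclidean distance between their endpoints.  The two objectives
defined here are the cost/performance pair the whole analysis trades off:

* ``total_length`` — the summed length of every edge (construction cost,
  a biomass proxy);
* ``travel_distance`` — the summed within-tree path length from the base to
  every terminal organ (nutrient-transport performance).

Edges are undirected for all distance computations; the root is used only to
orient traversals and to count children.
"""

from __future__ import annotations

import csv
import json
import math
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "ROOT_LABEL",
    "INTERIOR_LABELS",
    "TERMINAL_LABELS",
    "LEAF_LABELS",
    "FLOWER_LABELS",
    "ALL_LABELS",
    "Point3",
    "SkeletonNode",
    "PlantSkeleton",
    "TerminalSet",
    "ObjectivePair",
    "FeatureRecord",
    "SkeletonError",
    "MissingRootError",
    "DuplicateNodeError",
    "DisconnectedError",
    "CycleError",
    "ZeroLengthEdgeError",
    "UnknownLabelError",
    "NoTerminalsError",
    "total_length",
    "travel_distance",
    "extract_terminals",
    "filter_terminals",
    "prune_skeleton",
    "morphological_features",
    "load_skeleton",
    "save_skeleton",
]

ROOT_LABEL = "root"
INTERIOR_LABELS = frozenset({"branch", "bend"})
LEAF_LABELS = frozenset({"rosette_leaf", "cauline_leaf"})
FLOWER_LABELS = frozenset({"flower", "silique"})
TERMINAL_LABELS = LEAF_LABELS | FLOWER_LABELS
ALL_LABELS = frozenset({ROOT_LABEL}) | INTERIOR_LABELS | TERMINAL_LABELS

# CSV coordinate precision (decimal places); JSON round-trips full doubles.
CSV_DECIMALS = 6


class SkeletonError(ValueError):
    """Base class for skeleton validation failures."""


class MissingRootError(SkeletonError):
    """No node, or more than one node, carries the root label."""


class DuplicateNodeError(SkeletonError):
    """Two nodes share an id."""


class DisconnectedError(SkeletonError):
    """The edge set does not connect all nodes."""


class CycleError(SkeletonError):
    """The edge set contains a cycle."""


class ZeroLengthEdgeError(SkeletonError):
    """An edge joins two coincident points."""


class UnknownLabelError(SkeletonError):
    """A node label is outside the recognised vocabulary."""


class NoTerminalsError(SkeletonError):
    """An operation requiring terminal organs found none."""


Point3 = tuple[float, float, float]


def _as_point(x: float, y: float, z: float) -> Point3:
    p = (float(x), float(y), float(z))
    if not all(math.isfinite(c) for c in p):
        raise SkeletonError(f"non-finite coordinate {p!r}")
    return p


@dataclass(frozen=True)
class SkeletonNode:
    """A labeled point of the skeleton."""

    id: str
    coord: Point3
    label: str

    def __post_init__(self) -> None:
        if self.label not in ALL_LABELS:
            raise UnknownLabelError(
                f"node {self.id!r}: unknown label {self.label!r}"
            )
        object.__setattr__(self, "coord", _as_point(*self.coord))


@dataclass
class PlantSkeleton:
    """A validated rooted geometric tree.

    Attributes
    ----------
    nodes : mapping of node id to :class:`SkeletonNode`
    edges : list of unordered id pairs
    root_id : id of the unique root node
    meta : free-form provenance (e.g. the generating parameters)
    """

    nodes: dict[str, SkeletonNode]
    edges: list[tuple[str, str]]
    root_id: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._validate()
        self._adj: dict[str, list[tuple[str, float]]] = {
            nid: [] for nid in self.nodes
        }
        for a, b in self.edges:
            w = self.edge_length(a, b)
            self._adj[a].append((b, w))
            self._adj[b].append((a, w))

    # -- validation -------------------------------------------------------

    def _validate(self) -> None:
        roots = [n.id for n in self.nodes.values() if n.label == ROOT_LABEL]
        if len(roots) != 1 or roots[0] != self.root_id:
            raise MissingRootError(
                f"expected exactly one root node with id {self.root_id!r}, "
                f"found root-labeled nodes {roots!r}"
            )
        for a, b in self.edges:
            if a not in self.nodes or b not in self.nodes:
                raise SkeletonError(f"edge ({a!r}, {b!r}) references unknown node")
            if a == b:
                raise CycleError(f"self-loop at node {a!r}")
            if self.edge_length(a, b) <= 0.0:
                raise ZeroLengthEdgeError(
                    f"edge ({a!r}, {b!r}) has zero length"
                )
        n, m = len(self.nodes), len(self.edges)
        if m != n - 1:
            # distinguish the failure mode for the caller
            if m >= n:
                raise CycleError(f"{m} edges over {n} nodes imply a cycle")
            raise DisconnectedError(f"{m} edges cannot connect {n} nodes")
        # a connected check completes the tree proof (|E| = |V| - 1 + connected)
        seen = {self.root_id}
        stack = [self.root_id]
        adj: dict[str, list[str]] = {nid: [] for nid in self.nodes}
        for a, b in self.edges:
            adj[a].append(b)
            adj[b].append(a)
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        if len(seen) != n:
            raise DisconnectedError(
                f"{n - len(seen)} node(s) unreachable from the root"
            )
        # terminal labels only on leaves of the tree
        degree = {nid: len(adj[nid]) for nid in self.nodes}
        for node in self.nodes.values():
            if node.label in TERMINAL_LABELS and degree[node.id] > 1:
                raise SkeletonError(
                    f"terminal-labeled node {node.id!r} has degree "
                    f"{degree[node.id]}"
                )

    # -- basic geometry ----------------------------------------------------

    def edge_length(self, a: str, b: str) -> float:
        return math.dist(self.nodes[a].coord, self.nodes[b].coord)

    def terminal_ids(self) -> list[str]:
        """Ids of terminal-labeled nodes, in sorted id order."""
        return sorted(
            n.id for n in self.nodes.values() if n.label in TERMINAL_LABELS
        )

    def root_path_lengths(self) -> dict[str, float]:
        """Path length from the root to every node (BFS over the tree)."""
        dist = {self.root_id: 0.0}
        queue = deque([self.root_id])
        while queue:
            u = queue.popleft()
            for v, w in self._adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    queue.append(v)
        return dist

    def children(self) -> dict[str, list[str]]:
        """Children of each node in the tree rooted at ``root_id``."""
        out: dict[str, list[str]] = {nid: [] for nid in self.nodes}
        seen = {self.root_id}
        queue = deque([self.root_id])
        while queue:
            u = queue.popleft()
            for v, _ in self._adj[u]:
                if v not in seen:
                    seen.add(v)
                    out[u].append(v)
                    queue.append(v)
        return out

    def path_length(self, a: str, b: str) -> float:
        """Length of the unique tree path between two nodes."""
        dist = {a: 0.0}
        queue = deque([a])
        while queue:
            u = queue.popleft()
            if u == b:
                return dist[u]
            for v, w in self._adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    queue.append(v)
        raise DisconnectedError(f"no path between {a!r} and {b!r}")

    def to_networkx(self):
        """Export as a networkx.Graph with coord/label node attributes."""
        import networkx as nx

        g = nx.Graph()
        for node in self.nodes.values():
            g.add_node(node.id, coord=node.coord, label=node.label)
        for a, b in self.edges:
            g.add_edge(a, b, length=self.edge_length(a, b))
        return g


@dataclass(frozen=True)
class TerminalSet:
    """The algorithm input: the plant base plus the labeled terminal points."""

    root: Point3
    terminals: tuple[tuple[Point3, str], ...]

    def __post_init__(self) -> None:
        if not self.terminals:
            raise NoTerminalsError("a terminal set needs at least one terminal")
        for coord, label in self.terminals:
            if label not in TERMINAL_LABELS:
                raise UnknownLabelError(f"non-terminal label {label!r}")
            if coord == self.root:
                raise SkeletonError("terminal coincides with the root")

    @property
    def n(self) -> int:
        return len(self.terminals)

    def coords(self) -> np.ndarray:
        """Terminal coordinates as an (n, 3) array, in input order."""
        return np.asarray([c for c, _ in self.terminals], dtype=float)

    def labels(self) -> list[str]:
        return [l for _, l in self.terminals]

    def all_points(self) -> np.ndarray:
        """Root plus terminals as an (n+1, 3) array; the root is row 0."""
        return np.vstack([np.asarray(self.root, dtype=float), self.coords()])


@dataclass(frozen=True)
class ObjectivePair:
    """(total length, travel distance) of one architecture, in mm."""

    total_length: float
    travel_distance: float

    def __post_init__(self) -> None:
        if self.total_length <= 0 or self.travel_distance <= 0:
            raise ValueError("objectives must be positive")


@dataclass(frozen=True)
class FeatureRecord:
    """The per-replicate trait vector used in genotype statistics."""

    tradeoff: float
    epsilon: float
    alpha_closest: float
    total_length: float
    travel_distance: float
    n_rosette: int
    n_branch_points: int
    hull_volume: float

    def as_dict(self) -> dict[str, float]:
        return {
            "tradeoff": self.tradeoff,
            "epsilon": self.epsilon,
            "alpha_closest": self.alpha_closest,
            "total_length": self.total_length,
            "travel_distance": self.travel_distance,
            "n_rosette": self.n_rosette,
            "n_branch_points": self.n_branch_points,
            "hull_volume": self.hull_volume,
        }


# ---------------------------------------------------------------------------
# objectives
# ---------------------------------------------------------------------------

def total_length(skeleton: PlantSkeleton) -> float:
    """Summed Euclidean length of every edge (construction cost, mm)."""
    return float(
        sum(skeleton.edge_length(a, b) for a, b in skeleton.edges)
    )


def travel_distance(skeleton: PlantSkeleton) -> float:
    """Summed root-to-terminal path length over all terminal organs (mm).

    Interior bend and branch nodes do not contribute; only terminal-labeled
    leaves are transport endpoints.
    """
    terminals = skeleton.terminal_ids()
    if not terminals:
        raise NoTerminalsError("skeleton has no terminal-labeled node")
    dist = skeleton.root_path_lengths()
    return float(sum(dist[t] for t in terminals))


def extract_terminals(skeleton: PlantSkeleton) -> TerminalSet:
    """The plant base plus all terminal coordinates, in node-id order."""
    terms = tuple(
        (skeleton.nodes[t].coord, skeleton.nodes[t].label)
        for t in skeleton.terminal_ids()
    )
    if not terms:
        raise NoTerminalsError("skeleton has no terminal-labeled node")
    return TerminalSet(root=skeleton.nodes[skeleton.root_id].coord, terminals=terms)


def filter_terminals(ts: TerminalSet, exclude_labels: Iterable[str]) -> TerminalSet:
    """Drop terminals whose label is excluded (e.g. the rosette leaves)."""
    excluded = set(exclude_labels)
    kept = tuple(t for t in ts.terminals if t[1] not in excluded)
    if not kept:
        raise NoTerminalsError(
            f"excluding {sorted(excluded)!r} removes every terminal"
        )
    return TerminalSet(root=ts.root, terminals=kept)


def prune_skeleton(
    skeleton: PlantSkeleton, exclude_labels: Iterable[str]
) -> PlantSkeleton:
    """Remove excluded terminal organs and any dangling interior stubs.

    Used for the rosette-excluded re-analysis: excluded terminal nodes are
    deleted, then interior nodes left with degree 1 are stripped iteratively
    so the result is again a valid skeleton over the remaining organs.
    """
    excluded = set(exclude_labels)
    keep = {
        nid
        for nid, node in skeleton.nodes.items()
        if not (node.label in TERMINAL_LABELS and node.label in excluded)
    }
    if not any(skeleton.nodes[n].label in TERMINAL_LABELS for n in keep):
        raise NoTerminalsError("pruning removes every terminal")
    adj: dict[str, set[str]] = {nid: set() for nid in keep}
    for a, b in skeleton.edges:
        if a in keep and b in keep:
            adj[a].add(b)
            adj[b].add(a)
    changed = True
    while changed:
        changed = False
        for nid in list(adj):
            node = skeleton.nodes[nid]
            if (
                len(adj[nid]) <= 1
                and node.label in INTERIOR_LABELS
            ):
                for other in adj[nid]:
                    adj[other].discard(nid)
                del adj[nid]
                changed = True
    nodes = {nid: skeleton.nodes[nid] for nid in adj}
    edges = sorted(
        {tuple(sorted((a, b))) for a in adj for b in adj[a]}
    )
    return PlantSkeleton(
        nodes=nodes,
        edges=[(a, b) for a, b in edges],
        root_id=skeleton.root_id,
        meta=dict(skeleton.meta, pruned_labels=sorted(excluded)),
    )


def morphological_features(
    skeleton: PlantSkeleton,
) -> tuple[int, int, float]:
    """(rosette-leaf count, branch-point count, convex-hull volume in mm³).

    A node is a branch point iff it has at least two children in the tree
    rooted at the base.  The hull is taken over all skeleton node
    coordinates; degenerate (coplanar or collinear) point sets get volume 0.
    """
    n_rosette = sum(
        1 for n in skeleton.nodes.values() if n.label == "rosette_leaf"
    )
    children = skeleton.children()
    n_branch = sum(1 for kids in children.values() if len(kids) >= 2)
    pts = np.asarray([n.coord for n in skeleton.nodes.values()], dtype=float)
    if len(pts) < 4:
        volume = 0.0
    else:
        try:
            volume = float(ConvexHull(pts).volume)
        except QhullError:
            volume = 0.0
    return n_rosette, n_branch, volume


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _skeleton_from_records(
    records: Sequence[Mapping[str, object]],
    edge_pairs: Sequence[tuple[str, str]],
    meta: Mapping | None = None,
) -> PlantSkeleton:
    nodes: dict[str, SkeletonNode] = {}
    for rec in records:
        nid = str(rec["id"])
        if nid in nodes:
            raise DuplicateNodeError(f"duplicate node id {nid!r}")
        nodes[nid] = SkeletonNode(
            id=nid,
            coord=(float(rec["x"]), float(rec["y"]), float(rec["z"])),
            label=str(rec["label"]),
        )
    roots = [n.id for n in nodes.values() if n.label == ROOT_LABEL]
    if len(roots) != 1:
        raise MissingRootError(
            f"expected exactly one root-labeled node, found {len(roots)}"
        )
    return PlantSkeleton(
        nodes=nodes,
        edges=[(str(a), str(b)) for a, b in edge_pairs],
        root_id=roots[0],
        meta=dict(meta or {}),
    )


def load_skeleton(path: str | Path, format: str | None = None) -> PlantSkeleton:
    """Load a skeleton from JSON or a nodes/edges CSV pair.

    ``format`` is ``"json"`` or ``"csv"``; if omitted it is inferred from the
    suffix.  For CSV, ``path`` names the nodes file (``*nodes.csv``) and the
    edges file is found by replacing ``nodes`` with ``edges``.
    """
    path = Path(path)
    fmt = format or ("csv" if path.suffix == ".csv" else "json")
    if fmt == "json":
        doc = json.loads(path.read_text())
        return _skeleton_from_records(
            doc["nodes"], [tuple(e) for e in doc["edges"]], doc.get("meta")
        )
    if fmt == "csv":
        edges_path = Path(str(path).replace("nodes", "edges"))
        with open(path, newline="") as fh:
            records = list(csv.DictReader(fh))
        with open(edges_path, newline="") as fh:
            edge_pairs = [(row["id1"], row["id2"]) for row in csv.DictReader(fh)]
        return _skeleton_from_records(records, edge_pairs)
    raise ValueError(f"unknown skeleton format {fmt!r}")


def save_skeleton(
    skeleton: PlantSkeleton, path: str | Path, format: str | None = None
) -> None:
    """Write a skeleton as JSON or a nodes/edges CSV pair (see load_skeleton)."""
    path = Path(path)
    fmt = format or ("csv" if path.suffix == ".csv" else "json")
    if fmt == "json":
        doc = {
            "root_id": skeleton.root_id,
            "nodes": [
                {
                    "id": n.id,
                    "x": n.coord[0],
                    "y": n.coord[1],
                    "z": n.coord[2],
                    "label": n.label,
                }
                for n in skeleton.nodes.values()
            ],
            "edges": [[a, b] for a, b in skeleton.edges],
            "meta": skeleton.meta,
        }
        path.write_text(json.dumps(doc, indent=1))
        return
    if fmt == "csv":
        edges_path = Path(str(path).replace("nodes", "edges"))
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "x", "y", "z", "label"])
            for n in skeleton.nodes.values():
                writer.writerow(
                    [n.id]
                    + [f"{c:.{CSV_DECIMALS}f}" for c in n.coord]
                    + [n.label]
                )
        with open(edges_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id1", "id2"])
            writer.writerows(skeleton.edges)
        return
    raise ValueError(f"unknown skeleton format {fmt!r}")
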