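"""Synthetic Arabidopsis-like shoot architectures with known ground truth.

The generator emulates the geometry the analysis consumes: a rosette of
leaves ringing the base, plus an inflorescence stem carrying cauline leaves,
side branches, and flowers/siliques.  Plants are *built by the greedy joint
minimizer itself* at a genotype-specific prioritization weight alpha*, with
small "curvature" displacements of interior nodes — so each genotype has an
exact near-front ground truth (epsilon slightly above 1, stable trade-off
ratio) by construction.  This is a test harness for the analysis pipeline,
not a developmental model of plant growth.

Ground truth (alpha*, seed, parameters) is recorded in each skeleton's
metadata for recovery tests.
"""

from __future__ import annotations

import csv
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np

from .pareto import GreedyGrower, analyze_plant
from .reference import ConstructedTree
from .skeleton import (
    PlantSkeleton,
    SkeletonNode,
    TerminalSet,
    save_skeleton,
)
from .stats import GenotypeEnsemble

__all__ = [
    "GenotypeParams",
    "generate_terminal_set",
    "generate_plant",
    "generate_genotype_ensemble",
    "generate_growth_series",
    "tree_to_skeleton",
    "load_genotype_configs",
]


@dataclass(frozen=True)
class GenotypeParams:
    """Generator parameters for one genotype.

    Defaults describe a Columbia-wildtype-like plant: ~15 rosette leaves on a
    ~40 mm ring, a ~350 mm inflorescence with a few side branches, and a
    prioritization weight alpha* ≈ 0.14 (leaning toward minimizing length,
    as wildtype does).
    """

    name: str = "synthetic"
    n_rosette: int = 15
    n_cauline: int = 3
    n_flowers: int = 12
    rosette_radius: float = 40.0  # mm
    stem_height: float = 350.0  # mm
    n_side_branches: int = 3
    alpha_star: float = 0.143
    coord_noise_sd: float = 2.0  # mm, per-coordinate Gaussian
    count_jitter: int = 2  # per-replicate uniform jitter on organ counts
    size_jitter_sd: float = 0.3  # lognormal sigma of the per-plant size factor
    curvature_sd_frac: float = 0.01  # bend displacement, fraction of edge length
    k: int = 10  # subdivision points per greedy edge
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_rosette + self.n_cauline + self.n_flowers < 1:
            raise ValueError("at least one terminal organ required")
        if not 0.0 <= self.alpha_star <= 1.0:
            raise ValueError("alpha_star must lie in [0, 1]")
        if (
            self.coord_noise_sd < 0
            or self.curvature_sd_frac < 0
            or self.size_jitter_sd < 0
        ):
            raise ValueError("noise parameters must be non-negative")


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def generate_terminal_set(params: GenotypeParams, seed) -> TerminalSet:
    """Sample the base point plus labeled terminal coordinates.

    Rosette leaves sit on a jittered ring of ``rosette_radius`` at z within
    0–20 mm; cauline leaves sit close to the stem at intermediate heights;
    flowers/siliques sit near the stem apex and at side-branch tips.  A
    per-plant lognormal size factor (sigma ``size_jitter_sd``) rescales the
    whole architecture — replicates of a genotype differ visibly in overall
    size while their dimensionless features do not.  All coordinates then
    get isotropic Gaussian noise of ``coord_noise_sd`` mm.  Deterministic
    for a fixed seed.
    """
    rng = _rng(seed)
    size_factor = (
        rng.lognormal(0.0, params.size_jitter_sd)
        if params.size_jitter_sd > 0
        else 1.0
    )
    pts: list[np.ndarray] = []
    labels: list[str] = []

    for i in range(params.n_rosette):
        theta = 2 * np.pi * (i + rng.uniform(-0.25, 0.25)) / max(
            params.n_rosette, 1
        )
        r = params.rosette_radius * rng.uniform(0.75, 1.25)
        z = rng.uniform(0.0, 20.0)
        pts.append(np.array([r * np.cos(theta), r * np.sin(theta), z]))
        labels.append("rosette_leaf")

    # side branches: lateral direction and base height, reused by organs below
    n_br = max(params.n_side_branches, 1)
    br_theta = rng.uniform(0, 2 * np.pi, size=n_br)
    br_dir = np.column_stack(
        [np.cos(br_theta), np.sin(br_theta), np.zeros(n_br)]
    )
    br_height = np.sort(rng.uniform(0.35, 0.85, size=n_br)) * params.stem_height

    for i in range(params.n_cauline):
        b = i % n_br
        offset = rng.uniform(8.0, 20.0)
        pts.append(
            np.array([0.0, 0.0, br_height[b]])
            + br_dir[b] * offset
            + np.array([0.0, 0.0, rng.uniform(-10.0, 10.0)])
        )
        labels.append("cauline_leaf")

    for i in range(params.n_flowers):
        if params.n_side_branches and i % 2 == 0:
            # flower at a side-branch tip, angled upward and outward
            b = i % n_br
            lateral = rng.uniform(20.0, 60.0)
            rise = rng.uniform(30.0, 100.0)
            base = np.array([0.0, 0.0, br_height[b]])
            pts.append(base + br_dir[b] * lateral + np.array([0.0, 0.0, rise]))
        else:
            # flower on the main inflorescence near the apex
            z = params.stem_height * rng.uniform(0.8, 1.05)
            theta = rng.uniform(0, 2 * np.pi)
            lateral = rng.uniform(5.0, 25.0)
            pts.append(
                np.array(
                    [lateral * np.cos(theta), lateral * np.sin(theta), z]
                )
            )
        labels.append("flower" if i % 3 else "silique")

    coords = np.asarray(pts) * size_factor
    coords += rng.normal(0.0, params.coord_noise_sd, size=coords.shape)
    return TerminalSet(
        root=(0.0, 0.0, 0.0),
        terminals=tuple(
            (tuple(map(float, c)), lab) for c, lab in zip(coords, labels)
        ),
    )


def tree_to_skeleton(
    tree: ConstructedTree,
    terminal_labels: list[str],
    rng: np.random.Generator | None = None,
    curvature_sd: np.ndarray | float = 0.0,
    meta: dict | None = None,
) -> PlantSkeleton:
    """Turn a constructed tree into a labeled, validated skeleton.

    Interior (subdivision) nodes become bend or branch points and may be
    displaced by Gaussian "curvature" noise (``curvature_sd``: scalar or
    per-node array of mm).  Terminals that acquired children during greedy
    growth hand those children to their own parent so terminal organs stay
    on leaves of the tree.
    """
    n = tree.n_nodes
    coords = tree.coords.copy()
    parent = tree.parent.copy()
    term_rows = set(int(r) for r in tree.terminal_rows)

    # re-parent children of terminal rows onto the nearest non-terminal ancestor
    orig_parent = tree.parent
    for i in range(n):
        p = int(orig_parent[i])
        while p in term_rows:
            p = int(orig_parent[p])
        parent[i] = p

    if rng is not None and np.any(np.asarray(curvature_sd) > 0):
        sd = np.broadcast_to(np.asarray(curvature_sd, dtype=float), (n,))
        disp = rng.normal(0.0, 1.0, size=(n, 3)) * sd[:, None]
        movable = np.ones(n, dtype=bool)
        movable[tree.root_row] = False
        movable[list(term_rows)] = False
        coords[movable] += disp[movable]

    n_children = np.zeros(n, dtype=int)
    for i in range(n):
        if int(parent[i]) >= 0:
            n_children[int(parent[i])] += 1

    row_label: dict[int, str] = {tree.root_row: "root"}
    for r, lab in zip(tree.terminal_rows, terminal_labels):
        row_label[int(r)] = lab
    nodes = {}
    # fixed width keeps ids (and id-sorted order) stable across growth snapshots
    ids = [f"n{i:05d}" for i in range(n)]
    for i in range(n):
        lab = row_label.get(i)
        if lab is None:
            lab = "branch" if n_children[i] >= 2 else "bend"
        nodes[ids[i]] = SkeletonNode(
            id=ids[i], coord=tuple(map(float, coords[i])), label=lab
        )
    edges = [
        (ids[int(parent[i])], ids[i]) for i in range(n) if int(parent[i]) >= 0
    ]
    return PlantSkeleton(
        nodes=nodes,
        edges=edges,
        root_id=ids[tree.root_row],
        meta=dict(meta or {}),
    )


def generate_plant(params: GenotypeParams, seed) -> PlantSkeleton:
    """One synthetic plant: greedy construction at alpha* plus curvature noise.

    The returned skeleton records its ground truth (alpha*, seed, params) in
    ``meta``.
    """
    rng = _rng(seed)
    ts = generate_terminal_set(params, rng)
    grower = GreedyGrower(ts.root, params.alpha_star, params.k)
    grower.add_terminals(ts.coords())
    tree = grower.snapshot(provenance="plant")
    sd = _per_node_curvature_sd(tree, params)
    return tree_to_skeleton(
        tree,
        ts.labels(),
        rng=rng,
        curvature_sd=sd,
        meta={
            "genotype": params.name,
            "alpha_star": params.alpha_star,
            "seed": _seed_repr(seed),
            "params": asdict(params),
        },
    )


def _per_node_curvature_sd(tree: ConstructedTree, params: GenotypeParams) -> np.ndarray:
    """Curvature displacement scale per node: a fraction of its chain's edge."""
    n = tree.n_nodes
    # each node's segment length approximates its parent edge * (k+1)
    seg = np.zeros(n)
    for i in range(n):
        p = int(tree.parent[i])
        if p >= 0:
            seg[i] = np.linalg.norm(tree.coords[i] - tree.coords[p])
    return params.curvature_sd_frac * seg * (params.k + 1)


def _seed_repr(seed) -> object:
    if isinstance(seed, (int, np.integer)):
        return int(seed)
    return str(seed)


def _child_seeds(seed, n: int) -> list[int]:
    """n reproducible 31-bit child seeds from one root seed."""
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def _jittered(params: GenotypeParams, rng: np.random.Generator) -> GenotypeParams:
    j = params.count_jitter
    if j <= 0:
        return params
    return replace(
        params,
        n_rosette=max(int(params.n_rosette + rng.integers(-j, j + 1)), 0),
        n_cauline=max(int(params.n_cauline + rng.integers(-j, j + 1)), 0),
        n_flowers=max(int(params.n_flowers + rng.integers(-j, j + 1)), 1),
    )


def generate_genotype_ensemble(
    params: GenotypeParams,
    n_replicates: int,
    seed,
    out_dir: str | Path | None = None,
    analyze: bool = True,
    grid=None,
) -> tuple[GenotypeEnsemble | None, list[PlantSkeleton]]:
    """Generate a replicate ensemble (and optionally write skeleton files).

    Each replicate gets an independent child seed, a count-jittered copy of
    the parameters, and independent coordinate/curvature noise.  With
    ``analyze`` the full per-plant pipeline runs and a
    :class:`GenotypeEnsemble` of feature records is returned alongside the
    skeletons; otherwise the ensemble slot is ``None``.  With ``out_dir``,
    skeleton JSON files and a ``manifest.csv`` are written.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    seeds = _child_seeds(seed, n_replicates)
    plants: list[PlantSkeleton] = []
    rows = []
    for i, rep_seed in enumerate(seeds):
        jitter_rng = _rng(rep_seed)
        rep_params = _jittered(params, jitter_rng)
        plant = generate_plant(rep_params, rep_seed)
        plant.meta["replicate"] = i
        plants.append(plant)
        rows.append(
            {
                "file": f"{params.name}_rep{i:02d}.json",
                "genotype": params.name,
                "replicate": i,
                "seed": rep_seed,
                "alpha_star": params.alpha_star,
            }
        )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for plant, row in zip(plants, rows):
            save_skeleton(plant, out_dir / row["file"])
        with open(out_dir / f"{params.name}_manifest.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
            writer.writeheader()
            writer.writerows(rows)
    ensemble = None
    if analyze:
        records = [
            analyze_plant(p, grid=grid, k=params.k).features for p in plants
        ]
        ensemble = GenotypeEnsemble(genotype=params.name, records=records)
    return ensemble, plants


def generate_growth_series(
    params: GenotypeParams, n_timepoints: int, seed
) -> list[PlantSkeleton]:
    """Nested snapshots of one plant growing by online greedy extension.

    The rosette plus an initial share of inflorescence organs form the first
    time point; each later time point attaches its new terminals greedily at
    alpha* without disturbing the existing architecture, so every skeleton
    is a subgraph of its successor.  Curvature displacements are drawn once
    for the final tree and shared by all snapshots.
    """
    if n_timepoints < 2:
        raise ValueError("a growth series needs at least two time points")
    rng = _rng(seed)
    ts = generate_terminal_set(params, rng)
    labels = ts.labels()
    coords = ts.coords()
    rosette_idx = [i for i, l in enumerate(labels) if l == "rosette_leaf"]
    inflo_idx = [i for i, l in enumerate(labels) if l != "rosette_leaf"]
    # stage 1: rosette + first share of the inflorescence; later stages add the rest
    shares = np.array_split(np.asarray(inflo_idx, dtype=int), n_timepoints)
    grower = GreedyGrower(ts.root, params.alpha_star, params.k)
    stage_order: list[list[int]] = []
    snapshots: list[ConstructedTree] = []
    for t in range(n_timepoints):
        new_idx = (rosette_idx if t == 0 else []) + list(shares[t])
        if new_idx:
            grower.add_terminals(coords[new_idx])
        stage_order.append(new_idx)
        snapshots.append(grower.snapshot(provenance="plant"))
    order = [i for stage in stage_order for i in stage]
    final = snapshots[-1]
    sd = _per_node_curvature_sd(final, params)
    disp = rng.normal(0.0, 1.0, size=(final.n_nodes, 3)) * sd[:, None]
    skeletons = []
    for t, snap in enumerate(snapshots):
        m = snap.n_nodes
        moved = ConstructedTree(
            coords=snap.coords + _masked_disp(snap, disp[:m]),
            parent=snap.parent,
            dist_to_root=snap.dist_to_root,
            terminal_rows=snap.terminal_rows,
            provenance="plant",
        )
        term_labels = [labels[i] for i in order[: len(snap.terminal_rows)]]
        skeletons.append(
            tree_to_skeleton(
                moved,
                term_labels,
                meta={
                    "genotype": params.name,
                    "alpha_star": params.alpha_star,
                    "seed": _seed_repr(seed),
                    "timepoint": t,
                },
            )
        )
    return skeletons


def _masked_disp(tree: ConstructedTree, disp: np.ndarray) -> np.ndarray:
    out = disp.copy()
    out[tree.root_row] = 0.0
    out[tree.terminal_rows] = 0.0
    return out


def load_genotype_configs(path: str | Path) -> list[tuple[GenotypeParams, int]]:
    """Read a YAML genotype config: list of GenotypeParams fields plus
    ``n_replicates`` per entry (under a top-level ``genotypes`` key)."""
    import yaml

    doc = yaml.safe_load(Path(path).read_text())
    entries = doc["genotypes"] if isinstance(doc, dict) else doc
    out = []
    valid = set(GenotypeParams.__dataclass_fields__)
    for entry in entries:
        entry = dict(entry)
        n_rep = int(entry.pop("n_replicates", 5))
        unknown = set(entry) - valid
        if unknown:
            raise ValueError(
                f"unknown genotype config field(s): {sorted(unknown)}"
            )
        out.append((GenotypeParams(**entry), n_rep))
    return out
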