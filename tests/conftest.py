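import itertools

import numpy as np
import pytest

from shootpareto import GenotypeParams, PlantSkeleton, SkeletonNode, TerminalSet


def make_skeleton(nodes, edges, root_id="r"):
    """nodes: {id: (coord, label)} shorthand."""
    return PlantSkeleton(
        nodes={
            nid: SkeletonNode(id=nid, coord=coord, label=label)
            for nid, (coord, label) in nodes.items()
        },
        edges=list(edges),
        root_id=root_id,
    )


def random_terminal_set(rng, n, labels=("flower",)):
    pts = rng.uniform(-50.0, 50.0, size=(n, 3)) + np.array([0.0, 0.0, 60.0])
    labs = [labels[i % len(labels)] for i in range(n)]
    return TerminalSet(
        root=(0.0, 0.0, 0.0),
        terminals=tuple((tuple(map(float, p)), l) for p, l in zip(pts, labs)),
    )


def prufer_trees(n_vertices):
    """All labeled trees on n_vertices, as frozensets of edges (Prüfer)."""
    if n_vertices == 2:
        yield frozenset({(0, 1)})
        return
    for seq in itertools.product(range(n_vertices), repeat=n_vertices - 2):
        yield prufer_to_edges(seq, n_vertices)


def prufer_to_edges(seq, n_vertices):
    seq = list(seq)
    degree = [1] * n_vertices
    for s in seq:
        degree[s] += 1
    edges = []
    for s in seq:
        leaf = min(i for i in range(n_vertices) if degree[i] == 1)
        edges.append(tuple(sorted((leaf, s))))
        degree[leaf] -= 1
        degree[s] -= 1
    u, v = [i for i in range(n_vertices) if degree[i] == 1]
    edges.append(tuple(sorted((u, v))))
    return frozenset(edges)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def chain_skeleton():
    """root → bend → flower, collinear, unit edges."""
    return make_skeleton(
        {
            "r": ((0, 0, 0), "root"),
            "b": ((0, 0, 1), "bend"),
            "f": ((0, 0, 2), "flower"),
        },
        [("r", "b"), ("b", "f")],
    )


@pytest.fixture
def star_skeleton():
    """root with terminals at distances 5 (3-4-5) and 12."""
    return make_skeleton(
        {
            "r": ((0, 0, 0), "root"),
            "a": ((3, 4, 0), "rosette_leaf"),
            "b": ((0, 0, 12), "flower"),
        },
        [("r", "a"), ("r", "b")],
    )


@pytest.fixture
def small_params():
    """A light synthetic genotype for fast pipeline tests."""
    return GenotypeParams(
        name="test", n_rosette=6, n_cauline=2, n_flowers=6, count_jitter=1
    )
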