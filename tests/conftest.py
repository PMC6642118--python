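"""Shared fixtures: the 5-node toy tree, random trees, a fixture bundle."""

from __future__ import annotations

import io

import numpy as np
import pytest

from litmesh.mesh import MeshDescriptor, MeshTree, parse_mesh
from litmesh.fixtures import generate_fixtures

TOY_TSV = (
    "DA\tAlpha\tA01\n"
    "DB\tBeta\tA01.111\n"
    "DC\tGamma\tA01.111.222\n"
    "DD\tDelta\tA01.111.333\n"
    "DE\tEpsilon\tA01.444\n"
)


@pytest.fixture()
def toy_tree() -> MeshTree:
    """A=A01, B=A01.111, C=A01.111.222, D=A01.111.333, E=A01.444."""
    return parse_mesh(io.StringIO(TOY_TSV), dialect="tsv")


def make_random_tree(
    seed: int, n: int = 30, max_depth: int = 5, multi_frac: float = 0.2
) -> MeshTree:
    """Random multi-placement vocabulary for property tests."""
    rng = np.random.default_rng(seed)
    roots = ["A01", "B01"]
    positions = list(roots)
    owner = {p: i for i, p in enumerate(roots)}
    counter: dict[str, int] = {}
    idx = len(roots)
    while idx < n:
        eligible = [p for p in positions if p.count(".") + 1 < max_depth]
        parent = eligible[int(rng.integers(len(eligible)))]
        counter[parent] = counter.get(parent, 0) + 1
        pos = f"{parent}.{counter[parent]:03d}"
        positions.append(pos)
        owner[pos] = idx
        idx += 1
    placements: dict[int, list[str]] = {}
    for pos, i in owner.items():
        placements.setdefault(i, []).append(pos)
    if multi_frac > 0:
        for i in rng.choice(n, size=int(multi_frac * n), replace=False):
            eligible = [p for p in positions if p.count(".") + 1 < max_depth]
            parent = eligible[int(rng.integers(len(eligible)))]
            counter[parent] = counter.get(parent, 0) + 1
            placements[int(i)].append(f"{parent}.{counter[parent]:03d}")
    return MeshTree(
        MeshDescriptor(f"D{i:04d}", f"name-{i:04d}", tuple(sorted(placements[i])))
        for i in range(n)
    )


def bfs_placement_distance(tree: MeshTree, ui_a: str, ui_b: str) -> int:
    """Breadth-first-search oracle over the undirected placement forest.

    Nodes are tree positions plus a virtual root above category codes;
    the descriptor distance is the minimum over placement pairs.
    """
    ROOT = ""
    adj: dict[str, set[str]] = {ROOT: set()}
    for pos in tree.position_index:
        adj.setdefault(pos, set())
        parent = pos.rsplit(".", 1)[0] if "." in pos else ROOT
        adj.setdefault(parent, set())
        adj[pos].add(parent)
        adj[parent].add(pos)
    if ui_a == ui_b:
        return 0
    sources = tree.descriptors[ui_a].tree_numbers
    targets = set(tree.descriptors[ui_b].tree_numbers)
    best = None
    for src in sources:
        dist = {src: 0}
        frontier = [src]
        while frontier:
            nxt = []
            for node in frontier:
                for nb in adj[node]:
                    if nb not in dist:
                        dist[nb] = dist[node] + 1
                        nxt.append(nb)
            frontier = nxt
        for t in targets:
            if t in dist and (best is None or dist[t] < best):
                best = dist[t]
    assert best is not None
    return best


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Default-condition fixture bundle, generated once per session."""
    out = tmp_path_factory.mktemp("bundle")
    return generate_fixtures(1, out)
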