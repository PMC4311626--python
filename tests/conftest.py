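"""Shared fixtures and independent oracles.

The additive-tree generator and the patristic path-walk oracle here are
deliberately independent of the package's tree code: trees are built as
weighted adjacency graphs, distances by breadth-first path summation, and
splits by cutting edges — so they can serve as oracles for neighbor
joining and patristic extraction.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from mirrortree import DistanceMatrix, ProteinFamily, ProteinRecord

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


# ---------------------------------------------------------------------------
# independent random-additive-tree oracle
# ---------------------------------------------------------------------------

def random_additive_tree(rng: np.random.Generator, n_leaves: int,
                         blen_low: float = 0.05, blen_high: float = 1.0):
    """Random unrooted binary tree as a weighted adjacency graph.

    Returns (labels, adjacency) where adjacency maps node id -> list of
    (neighbor, weight); leaves are ids 0..n_leaves-1 with labels 'T00'....
    Topology: start from a 3-leaf star, then attach each further leaf to a
    uniformly chosen existing edge.
    """
    assert n_leaves >= 3
    labels = [f"T{i:02d}" for i in range(n_leaves)]
    next_id = n_leaves
    center = next_id
    next_id += 1
    edges = [(0, center), (1, center), (2, center)]
    for leaf in range(3, n_leaves):
        a, b = edges.pop(int(rng.integers(len(edges))))
        mid = next_id
        next_id += 1
        edges += [(a, mid), (b, mid), (leaf, mid)]
    adjacency: dict[int, list[tuple[int, float]]] = {}
    for a, b in edges:
        w = float(rng.uniform(blen_low, blen_high))
        adjacency.setdefault(a, []).append((b, w))
        adjacency.setdefault(b, []).append((a, w))
    return labels, adjacency


def path_walk_distances(labels, adjacency) -> np.ndarray:
    """Brute-force patristic oracle: per-leaf Dijkstra-free tree walk."""
    n = len(labels)
    mat = np.zeros((n, n))
    for src in range(n):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adjacency[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for dst in range(n):
            mat[src, dst] = dist[dst]
    np.fill_diagonal(mat, 0.0)
    return mat


def graph_splits(labels, adjacency) -> set[frozenset]:
    """Non-trivial splits of the graph tree, as sides not containing labels[0]."""
    n = len(labels)
    splits = set()
    seen = set()
    for a in adjacency:
        for b, _ in adjacency[a]:
            if (b, a) in seen:
                continue
            seen.add((a, b))
            # leaves reachable from b without crossing edge (a, b)
            comp = set()
            stack = [b]
            visited = {a, b}
            if b < n:
                comp.add(b)
            while stack:
                u = stack.pop()
                for v, _ in adjacency[u]:
                    if v not in visited:
                        visited.add(v)
                        if v < n:
                            comp.add(v)
                        stack.append(v)
            side = frozenset(labels[i] for i in comp)
            if 0 in comp:
                side = frozenset(labels) - side
            if 2 <= len(side) <= n - 2:
                splits.add(side)
    return splits


def graph_to_newick(labels, adjacency) -> str:
    """Render the adjacency tree as newick, rooted at the first internal node."""
    n = len(labels)
    root = n  # the initial star center

    def render(node, parent):
        children = [(v, w) for v, w in adjacency[node] if v != parent]
        if not children:
            return labels[node]
        inner = ",".join(f"{render(v, node)}:{w:.10g}" for v, w in children)
        return f"({inner})"

    return render(root, None) + ";"


def tree_splits(tree) -> set[frozenset]:
    """Splits of a dendropy tree, normalized like graph_splits."""
    from mirrortree.treebuild import _splits_of

    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    return set(_splits_of(tree, labels[0]).keys())


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def rng():
    return np.random.default_rng(20150130)


@pytest.fixture
def small_family():
    """A 4-organism aligned family with known pairwise differences."""
    return ProteinFamily(
        name="toy",
        records=[
            ProteinRecord(id="a|OrgA", organism="OrgA", sequence="AAAAAAAA"),
            ProteinRecord(id="b|OrgB", organism="OrgB", sequence="AAAAAAAV"),
            ProteinRecord(id="c|OrgC", organism="OrgC", sequence="AAAAAAVV"),
            ProteinRecord(id="d|OrgD", organism="OrgD", sequence="AAAVVVVV"),
        ],
    )


def family_from_strings(seqs: dict[str, str], name: str = "fam") -> ProteinFamily:
    return ProteinFamily(
        name=name,
        records=[
            ProteinRecord(id=f"{org.lower()}|{org}", organism=org, sequence=s)
            for org, s in seqs.items()
        ],
    )
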