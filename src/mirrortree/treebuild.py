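"""Distance-based tree inference and tree-derived distances.

Covers the tree stage of the mirrortree pipeline:

* neighbor-joining (Saitou–Nei agglomeration on the Q-criterion), which is
  exact on additive distance matrices;
* column-resampling bootstrap over an alignment, with a majority-rule
  extended consensus in which internal edges below a support threshold are
  collapsed;
* patristic distance matrices (sum of branch lengths along the leaf-to-leaf
  path), the quantity the mirrortree correlation is computed on;
* newick reading/writing, with bootstrap supports stored as internal node
  labels.

Trees are :class:`dendropy.Tree` objects throughout and are treated as
unrooted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

from .distance import DistanceMatrix, distance_matrix
from .errors import InputError, MirrortreeError
from .seqio import ProteinFamily, ProteinRecord


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(D: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree for a labeled distance matrix.

    Standard Saitou–Nei agglomeration: at each step join the pair (i, j)
    minimizing Q(i, j) = (m - 2) d(i, j) - r_i - r_j.  Ties in the Q minimum
    are broken by the smallest (row, column) index pair, so the result is
    deterministic.  Negative estimated branch lengths are clamped to zero
    with the deficit moved to the sister edge, preserving the joined pair's
    distance.  Exact on additive matrices.
    """
    n = len(D)
    if n < 3:
        raise InputError(f"neighbor joining needs at least 3 taxa, got {n}")

    tns = dendropy.TaxonNamespace(list(D.labels))
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes: list[dendropy.Node] = []
    for lab in D.labels:
        node = dendropy.Node()
        node.taxon = tns.get_taxon(lab)
        nodes.append(node)

    d = D.values.astype(float).copy()
    while d.shape[0] > 3:
        m = d.shape[0]
        r = d.sum(axis=1)
        Q = (m - 2) * d - r[:, None] - r[None, :]
        Q[np.tril_indices(m)] = np.inf  # row-major argmin => smallest (i, j), i < j
        i, j = divmod(int(np.argmin(Q)), m)

        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = _clamp_pair(li, lj)

        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj

        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], dnew[keep]])
        d = np.hstack([d, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    # final three-way star: closed-form edge lengths
    a = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    b = d[0, 1] - a
    c = d[0, 2] - a
    for node, length in zip(nodes, (a, b, c)):
        tree.seed_node.add_child(node)
        node.edge.length = max(length, 0.0)
    tree.is_rooted = False
    return tree


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    """Clamp a negative branch estimate to 0, shifting the deficit to its sister."""
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


# ---------------------------------------------------------------------------
# patristic distances
# ---------------------------------------------------------------------------

def patristic_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix, labels sorted lexicographically.

    Entry (i, j) sums the branch lengths on the unique path between leaves
    i and j.  Every non-root edge must carry a length.
    """
    leaves = [lf for lf in tree.leaf_node_iter()]
    if len(leaves) < 2:
        raise InputError("patristic matrix needs at least 2 leaves")
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            name = node.taxon.label if node.taxon else "internal node"
            raise InputError(f"missing branch length on edge above {name}")

    labels = sorted(lf.taxon.label for lf in leaves)
    if len(set(labels)) != len(labels):
        raise InputError("duplicate leaf labels")

    # depth of every node from the seed, then distance via lowest common ancestor
    depth: dict[dendropy.Node, float] = {tree.seed_node: 0.0}
    parent: dict[dendropy.Node, dendropy.Node] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent[node] = node.parent_node
        depth[node] = depth[node.parent_node] + node.edge.length

    by_label = {lf.taxon.label: lf for lf in leaves}
    ancestors: dict[str, dict[dendropy.Node, float]] = {}
    for lab in labels:
        chain: dict[dendropy.Node, float] = {}
        node = by_label[lab]
        while node is not None:
            chain[node] = depth[node]
            node = parent.get(node)
        ancestors[lab] = chain

    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        anc_i = ancestors[labels[i]]
        for j in range(i + 1, n):
            u, v = by_label[labels[i]], by_label[labels[j]]
            node = v
            while node not in anc_i:
                node = parent[node]
            mat[i, j] = mat[j, i] = depth[u] + depth[v] - 2 * depth[node]
    return DistanceMatrix(labels, mat)


# ---------------------------------------------------------------------------
# bootstrap and consensus
# ---------------------------------------------------------------------------

@dataclass
class BootstrapSet:
    """Replicate trees from column-resampling, plus the seed that made them."""

    replicates: list[dendropy.Tree]
    B: int
    seed: int

    def __post_init__(self) -> None:
        if self.B < 1 or len(self.replicates) != self.B:
            raise InputError("replicate count does not match B")


def bootstrap_trees(
    family: ProteinFamily,
    B: int = 100,
    seed: int = 0,
    gap_policy: str = "pairwise_deletion",
    correction: str = "poisson",
) -> BootstrapSet:
    """B neighbor-joining trees from alignments resampled column-wise.

    Each replicate draws alignment columns with replacement (same length),
    recomputes distances under the given gap policy/correction, and builds
    an NJ tree.  Reproducible for a fixed seed.
    """
    if B < 1:
        raise InputError("B must be >= 1")
    if not family.aligned:
        raise InputError(f"family {family.name!r} is not aligned")
    rng = np.random.default_rng(seed)
    ncol = family.alignment_length
    trees = []
    for b in range(B):
        cols = rng.integers(0, ncol, size=ncol)
        records = [
            ProteinRecord(
                id=rec.id,
                organism=rec.organism,
                sequence="".join(rec.sequence[c] for c in cols),
            )
            for rec in family.records
        ]
        rep = ProteinFamily(name=f"{family.name}#bs{b}", records=records)
        try:
            D = distance_matrix(rep, gap_policy=gap_policy, correction=correction)
            trees.append(nj_tree(D))
        except MirrortreeError as exc:
            raise type(exc)(f"bootstrap replicate {b}: {exc}") from exc
    return BootstrapSet(replicates=trees, B=B, seed=seed)


def _splits_of(tree: dendropy.Tree, ref: str) -> dict[frozenset, float]:
    """Non-trivial splits of an unrooted tree, as the side not containing *ref*.

    Maps each split to the length of its edge (None-safe: 0.0).
    """
    all_labels = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    n = len(all_labels)
    out: dict[frozenset, float] = {}
    for node in tree.postorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = all_labels - below if ref in below else below
        if 2 <= len(side) <= n - 2:
            out[side] = node.edge.length or 0.0
    return out


def _compatible(a: frozenset, b: frozenset) -> bool:
    return a <= b or b <= a or not (a & b)


def consensus_collapse(bs: BootstrapSet, threshold_pct: float = 45.0) -> dendropy.Tree:
    """Majority-rule extended consensus with low-support edges collapsed.

    Splits are counted over the replicates and greedily added in order of
    decreasing frequency (ties: smaller split, then lexicographic) as long
    as they stay pairwise compatible; edges whose support falls below
    ``threshold_pct`` percent are then contracted.  Supports are annotated
    as internal node labels; branch lengths are averages over the
    replicates that contain the corresponding split (leaf edges over all
    replicates).
    """
    if not 0 <= threshold_pct <= 100:
        raise InputError("threshold_pct must be in [0, 100]")
    trees = bs.replicates
    label_sets = {frozenset(lf.taxon.label for lf in t.leaf_node_iter()) for t in trees}
    if len(label_sets) != 1:
        raise InputError("bootstrap replicates disagree on the leaf set")
    labels = sorted(next(iter(label_sets)))
    ref = labels[0]

    counts: dict[frozenset, int] = {}
    lens: dict[frozenset, float] = {}
    leaf_lens = {lab: 0.0 for lab in labels}
    for t in trees:
        for split, length in _splits_of(t, ref).items():
            counts[split] = counts.get(split, 0) + 1
            lens[split] = lens.get(split, 0.0) + length
        for lf in t.leaf_node_iter():
            leaf_lens[lf.taxon.label] += lf.edge.length or 0.0

    candidates = sorted(
        counts, key=lambda s: (-counts[s], len(s), tuple(sorted(s)))
    )
    accepted: list[frozenset] = []
    for split in candidates:
        if all(_compatible(split, a) for a in accepted):
            accepted.append(split)
    kept = [s for s in accepted if 100.0 * counts[s] / bs.B >= threshold_pct]

    tns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    clade_nodes: dict[frozenset, dendropy.Node] = {}
    for split in sorted(kept, key=len, reverse=True):
        node = dendropy.Node()
        support = 100.0 * counts[split] / bs.B
        node.label = f"{support:g}"
        node.edge.length = lens[split] / counts[split]
        enclosing = [c for c in clade_nodes if split < c]
        parent = clade_nodes[min(enclosing, key=len)] if enclosing else root
        parent.add_child(node)
        clade_nodes[split] = node
    for lab in labels:
        node = dendropy.Node()
        node.taxon = tns.get_taxon(lab)
        node.edge.length = leaf_lens[lab] / bs.B
        enclosing = [c for c in clade_nodes if lab in c]
        parent = clade_nodes[min(enclosing, key=len)] if enclosing else root
        parent.add_child(node)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# newick I/O
# ---------------------------------------------------------------------------

_NEWICK_KWARGS = dict(
    schema="newick",
    suppress_rooting=True,
    unquoted_underscores=True,
    real_value_format_specifier=".12g",
)


def to_newick(tree: dendropy.Tree) -> str:
    """Newick string with branch lengths and supports as internal labels."""
    return tree.as_string(**_NEWICK_KWARGS).strip() + "\n"


def from_newick(newick: str) -> dendropy.Tree:
    """Parse a newick string; internal node labels (e.g. supports) are kept."""
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parser error types
        raise InputError(f"newick parse error: {exc}") from exc
    tree.is_rooted = False
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(to_newick(tree))


def read_newick(path: str | Path) -> dendropy.Tree:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    return from_newick(path.read_text())
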