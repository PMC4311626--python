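"""Synthetic coevolving (and null) protein-family pairs.

The generator emulates the data structure the mirrortree analysis assumes:
two organism-labeled families whose sequences evolved either along a shared
species tree (coevolving mode — distance matrices correlated) or along two
independently drawn trees over the same organisms (independent mode — the
null).  Sequences evolve under a 20-state equal-rates (Poisson) model, for
which the expected observed difference after total path length t is

    E[p] = (19/20) (1 - exp(-20 t / 19)),

the closed form every distance-stage test checks against.  Per-family
lognormal rate scalars model rate variation between families — the nuisance
that makes correlation, not equality, the right comparison.  An optional
"distant clade" grafts a long-branch subtree shared by both families,
mimicking the addition of remote but genuinely interacting homolog pairs
to a homolog set.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import dendropy
import numpy as np

from .errors import InputError
from .seqio import AMINO_ACIDS, ProteinFamily, ProteinRecord

_AA = np.frombuffer(AMINO_ACIDS.encode("ascii"), dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated family pair.

    Defaults describe the reference condition: 20 organisms on a Yule tree
    with birth rate 4 per lineage (expected root-to-tip depth around 0.65
    substitutions/site, i.e. divergent but unsaturated homologs), alignment
    length 200, lognormal rate scatter sigma = 0.3 between families.
    """

    n_organisms: int = 20
    birth_rate: float = 4.0
    seq_length: int = 200
    mode: str = "coevolving"
    rate_sigma: float = 0.3
    distant_clade: bool = False
    gap_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_organisms < 4:
            raise InputError("n_organisms must be >= 4")
        if self.seq_length < 1:
            raise InputError("seq_length must be >= 1")
        if self.birth_rate <= 0:
            raise InputError("birth_rate must be > 0")
        if self.mode not in ("coevolving", "independent"):
            raise InputError(f"unknown mode {self.mode!r}")
        if self.rate_sigma < 0:
            raise InputError("rate_sigma must be >= 0")
        if not 0.0 <= self.gap_fraction <= 0.5:
            raise InputError("gap_fraction must be in [0, 0.5]")

    def to_dict(self) -> dict:
        return {
            "n_organisms": self.n_organisms,
            "birth_rate": self.birth_rate,
            "seq_length": self.seq_length,
            "mode": self.mode,
            "rate_sigma": self.rate_sigma,
            "distant_clade": self.distant_clade,
            "gap_fraction": self.gap_fraction,
            "seed": self.seed,
        }


def _organism_labels(count: int, start: int = 1) -> list[str]:
    return [f"org_{i:03d}" for i in range(start, start + count)]


def _yule(labels: list[str], birth_rate: float, rng: np.random.Generator,
          tns: dendropy.TaxonNamespace) -> dendropy.Tree:
    """Pure-birth tree over the given labels.

    Starts from the root split (2 lineages); with k lineages the waiting
    time to the next split is Exp(birth_rate * k) and a uniformly chosen
    lineage splits.  After reaching len(labels) lineages one more waiting
    time elapses before the present, so the expected height is
    sum_{k=2}^{N} 1/(birth_rate * k).
    """
    n = len(labels)
    if n < 2:
        raise InputError("a Yule tree needs at least 2 tips")
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    # active lineages: (attachment node, birth time of its pendant edge)
    t = 0.0
    tips: list[tuple[dendropy.Node, float]] = []
    for _ in range(2):
        node = dendropy.Node()
        root.add_child(node)
        tips.append((node, 0.0))
    k = 2
    while k < n:
        t += rng.exponential(1.0 / (birth_rate * k))
        node, born = tips.pop(int(rng.integers(len(tips))))
        node.edge.length = t - born
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            tips.append((child, t))
        k += 1
    t += rng.exponential(1.0 / (birth_rate * k))
    order = rng.permutation(len(tips))
    for lab, idx in zip(labels, order):
        node, born = tips[idx]
        node.edge.length = t - born
        node.taxon = tns.get_taxon(lab)
    tree.is_rooted = False
    return tree


def tree_height(tree: dendropy.Tree) -> float:
    """Maximum root-to-leaf path length."""
    return max(
        lf.distance_from_root() for lf in tree.leaf_node_iter()
    )


def simulate_species_tree(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> dendropy.Tree:
    """Yule species tree with n_organisms leaves labeled org_001, org_002, ..."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    labels = _organism_labels(config.n_organisms)
    tns = dendropy.TaxonNamespace(labels)
    return _yule(labels, config.birth_rate, rng, tns)


def _graft_distant_clade(
    tree: dendropy.Tree, config: SimulationConfig, rng: np.random.Generator
) -> dendropy.Tree:
    """Attach a long-branch clade of extra organisms above the current root.

    The clade holds 20% of n_organisms (at least 2) fresh organisms on its
    own Yule subtree, joined to the original root by a stem of 3x the tree
    height — the "remote but coherent homologs" scenario.
    """
    n_extra = max(2, round(0.2 * config.n_organisms))
    extra = _organism_labels(n_extra, start=config.n_organisms + 1)
    height = tree_height(tree)
    tns = dendropy.TaxonNamespace(
        [t.label for t in tree.taxon_namespace] + extra
    )
    clade = _yule(extra, config.birth_rate, rng, tns)

    merged = dendropy.Tree(taxon_namespace=tns)
    old_root = tree.seed_node
    clade_root = clade.seed_node
    merged.seed_node.add_child(old_root)
    old_root.edge.length = 0.0
    merged.seed_node.add_child(clade_root)
    clade_root.edge.length = 3.0 * height
    for lf in merged.leaf_node_iter():
        lf.taxon = tns.get_taxon(lf.taxon.label)
    merged.is_rooted = False
    return merged


def evolve_family(
    tree: dendropy.Tree,
    config: SimulationConfig,
    rate_scalar: float = 1.0,
    rng: np.random.Generator | None = None,
    name: str = "family",
) -> ProteinFamily:
    """Evolve an aligned family down a species tree under the Poisson model.

    The root sequence is uniform over the 20 amino acids; along a branch of
    length t each site substitutes with probability
    (19/20)(1 - exp(-20 t rate_scalar / 19)), to a uniformly chosen
    *different* residue.  Optional gaps are punched into random cells at
    rate ``gap_fraction`` afterwards.
    """
    if rate_scalar <= 0:
        raise InputError("rate_scalar must be > 0")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    L = config.seq_length

    seqs: dict[dendropy.Node, np.ndarray] = {
        tree.seed_node: rng.integers(0, 20, size=L)
    }
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        t = node.edge.length
        if t is None:
            raise InputError("tree has an edge without length")
        parent_seq = seqs[node.parent_node]
        p_sub = (19.0 / 20.0) * (1.0 - np.exp(-20.0 * t * rate_scalar / 19.0))
        hit = rng.random(L) < p_sub
        seq = parent_seq.copy()
        seq[hit] = (seq[hit] + rng.integers(1, 20, size=int(hit.sum()))) % 20
        seqs[node] = seq
        if not node.is_leaf():
            continue

    records = []
    leaves = sorted(tree.leaf_node_iter(), key=lambda lf: lf.taxon.label)
    gap_mask = None
    if config.gap_fraction > 0:
        gap_mask = rng.random((len(leaves), L)) < config.gap_fraction
    for i, lf in enumerate(leaves):
        chars = _AA[seqs[lf]]
        seq = bytearray(chars.tobytes())
        if gap_mask is not None:
            for c in np.flatnonzero(gap_mask[i]):
                seq[c] = ord("-")
        lab = lf.taxon.label
        records.append(
            ProteinRecord(id=f"{name}|{lab}", organism=lab,
                          sequence=seq.decode("ascii"))
        )
    return ProteinFamily(name=name, records=records)


def make_family_pair(
    config: SimulationConfig, return_trees: bool = False
):
    """Simulate the two families of one mirrortree experiment.

    coevolving mode: both families evolve on the *same* species tree, with
    independent lognormal rate scalars (median 1, log-sd ``rate_sigma``).
    independent mode: each family evolves on its own Yule tree drawn over
    the same organism labels.  With ``return_trees`` the true species
    tree(s) are returned as a third element.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_tree1, rng_tree2, rng_rates, rng_ev1, rng_ev2 = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    tree1 = simulate_species_tree(config, rng_tree1)
    if config.distant_clade:
        tree1 = _graft_distant_clade(tree1, config, rng_tree1)
    if config.mode == "coevolving":
        tree2 = tree1
    else:
        tree2 = simulate_species_tree(config, rng_tree2)
        if config.distant_clade:
            tree2 = _graft_distant_clade(tree2, config, rng_tree2)

    rho1, rho2 = np.exp(rng_rates.normal(0.0, config.rate_sigma, size=2))
    fam1 = evolve_family(tree1, config, rho1, rng_ev1, name="family1")
    fam2 = evolve_family(tree2, config, rho2, rng_ev2, name="family2")
    if return_trees:
        return fam1, fam2, (tree1, tree2)
    return fam1, fam2


def reference_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The package's reference study condition with a given seed."""
    return replace(SimulationConfig(seed=seed), **overrides)
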