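"""Rank-based taxonomy trees, Faith's PD, phylogenetic dispersion, Blomberg's K.

No molecular phylogeny is available for the species pool, so phylogenetic
structure is approximated by a nested taxonomy (superclass, class, order,
family, genus, species) turned into a rooted tree with unit branch lengths
per rank step.  Every tip therefore sits at depth 6 below an artificial root
placed above the superclasses.

On that tree the module computes:

* Faith's phylogenetic diversity (PD): the total branch length of the minimal
  rooted subtree spanning a set of species (root included, so a single
  species has PD 6);
* phylogenetic dispersion (PDis): per-station residuals of PD regressed on
  species richness;
* Blomberg's K with a tip-shuffling permutation test for phylogenetic signal
  in a continuous trait (here, the fast-slow rank vectors).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

#: Internal-node rank order from root downwards (species level = tips).
TREE_RANKS = ("superclass", "class", "order", "family", "genus")


class TaxonomyError(ValueError):
    """Raised on inconsistent nesting or unknown species."""


def build_taxonomy_tree(meta: pd.DataFrame) -> dendropy.Tree:
    """Build the unit-branch-length taxonomy tree from a metadata table.

    ``meta`` is indexed by species_id with columns superclass..genus and
    species_name.  Tips are labelled by species_id.  Each taxon must nest
    under exactly one parent taxon (no genus in two families).
    """
    required = list(TREE_RANKS)
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise TaxonomyError(f"metadata missing taxonomy columns: {missing}")

    taxon_namespace = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    tree.seed_node.label = "root"
    # (rank_index, taxon_name) -> node; also check single parentage
    nodes: dict[tuple[int, str], dendropy.Node] = {}
    parent_of: dict[tuple[int, str], str] = {}

    for sid, row in meta.iterrows():
        path = [str(row[r]) for r in TREE_RANKS]
        parent = tree.seed_node
        for level, name in enumerate(path):
            key = (level, name)
            parent_name = "root" if level == 0 else path[level - 1]
            if key in parent_of and parent_of[key] != parent_name:
                raise TaxonomyError(
                    f"taxon {name!r} at rank {TREE_RANKS[level]!r} nested under "
                    f"both {parent_of[key]!r} and {parent_name!r}"
                )
            parent_of.setdefault(key, parent_name)
            node = nodes.get(key)
            if node is None:
                node = parent.new_child(edge_length=1.0)
                node.label = name
                nodes[key] = node
            parent = node
        taxon = taxon_namespace.new_taxon(label=str(sid))
        tip = parent.new_child(taxon=taxon, edge_length=1.0)
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def _tip_edge_paths(tree: dendropy.Tree) -> dict[str, list[int]]:
    """Map tip label -> list of edge ids on the path tip..root (cached)."""
    cache = getattr(tree, "_fastslow_paths", None)
    if cache is not None:
        return cache
    edge_ids: dict[int, int] = {}
    lengths: list[float] = []
    paths: dict[str, list[int]] = {}
    for leaf in tree.leaf_node_iter():
        path = []
        node = leaf
        while node.parent_node is not None:
            eid = id(node.edge)
            if eid not in edge_ids:
                edge_ids[eid] = len(lengths)
                lengths.append(float(node.edge.length or 0.0))
            path.append(edge_ids[eid])
            node = node.parent_node
        paths[leaf.taxon.label] = path
    tree._fastslow_paths = paths
    tree._fastslow_edge_lengths = np.asarray(lengths)
    return paths


def faith_pd(tree: dendropy.Tree, taxa: Iterable[str]) -> float:
    """Faith's PD: branch length of the minimal rooted subtree over ``taxa``."""
    taxa = list(taxa)
    if not taxa:
        raise ValueError("taxa set must be non-empty")
    paths = _tip_edge_paths(tree)
    lengths = tree._fastslow_edge_lengths
    unknown = [t for t in taxa if t not in paths]
    if unknown:
        raise TaxonomyError(f"species not in tree: {unknown}")
    edges: set[int] = set()
    for t in taxa:
        edges.update(paths[t])
    return float(lengths[list(edges)].sum())


def phylo_dispersion(
    pd_values: Sequence[float], sr_values: Sequence[float]
) -> np.ndarray:
    """OLS residuals of PD on species richness, in station order.

    Positive PDis = assemblage more phylogenetically diverse than its
    richness predicts.
    """
    pd_arr = np.asarray(pd_values, dtype=float)
    sr = np.asarray(sr_values, dtype=float)
    if pd_arr.shape != sr.shape or pd_arr.ndim != 1:
        raise ValueError("pd_values and sr_values must be 1-D and equal length")
    if len(sr) < 3:
        raise ValueError("need at least 3 stations to fit PD ~ SR")
    if np.ptp(sr) == 0:
        raise ValueError("species richness is constant; PD~SR slope unidentifiable")
    design = np.column_stack([np.ones_like(sr), sr])
    beta, *_ = np.linalg.lstsq(design, pd_arr, rcond=None)
    return pd_arr - design @ beta


def _brownian_vcv(tree: dendropy.Tree, tip_order: Sequence[str]) -> np.ndarray:
    """Brownian covariance matrix: V[i,j] = root-to-MRCA(i,j) path length."""
    cache = getattr(tree, "_fastslow_vcv", None)
    key = tuple(tip_order)
    if cache is not None and cache[0] == key:
        return cache[1]
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    unknown = [t for t in tip_order if t not in taxa]
    if unknown:
        raise TaxonomyError(f"species not in tree: {unknown}")
    depths = {
        leaf.taxon.label: float(leaf.distance_from_root())
        for leaf in tree.leaf_node_iter()
    }
    n = len(tip_order)
    V = np.empty((n, n))
    for i, a in enumerate(tip_order):
        V[i, i] = depths[a]
        for j in range(i + 1, n):
            b = tip_order[j]
            d = float(pdm.patristic_distance(taxa[a], taxa[b]))
            # depth of MRCA = (depth_a + depth_b - patristic distance)/2
            V[i, j] = V[j, i] = 0.5 * (depths[a] + depths[b] - d)
    tree._fastslow_vcv = (key, V)
    return V


def _k_from_vcv(V: np.ndarray, x: np.ndarray) -> float | np.ndarray:
    """Blomberg's K for trait column(s) x given the Brownian covariance V.

    K = (MSE0/MSE) / E[MSE0/MSE], with the GLS-estimated root state
    a_hat = (1' V^-1 x)/(1' V^-1 1), MSE0 the mean squared tip deviation from
    a_hat, MSE the GLS mean squared error, and
    E[MSE0/MSE] = (tr(V) - n / sum(V^-1)) / (n - 1).
    Accepts a vector or an (n, m) matrix of traits; vectorised over columns.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = x[:, None] if single else x
    n = V.shape[0]
    Vinv = np.linalg.inv(V)
    one = np.ones(n)
    Vinv_one = Vinv @ one
    denom_root = float(one @ Vinv_one)
    a_hat = (Vinv_one @ X) / denom_root  # (m,)
    D = X - a_hat[None, :]
    mse0 = np.einsum("im,im->m", D, D) / (n - 1)
    mse = np.einsum("im,im->m", D, Vinv @ D) / (n - 1)
    if np.any(mse <= 0) or np.any(mse0 <= 0):
        raise ValueError("trait is constant; Blomberg's K undefined")
    expected = (np.trace(V) - n / Vinv.sum()) / (n - 1)
    K = (mse0 / mse) / expected
    return float(K[0]) if single else K


def blomberg_k(tree: dendropy.Tree, trait: Mapping[str, float] | pd.Series) -> float:
    """Blomberg's K of a continuous trait on the taxonomy tree.

    K = 1 under Brownian evolution along the tree; K -> 0 with no signal;
    K > 1 when relatives resemble each other more than Brownian expects.
    """
    trait = pd.Series(trait, dtype=float)
    tips = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    missing = [t for t in tips if t not in trait.index]
    if missing:
        raise ValueError(f"trait undefined for tips: {missing}")
    V = _brownian_vcv(tree, tips)
    return _k_from_vcv(V, trait.loc[tips].to_numpy())


@dataclass(frozen=True)
class SignalTestResult:
    """Observed K with its tip-shuffling permutation p-value."""

    K: float
    p_value: float
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        assert self.p_value >= 1.0 / (self.n_permutations + 1)


def phylo_signal_test(
    tree: dendropy.Tree,
    trait: Mapping[str, float] | pd.Series,
    n_permutations: int = 999,
    seed: int = 0,
) -> SignalTestResult:
    """Permutation test of phylogenetic signal in a trait via Blomberg's K.

    Trait values are shuffled across tips; p = (1 + #{K_perm >= K_obs}) /
    (n_permutations + 1).  With 999 permutations the smallest attainable p
    is 0.001.
    """
    if n_permutations < 99:
        raise ValueError("need at least 99 permutations")
    trait = pd.Series(trait, dtype=float)
    tips = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    missing = [t for t in tips if t not in trait.index]
    if missing:
        raise ValueError(f"trait undefined for tips: {missing}")
    x = trait.loc[tips].to_numpy()
    V = _brownian_vcv(tree, tips)
    k_obs = _k_from_vcv(V, x)
    rng = np.random.default_rng(seed)
    perms = np.column_stack(
        [rng.permutation(x) for _ in range(n_permutations)]
    )
    k_perm = _k_from_vcv(V, perms)
    p = (1 + int(np.sum(k_perm >= k_obs))) / (n_permutations + 1)
    return SignalTestResult(K=k_obs, p_value=p, n_permutations=n_permutations, seed=seed)
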