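import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

import fastslow as fs
from fastslow.phylogeny import (
    TaxonomyError,
    _brownian_vcv,
    read_newick,
    write_newick,
)


def meta_from_paths(paths):
    """Build a metadata frame from {species_id: 5-tuple of internal ranks}."""
    rows = {
        sid: dict(zip(("superclass", "class", "order", "family", "genus"), p))
        for sid, p in paths.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def star_tree(n, depth=6.0):
    """All tips hang directly off the root at equal depth (no structure)."""
    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    for i in range(n):
        taxon = ns.new_taxon(label=f"t{i}")
        tree.seed_node.new_child(taxon=taxon, edge_length=depth)
    return tree


class TestBuildTaxonomyTree:
    def test_single_species_is_a_six_edge_path(self):
        meta = meta_from_paths({"sp1": ("S", "C", "O", "F", "G")})
        tree = fs.build_taxonomy_tree(meta)
        assert tree.length() == 6.0
        assert fs.faith_pd(tree, ["sp1"]) == 6.0

    def test_two_congeners_share_the_root_to_genus_path(self):
        meta = meta_from_paths(
            {"sp1": ("S", "C", "O", "F", "G"), "sp2": ("S", "C", "O", "F", "G")}
        )
        tree = fs.build_taxonomy_tree(meta)
        # 5 shared internal edges + 2 tip edges
        assert tree.length() == 7.0

    def test_inconsistent_nesting_names_the_taxon(self):
        meta = meta_from_paths(
            {"sp1": ("S", "C", "O", "F1", "G"), "sp2": ("S", "C", "O", "F2", "G")}
        )
        with pytest.raises(TaxonomyError, match="'G'"):
            fs.build_taxonomy_tree(meta)

    def test_newick_round_trip_preserves_tips_and_distances(self, tmp_path, small_tree):
        path = tmp_path / "tree.nwk"
        write_newick(small_tree, path)
        back = read_newick(path)
        tips1 = sorted(l.taxon.label for l in small_tree.leaf_node_iter())
        tips2 = sorted(l.taxon.label for l in back.leaf_node_iter())
        assert tips1 == tips2
        V1 = _brownian_vcv(small_tree, tips1)
        V2 = _brownian_vcv(back, tips1)
        np.testing.assert_allclose(V1, V2, atol=1e-9)


class TestFaithPD:
    def test_two_species_in_different_superclasses(self):
        meta = meta_from_paths(
            {"sp1": ("S1", "C1", "O1", "F1", "G1"),
             "sp2": ("S2", "C2", "O2", "F2", "G2")}
        )
        tree = fs.build_taxonomy_tree(meta)
        assert fs.faith_pd(tree, ["sp1", "sp2"]) == 12.0

    def test_unknown_species_rejected(self, small_tree):
        with pytest.raises(TaxonomyError, match="nope"):
            fs.faith_pd(small_tree, ["nope"])

    def test_monotone_under_species_addition(self, small_pool, small_tree):
        pool, _ = small_pool
        rng = np.random.default_rng(0)
        order = list(rng.permutation(pool.species_ids))
        pds = [fs.faith_pd(small_tree, order[: k + 1]) for k in range(len(order))]
        assert all(b >= a for a, b in zip(pds, pds[1:]))
        assert pds[-1] == pytest.approx(small_tree.length())

    def test_matches_edge_enumeration_oracle_on_all_subsets(self):
        pool, _ = fs.simulate_species_pool(
            fs.SimulationConfig(n_species=10, n_superclasses=2, n_classes=3,
                                n_orders=4, n_families=5, n_genera=7,
                                n_imputed_flags=0),
            11,
        )
        tree = fs.build_taxonomy_tree(pool.meta)
        # oracle: for every edge, does its tip-descendant set hit the subset?
        edges = []
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            tips = frozenset(
                l.taxon.label for l in node.leaf_iter()
            )
            edges.append((tips, float(node.edge.length)))
        species = pool.species_ids
        for r in range(1, 11):
            for subset in itertools.combinations(species, r):
                s = set(subset)
                oracle = sum(ln for tips, ln in edges if tips & s)
                assert fs.faith_pd(tree, subset) == pytest.approx(oracle)

    def test_frozen_reference_value(self, small_pool, small_tree):
        # value independently verified with picante::pd (include.root=TRUE)
        pool, _ = small_pool
        assert fs.faith_pd(small_tree, pool.species_ids[:5]) == pytest.approx(21.0)


class TestPhyloDispersion:
    def test_affine_pd_gives_zero_residuals(self):
        sr = np.array([1.0, 2.0, 3.0, 4.0])
        out = fs.phylo_dispersion(6 + 2 * sr, sr)
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_hand_computed_ols_residuals(self):
        # PD ~ SR through (1,6),(2,7),(3,14): slope 4, intercept 1
        out = fs.phylo_dispersion([6.0, 7.0, 14.0], [1.0, 2.0, 3.0])
        np.testing.assert_allclose(out, [1.0, -2.0, 1.0], atol=1e-10)

    def test_residuals_sum_to_zero(self):
        rng = np.random.default_rng(1)
        sr = rng.integers(1, 20, size=50).astype(float)
        pdv = 3 * sr + rng.normal(size=50)
        assert fs.phylo_dispersion(pdv, sr).sum() == pytest.approx(0.0, abs=1e-9)

    def test_location_invariance(self):
        rng = np.random.default_rng(2)
        sr = rng.integers(1, 20, size=30).astype(float)
        pdv = 2 * sr + rng.normal(size=30)
        r1 = fs.phylo_dispersion(pdv, sr)
        r2 = fs.phylo_dispersion(pdv + 100.0, sr)
        np.testing.assert_allclose(r1, r2, atol=1e-9)

    def test_constant_richness_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fs.phylo_dispersion([6.0, 7.0, 8.0], [3.0, 3.0, 3.0])


class TestBlombergK:
    def test_star_tree_k_is_one(self):
        tree = star_tree(15)
        rng = np.random.default_rng(3)
        trait = pd.Series(rng.normal(size=15), index=[f"t{i}" for i in range(15)])
        assert fs.blomberg_k(tree, trait) == pytest.approx(1.0, abs=1e-10)

    def test_deep_clade_indicator_exceeds_one(self):
        paths = {}
        for i in range(4):
            paths[f"a{i}"] = ("S1", "C1", "O1", "F1", "G1")
            paths[f"b{i}"] = ("S2", "C2", "O2", "F2", "G2")
        tree = fs.build_taxonomy_tree(meta_from_paths(paths))
        trait = pd.Series(
            {f"a{i}": 0.0 + 0.01 * i for i in range(4)}
            | {f"b{i}": 1.0 + 0.01 * i for i in range(4)}
        )
        assert fs.blomberg_k(tree, trait) > 1.0

    def test_frozen_picante_reference(self, small_pool, small_tree):
        # K computed independently with picante::Kcalc on this exact fixture
        pool, _ = small_pool
        rng = np.random.default_rng(7)
        trait = pd.Series(
            rng.normal(size=12), index=pool.species_ids
        ).round(6)
        assert fs.blomberg_k(small_tree, trait) == pytest.approx(0.320099, abs=1e-6)

    def test_brownian_traits_average_k_near_one(self, small_tree):
        tips = sorted(l.taxon.label for l in small_tree.leaf_node_iter())
        V = _brownian_vcv(small_tree, tips)
        L = np.linalg.cholesky(V)
        rng = np.random.default_rng(4)
        X = L @ rng.normal(size=(len(tips), 200))
        from fastslow.phylogeny import _k_from_vcv

        ks = _k_from_vcv(V, X)
        assert abs(ks.mean() - 1.0) <= 0.1

    def test_constant_trait_rejected(self, small_pool, small_tree):
        pool, _ = small_pool
        trait = pd.Series(1.0, index=pool.species_ids)
        with pytest.raises(ValueError, match="constant"):
            fs.blomberg_k(small_tree, trait)


class TestSignalTest:
    def test_clade_structured_trait_hits_permutation_floor(self):
        paths = {}
        for i in range(8):
            clade = "S1" if i < 4 else "S2"
            paths[f"t{i}"] = (clade, f"C{clade}", f"O{clade}", f"F{clade}", f"G{clade}")
        tree = fs.build_taxonomy_tree(meta_from_paths(paths))
        trait = pd.Series(
            {f"t{i}": (0.0 if i < 4 else 10.0) + 0.01 * i for i in range(8)}
        )
        res = fs.phylo_signal_test(tree, trait, n_permutations=999, seed=5)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_same_seed_reproduces_p(self, default_tree, default_ranks):
        a = fs.phylo_signal_test(default_tree, default_ranks.ranks("fs1"), 199, seed=9)
        b = fs.phylo_signal_test(default_tree, default_ranks.ranks("fs1"), 199, seed=9)
        assert a.p_value == b.p_value and a.K == b.K

    def test_default_pool_ranks_carry_signal(self, default_tree, default_ranks):
        res = fs.phylo_signal_test(default_tree, default_ranks.ranks("fs1"), 999, seed=0)
        assert res.p_value <= 0.01

    def test_too_few_permutations_rejected(self, default_tree, default_ranks):
        with pytest.raises(ValueError, match="99"):
            fs.phylo_signal_test(default_tree, default_ranks.ranks("fs1"), 10, seed=0)
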