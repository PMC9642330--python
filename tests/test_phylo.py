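"""Neighbour-joining recovery, bootstrap determinism and monophyly."""

import itertools

import numpy as np
import pytest

from barcodekit.distances import DistanceMatrix, distance_matrix
from barcodekit.phylo import (
    bootstrap_support,
    monophyly,
    nj_tree,
    read_newick,
    write_newick,
)
from barcodekit.synthgen import SynthSpec, generate_community

from conftest import make_dataset


def _dm(ids, mat):
    return DistanceMatrix(ids, np.asarray(mat, dtype=float), "k2p")


def _tip_distances(tree, ids):
    out = np.zeros((len(ids), len(ids)))
    dm = tree.tip_tip_distances(ids)
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            out[i, j] = dm[a, b]
    return out


def _random_additive(rng, n_taxa):
    """Random binary tree with positive lengths and its path-distance matrix."""
    import skbio

    nodes = [skbio.TreeNode(name=f"t{i}", length=None) for i in range(n_taxa)]
    for node in nodes:
        node.length = float(rng.integers(1, 10))
    while len(nodes) > 2:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        parent = skbio.TreeNode(children=[a, b],
                                length=float(rng.integers(1, 10)))
        nodes = [x for x in nodes if x not in (a, b)] + [parent]
    root = skbio.TreeNode(children=nodes)
    ids = [f"t{i}" for i in range(n_taxa)]
    dm = np.zeros((n_taxa, n_taxa))
    tips = {t.name: t for t in root.tips()}
    for a, b in itertools.combinations(ids, 2):
        d = tips[a].distance(tips[b])
        dm[ids.index(a), ids.index(b)] = dm[ids.index(b), ids.index(a)] = d
    return _dm(ids, dm)


class TestNJTree:
    def test_three_taxon_closed_form(self):
        # three-point formulas: a=(AB+AC-BC)/2, etc.
        dm = _dm(["A", "B", "C"], [[0, 2, 3], [2, 0, 4], [3, 4, 0]])
        tree = nj_tree(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx(0.5)
        assert lengths["B"] == pytest.approx(1.5)
        assert lengths["C"] == pytest.approx(2.5)

    def test_four_taxon_additive_exact_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) gives these pairwise path lengths
        ids = ["A", "B", "C", "D"]
        m = [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]]
        tree = nj_tree(_dm(ids, m))
        assert np.allclose(_tip_distances(tree, ids), np.asarray(m, float))
        # the split AB|CD must be present
        splits = [frozenset(t.name for t in n.tips())
                  for n in tree.non_tips(include_self=False)]
        assert frozenset({"A", "B"}) in splits or frozenset({"C", "D"}) in splits

    @pytest.mark.parametrize("seed", range(5))
    def test_recovers_random_additive_trees(self, seed):
        rng = np.random.default_rng(seed)
        dm = _random_additive(rng, int(rng.integers(5, 9)))
        tree = nj_tree(dm)
        assert np.allclose(_tip_distances(tree, dm.ids), dm.data, atol=1e-9)

    def test_zero_matrix_gives_zero_lengths(self):
        dm = _dm(["A", "B", "C", "D"], np.zeros((4, 4)))
        tree = nj_tree(dm)
        assert all((t.length or 0) == 0 for t in tree.traverse())

    def test_undefined_entries_rejected(self):
        m = np.array([[0, 0.1, np.nan], [0.1, 0, 0.2], [np.nan, 0.2, 0]])
        with pytest.raises(ValueError, match="undefined"):
            nj_tree(DistanceMatrix(["A", "B", "C"], m, "k2p"))

    def test_branch_lengths_never_negative(self, clear_community):
        ds, _ = clear_community
        tree = nj_tree(distance_matrix(ds, "k2p"))
        assert all((n.length or 0) >= 0 for n in tree.traverse())


class TestBootstrap:
    def test_deterministic_under_seed(self, clear_community):
        ds, _ = clear_community
        a = bootstrap_support(ds, "k2p", replicates=10, seed=42)
        b = bootstrap_support(ds, "k2p", replicates=10, seed=42)
        assert a.supports == b.supports

    def test_uniform_columns_give_full_support(self):
        # homopolymer sequences make every alignment column identical, so
        # any column resample reproduces the distance matrix exactly and
        # each original bipartition appears in 100% of replicates
        ds = make_dataset(
            {"A": ["A" * 12], "B": ["C" * 12], "C": ["G" * 12],
             "D": ["T" * 12]}
        )
        st = bootstrap_support(ds, "p", replicates=5, seed=0)
        assert st.supports and all(v == 100.0 for v in st.supports.values())

    def test_separated_species_highly_supported(self):
        spec = SynthSpec(S=6, n_per_species=3, delta_intra=0.002,
                         delta_inter=0.08, sibling_pairs=(), n_singletons=0,
                         seed=0)
        ds, _ = generate_community(spec)
        st = bootstrap_support(ds, "k2p", replicates=50, seed=1)
        report = monophyly(st, ds.species_of())
        for sp, cat in report.categories.items():
            assert cat == "monophyletic"
            assert report.supports[sp] >= 95


class TestMonophyly:
    def test_clean_species_clades(self):
        ds = make_dataset(
            {"A": ["AAAA", "AAAT"], "B": ["CCCC", "CCCG"],
             "C": ["GGGG", "GGGT"]}
        )
        tree = nj_tree(distance_matrix(ds, "p"))
        cats = monophyly(tree, ds.species_of()).categories
        assert set(cats.values()) == {"monophyletic"}

    def test_interleaved_species_non_monophyletic(self):
        # B's members nest inside A's spread: neither can be isolated
        ids = ["a1", "a2", "b1", "b2"]
        m = np.array(
            [
                [0.0, 0.10, 0.02, 0.09],
                [0.10, 0.0, 0.09, 0.02],
                [0.02, 0.09, 0.0, 0.08],
                [0.09, 0.02, 0.08, 0.0],
            ]
        )
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        cats = monophyly(nj_tree(_dm(ids, m)), labels).categories
        assert cats["A"] == "non-monophyletic"
        assert cats["B"] == "non-monophyletic"

    def test_singleton_species_trivial(self):
        ds = make_dataset({"A": ["AAAA", "AAAT"], "B": ["CCCC"]})
        tree = nj_tree(distance_matrix(ds, "p"))
        cats = monophyly(tree, ds.species_of()).categories
        assert cats["B"] == "trivial"

    def test_invariant_under_rerooting(self, clear_community):
        ds, _ = clear_community
        tree = nj_tree(distance_matrix(ds, "k2p"))
        labels = ds.species_of()
        base = monophyly(tree, labels).categories
        rerooted = tree.root_at(tree.find(ds.ids[5]).parent)
        assert monophyly(rerooted, labels).categories == base


class TestNewickRoundTrip:
    def test_topology_lengths_and_supports_preserved(self, tmp_path,
                                                     clear_community):
        ds, _ = clear_community
        st = bootstrap_support(ds, "k2p", replicates=5, seed=0)
        path = tmp_path / "tree.nwk"
        write_newick(st, path)
        back = read_newick(path)
        orig_tips = {t.name: t.length for t in st.tree.tips()}
        back_tips = {t.name: t.length for t in back.tips()}
        assert orig_tips.keys() == back_tips.keys()
        for name in orig_tips:
            assert back_tips[name] == pytest.approx(orig_tips[name], abs=1e-9)
        orig_internal = sorted(
            n.name for n in st.tree.non_tips(include_self=False) if n.name
        )
        back_internal = sorted(
            n.name for n in back.non_tips(include_self=False) if n.name
        )
        assert back_internal == orig_internal
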