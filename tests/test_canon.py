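"""Canonical keys and isomorphism: validated against independent matchers."""

import time

import pytest
from hypothesis import given, settings, strategies as st

from molassembly.canon import (
    ClassRegistry,
    class_key,
    cyclic_isomorphic,
    is_acyclic,
    tree_key,
)
from molassembly.fixtures import exhaustive_small_graphs, path_graph, random_tree
from molassembly.graph import FragmentView, MolecularGraph, mask_of, parse_smiles

from conftest import nx_isomorphic, permutation_isomorphic


def full(g):
    return FragmentView(g, g.full_mask)


class TestIsAcyclic:
    def test_examples(self):
        assert is_acyclic(full(path_graph(2)))
        assert not is_acyclic(full(parse_smiles("c1ccccc1")))
        assert is_acyclic(full(random_tree(5, seed=3)))

    def test_disconnected_raises(self):
        g = MolecularGraph(("C",) * 4, ((0, 1, "single"), (2, 3, "single")))
        with pytest.raises(ValueError):
            is_acyclic(full(g))


class TestTreeKey:
    def test_relabel_invariance(self):
        k1 = tree_key(full(parse_smiles("CCO")))
        k2 = tree_key(full(parse_smiles("OCC")))
        assert k1 == k2

    def test_bond_order_matters(self):
        assert tree_key(full(parse_smiles("CCO"))) != tree_key(
            full(parse_smiles("C=CO"))
        )

    def test_path_vs_star(self):
        from molassembly.fixtures import star_graph

        assert tree_key(full(path_graph(3))) != tree_key(full(star_graph(3)))

    def test_cyclic_input_raises(self):
        with pytest.raises(ValueError):
            tree_key(full(parse_smiles("C1CC1")))

    def test_exactness_on_exhaustive_trees(self):
        """Equal tree keys <=> isomorphic, vs the permutation brute force."""
        trees = [
            g
            for g in exhaustive_small_graphs(4)
            if g.n_edges == g.n_vertices - 1
        ]
        by_key = {}
        for g in trees:
            by_key.setdefault(tree_key(full(g)).key, []).append(g)
        # generator emits one representative per class: all keys distinct
        assert all(len(v) == 1 for v in by_key.values())
        # and distinct keys really are non-isomorphic for a sample of pairs
        sample = trees[::7]
        for i, g1 in enumerate(sample):
            for g2 in sample[i + 1 : i + 4]:
                assert not permutation_isomorphic(
                    g1, g1.full_mask, g2, g2.full_mask
                )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(1, 9))
    def test_random_tree_relabel_invariance(self, seed, n):
        g = random_tree(n, atoms=("C", "N"), bonds=("single", "double"), seed=seed)
        # reverse the vertex order: a nontrivial relabeling of the same tree
        nv = g.n_vertices
        g2 = MolecularGraph(
            tuple(reversed(g.atoms)),
            tuple((nv - 1 - u, nv - 1 - v, o) for u, v, o in g.bonds),
        )
        assert tree_key(full(g)) == tree_key(full(g2))

    def test_no_quadratic_blowup_on_long_paths(self):
        g = path_graph(200, bonds=("single", "double"))
        t0 = time.perf_counter()
        tree_key(full(g))
        assert time.perf_counter() - t0 < 1.0


class TestCyclicIsomorphic:
    def test_ring_rotation(self):
        g1 = MolecularGraph(
            ("C", "N", "C", "N"),
            tuple((i, (i + 1) % 4, "single") for i in range(4)),
        )
        g2 = MolecularGraph(
            ("N", "C", "N", "C"),
            tuple((i, (i + 1) % 4, "single") for i in range(4)),
        )
        assert cyclic_isomorphic(full(g1), full(g2))

    def test_cycle_vs_path(self):
        from molassembly.fixtures import cycle_graph

        assert not cyclic_isomorphic(full(cycle_graph(6)), full(path_graph(6)))

    def test_two_ring_embeddings(self):
        g = parse_smiles("C1CC1CC1CC1")  # two cyclopropyl rings
        ring_masks = []
        for e1 in range(g.n_edges):
            for e2 in range(e1 + 1, g.n_edges):
                for e3 in range(e2 + 1, g.n_edges):
                    m = mask_of([e1, e2, e3])
                    verts = g.edge_vertices(m)
                    if len(verts) == 3:
                        ring_masks.append(m)
        assert len(ring_masks) == 2
        assert cyclic_isomorphic(
            FragmentView(g, ring_masks[0]), FragmentView(g, ring_masks[1])
        )

    def test_agrees_with_networkx_on_small_graphs(self):
        graphs = list(exhaustive_small_graphs(4))
        cyclic = [g for g in graphs if g.n_edges >= g.n_vertices]
        for i, g1 in enumerate(cyclic):
            for g2 in cyclic[i + 1 : i + 8]:
                mine = cyclic_isomorphic(full(g1), full(g2))
                ref = nx_isomorphic(g1, g1.full_mask, g2, g2.full_mask)
                assert mine == ref, (g1.bonds, g2.bonds)


class TestClassKey:
    def test_acyclic_equals_tree_key(self):
        g = parse_smiles("CCO")
        assert class_key(full(g)) == tree_key(full(g))

    def test_registry_groups_isomorphic_cyclic_fragments(self):
        g = parse_smiles("C1CC1CC1CC1")
        reg = ClassRegistry(g)
        rings = []
        for e1 in range(g.n_edges):
            for e2 in range(e1 + 1, g.n_edges):
                for e3 in range(e2 + 1, g.n_edges):
                    m = mask_of([e1, e2, e3])
                    if len(g.edge_vertices(m)) == 3:
                        rings.append(m)
        ids = {reg.classify(m) for m in rings}
        assert len(ids) == 1

    def test_co_bucket_pairs_get_distinct_ids(self):
        """Non-isomorphic graphs sharing a bucket key are split by matching."""
        graphs = list(exhaustive_small_graphs(5))
        buckets = {}
        for g in graphs:
            key = class_key(full(g))
            buckets.setdefault((key.kind, key.key), []).append(g)
        collisions = [
            v for (kind, _), v in buckets.items()
            if kind == "cyclic-bucket" and len(v) > 1
        ]
        assert collisions, "expected at least one cyclic bucket collision"
        for group in collisions[:5]:
            for i, g1 in enumerate(group):
                for g2 in group[i + 1 :]:
                    # generator yields one per class: these must be distinct
                    assert not cyclic_isomorphic(full(g1), full(g2))
                    assert not nx_isomorphic(
                        g1, g1.full_mask, g2, g2.full_mask
                    )

    def test_class_identity_matches_networkx_partition(self):
        """Class ids induce the same partition as reference isomorphism on
        all connected labeled graphs with <= 4 edges: the generator yields
        one representative per class, so no two may be isomorphic."""
        by_inv = {}
        for g in exhaustive_small_graphs(4):
            inv = (
                g.n_edges,
                g.n_vertices,
                tuple(sorted(g.atoms)),
                tuple(sorted(g.bond_labels)),
            )
            by_inv.setdefault(inv, []).append(g)
        for group in by_inv.values():
            for i, g1 in enumerate(group):
                for g2 in group[i + 1 :]:
                    assert not nx_isomorphic(
                        g1, g1.full_mask, g2, g2.full_mask
                    ), (g1.bonds, g2.bonds)
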