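"""Assembly-state search: fragmentation, DP, pruning and pathways."""

import math

import pytest

from molassembly.bounds import addition_chain_length
from molassembly.duplicates import enumerate_duplicates
from molassembly.fixtures import cycle_graph, path_graph
from molassembly.graph import (
    connected_components,
    mask_of,
    parse_smiles,
    remove_unique_bonds,
)
from molassembly.search import (
    AssemblyState,
    SearchConfig,
    apply_removal,
    compute_ma,
    disjoint_set_split,
    hash_state,
    search,
)

NO_PATHWAY = SearchConfig(track_pathway=False)


class TestDisjointSetSplit:
    def test_path_minus_middle(self):
        g = path_graph(4)
        assert disjoint_set_split(g, mask_of([0, 3])) == [
            mask_of([0]),
            mask_of([3]),
        ]

    def test_connected_remnant_is_identity(self):
        g = path_graph(5)
        m = mask_of([1, 2, 3])
        assert disjoint_set_split(g, m) == [m]

    def test_ring_minus_arc_is_arc(self, benzoic):
        ring = remove_unique_bonds(benzoic)
        table = enumerate_duplicates(benzoic, ring)
        arc3 = [c for c in table.classes if c.size == 3][0]
        occ = arc3.occurrences[0]
        remnant = disjoint_set_split(benzoic, ring & ~occ)
        assert len(remnant) == 1
        assert remnant[0].bit_count() == 3


class TestApplyRemoval:
    def test_path_4_removal(self):
        g = path_graph(4)
        table = enumerate_duplicates(g, remove_unique_bonds(g))
        cls = table.classes[0]
        state = AssemblyState((g.full_mask,), 0, 0)
        child, step = apply_removal(g, state, cls, (mask_of([0, 1]), mask_of([2, 3])))
        # both occurrences leave; one copy of the duplicate remains
        assert child.fragments == (mask_of([0, 1]),)
        assert child.S == 1
        assert step.k == 2
        assert g.n_edges - 1 - child.S == 2 == addition_chain_length(4)

    def test_benzoic_first_step(self, benzoic):
        table = enumerate_duplicates(benzoic, remove_unique_bonds(benzoic))
        arc3 = [c for c in table.classes if c.size == 3][0]
        state = AssemblyState((benzoic.full_mask,), 0, 0)
        pair = next(
            (a, b)
            for i, a in enumerate(arc3.occurrences)
            for b in arc3.occurrences[i + 1 :]
            if a & b == 0
        )
        child, step = apply_removal(benzoic, state, arc3, pair)
        assert child.S == 2
        assert step.k == 3

    def test_cross_fragment_removal(self):
        g = parse_smiles("CCC.CCC")
        comps = connected_components(g, g.full_mask)
        table = enumerate_duplicates(g, remove_unique_bonds(g))
        whole = [c for c in table.classes if c.size == 2][0]
        a, b = comps
        state = AssemblyState(tuple(comps), 0, 0)
        child, _ = apply_removal(g, state, whole, (a, b))
        assert child.fragments == (min(a, b),)
        assert child.S == 1

    def test_invalid_pair_raises(self):
        g = path_graph(4)
        table = enumerate_duplicates(g, remove_unique_bonds(g))
        state = AssemblyState((mask_of([0, 1]),), 0, 0)
        with pytest.raises(ValueError):
            apply_removal(
                g, state, table.classes[0], (mask_of([0, 1]), mask_of([2, 3]))
            )


class TestHashState:
    def test_equal_states_equal_keys(self):
        s1 = AssemblyState((3, 12), 1, 2)
        s2 = AssemblyState((3, 12), 1, 2)
        assert hash_state(s1) == hash_state(s2)

    def test_rank_is_semantic(self):
        assert hash_state(AssemblyState((3, 12), 1, 2)) != hash_state(
            AssemblyState((3, 12), 1, 3)
        )

    def test_fragment_order_is_normalised_by_caller(self):
        # fragments are stored sorted; same multiset => same key
        assert hash_state(AssemblyState(tuple(sorted([12, 3])), 1, 2)) == hash_state(
            AssemblyState(tuple(sorted([3, 12])), 1, 2)
        )


class TestSearch:
    def test_benzoic_acid(self, benzoic):
        res = search(benzoic)
        assert res.ma == 6
        assert res.converged
        assert res.best_s == 2

    def test_single_edge_molecule(self):
        assert compute_ma(parse_smiles("CC")) == 0

    def test_isolated_atom(self):
        assert compute_ma(parse_smiles("C")) == 0

    def test_triangle(self):
        assert compute_ma(cycle_graph(3)) == 2

    def test_no_duplicates_means_n_minus_one(self):
        g = parse_smiles("OC#N")
        res = search(g)
        assert res.ma == g.n_edges - 1
        assert res.pathway == []

    @pytest.mark.parametrize("n", range(2, 21))
    def test_uniform_chain_equals_addition_chain(self, n):
        assert compute_ma(path_graph(n)) == addition_chain_length(n)

    def test_bounds_sandwich_on_connected_fixtures(self, small_fixture_graphs):
        for g in small_fixture_graphs:
            if len(connected_components(g, g.full_mask)) != 1:
                continue
            ma = search(g, NO_PATHWAY).ma
            assert math.ceil(math.log2(g.n_edges)) <= ma <= g.n_edges - 1

    def test_input_order_invariance(self, benzoic):
        from molassembly.graph import MolecularGraph

        perm = [8, 3, 5, 0, 7, 2, 6, 1, 4]
        inv = {p: i for i, p in enumerate(perm)}
        g2 = MolecularGraph(
            tuple(benzoic.atoms[perm[i]] for i in range(9)),
            tuple(
                (inv[u], inv[v], o)
                for u, v, o in reversed(benzoic.bonds)
            ),
        )
        assert compute_ma(g2) == compute_ma(benzoic)

    def test_budget_rejects_nonpositive(self, benzoic):
        with pytest.raises(ValueError):
            search(benzoic, SearchConfig(max_seconds=0))
        with pytest.raises(ValueError):
            search(benzoic, SearchConfig(max_states=0))

    def test_state_budget_gives_anytime_result(self):
        from molassembly.jointspace import join_graphs
        from molassembly.peptides import peptide_graph

        g = join_graphs([peptide_graph("STV"), peptide_graph("SVT")])
        res = search(g, SearchConfig(max_states=50, track_pathway=False))
        assert not res.converged
        assert res.ma >= 13  # the exact value; anytime gives an upper bound
        ubs = [ub for _, ub in res.trace]
        assert ubs == sorted(ubs, reverse=True)


class TestPruningSafety:
    """Disabling the bound and the state table never changes the MA."""

    def test_heuristics_are_lossless(self, small_fixture_graphs):
        for g in small_fixture_graphs:
            reference = search(g, NO_PATHWAY)
            plain = search(
                g,
                SearchConfig(
                    use_bound=False, use_state_table=False, track_pathway=False
                ),
            )
            no_bound = search(
                g, SearchConfig(use_bound=False, track_pathway=False)
            )
            no_table = search(
                g, SearchConfig(use_state_table=False, track_pathway=False)
            )
            assert (
                reference.ma == plain.ma == no_bound.ma == no_table.ma
            ), g.bonds
            # pruning only reduces work
            assert reference.stats["expanded"] <= plain.stats["expanded"]

    def test_split_bound_refinement_is_lossless(self, small_fixture_graphs):
        for g in small_fixture_graphs:
            assert (
                search(g, SearchConfig(use_split_bound=True, track_pathway=False)).ma
                == search(g, NO_PATHWAY).ma
            )


class TestPathway:
    def replay(self, g, result):
        state = tuple(
            sorted(
                m
                for m in connected_components(g, g.full_mask)
                if m.bit_count() >= 2
            )
        )
        total = 0
        for step in result.pathway:
            a, b = step.pair
            fa = next(f for f in state if a & f == a)
            fb = next(f for f in state if b & f == b)
            rest = [f for f in state if f != fa and f != fb]
            if fa == fb:
                remn = disjoint_set_split(g, fa & ~(a | b))
            else:
                remn = disjoint_set_split(g, fa & ~a) + disjoint_set_split(
                    g, fb & ~b
                )
            state = tuple(
                sorted(
                    rest
                    + [r for r in remn if r.bit_count() >= 2]
                    + [min(a, b)]
                )
            )
            total += step.k - 1
        return state, total

    def test_replay_reproduces_best_s(self, benzoic, small_fixture_graphs):
        for g in [benzoic, *small_fixture_graphs]:
            res = search(g)
            _, total = self.replay(g, res)
            assert total == res.best_s
            assert res.ma == g.n_edges - res.n_components - res.best_s

    def test_path_4_single_step(self):
        res = search(path_graph(4))
        assert len(res.pathway) == 1
        assert res.pathway[0].k == 2
        assert res.best_s == 1

    def test_steps_are_disjoint_from_remnants(self, benzoic):
        res = search(benzoic)
        for step in res.pathway:
            for r in step.remnants:
                assert step.duplicate & r == 0


class TestAnytimeTrace:
    def test_trace_monotone_and_terminal_exact(self, small_fixture_graphs):
        for g in small_fixture_graphs:
            res = search(g, NO_PATHWAY)
            ubs = [ub for _, ub in res.trace]
            assert ubs == sorted(ubs, reverse=True)
            assert res.converged
            assert ubs[-1] == res.ma

    def test_times_nondecreasing(self, benzoic):
        res = search(benzoic)
        times = [t for t, _ in res.trace]
        assert times == sorted(times)
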