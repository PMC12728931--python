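"""Shared fixtures and independent reference implementations.

The references here deliberately use different machinery from the package:
networkx's VF2 matcher and a plain permutation brute force stand in as
isomorphism ground truth, so the package's tree canonization and its own
backtracking matcher are validated against genuinely independent code.
"""

from __future__ import annotations

import itertools

import pytest

from molassembly.graph import MolecularGraph, mask_edges, parse_smiles


def nx_fragment(g: MolecularGraph, mask: int):
    import networkx as nx

    G = nx.Graph()
    for e in mask_edges(mask):
        u, v, order = g.bonds[e]
        G.add_node(u, el=g.atoms[u])
        G.add_node(v, el=g.atoms[v])
        G.add_edge(u, v, bo=order)
    return G


def nx_isomorphic(g1: MolecularGraph, m1: int, g2: MolecularGraph, m2: int) -> bool:
    """Reference isomorphism via networkx VF2."""
    from networkx.algorithms import isomorphism as iso

    gm = iso.GraphMatcher(
        nx_fragment(g1, m1),
        nx_fragment(g2, m2),
        node_match=lambda a, b: a["el"] == b["el"],
        edge_match=lambda a, b: a["bo"] == b["bo"],
    )
    return gm.is_isomorphic()


def permutation_isomorphic(
    g1: MolecularGraph, m1: int, g2: MolecularGraph, m2: int
) -> bool:
    """Reference isomorphism by trying every vertex bijection."""
    verts1 = sorted(g1.edge_vertices(m1))
    verts2 = sorted(g2.edge_vertices(m2))
    if len(verts1) != len(verts2) or m1.bit_count() != m2.bit_count():
        return False

    def edge_set(g, mask, relabel):
        out = set()
        for e in mask_edges(mask):
            u, v, order = g.bonds[e]
            a, b = relabel[u], relabel[v]
            out.add((min(a, b), max(a, b), order))
        return out

    base = {v: i for i, v in enumerate(verts1)}
    target_atoms = [g1.atoms[v] for v in verts1]
    edges1 = edge_set(g1, m1, base)
    for perm in itertools.permutations(range(len(verts2))):
        relabel = {v: perm[i] for i, v in enumerate(verts2)}
        if any(
            g2.atoms[v] != target_atoms[relabel[v]] for v in verts2
        ):
            continue
        if edge_set(g2, m2, relabel) == edges1:
            return True
    return False


def capped_oracle_best_s(g: MolecularGraph, cap: int, fragments=None) -> int:
    """Exhaustive best duplicate sum when removals are capped at *cap* bonds.

    Reference for bound admissibility: recursion over every valid removal of
    size <= cap, no ordering, no pruning.  Starts from an arbitrary state
    (default: the connected components of *g*).
    """
    from molassembly.graph import connected_components
    from molassembly.oracle import _occurrence_classes

    classes = [
        grp for grp in _occurrence_classes(g) if grp[0].bit_count() <= cap
    ]
    if fragments is None:
        fragments = tuple(
            m
            for m in connected_components(g, g.full_mask)
            if m.bit_count() >= 2
        )

    def best(frags):
        best_s = 0
        union = 0
        for f in frags:
            union |= f
        for occs in classes:
            contained = [
                o
                for o in occs
                if o & union == o and any(o & f == o for f in frags)
            ]
            if len(contained) < 2:
                continue
            k = contained[0].bit_count()
            for i, a in enumerate(contained):
                fa = next(f for f in frags if a & f == a)
                for b in contained[i + 1 :]:
                    if a & b:
                        continue
                    fb = next(f for f in frags if b & f == b)
                    rest = [f for f in frags if f != fa and f != fb]
                    if fa == fb:
                        remn = connected_components(g, fa & ~(a | b))
                    else:
                        remn = connected_components(
                            g, fa & ~a
                        ) + connected_components(g, fb & ~b)
                    child = tuple(
                        rest + [r for r in remn if r.bit_count() >= 2] + [a]
                    )
                    s = (k - 1) + best(child)
                    if s > best_s:
                        best_s = s
        return best_s

    return best(tuple(fragments))


@pytest.fixture(scope="session")
def benzoic():
    return parse_smiles("OC(=O)c1ccccc1")


@pytest.fixture(scope="session")
def small_fixture_graphs():
    """A deterministic spread of small molecules used by several suites."""
    from molassembly.fixtures import cycle_graph, path_graph, random_tree, star_graph

    graphs = [
        parse_smiles("OC(=O)c1ccccc1"),   # benzoic acid
        parse_smiles("CC(C)C"),           # isobutane star
        parse_smiles("CCOCC"),            # diethyl ether: symmetric arms
        parse_smiles("C1CC1CC1CC1"),      # two cyclopropyl rings
        parse_smiles("CC(=O)OC(=O)C"),    # acetic anhydride
        path_graph(8),
        path_graph(10, bonds=("single", "double")),
        cycle_graph(6),
        star_graph(5),
        random_tree(7, atoms=("C", "N"), bonds=("single", "double"), seed=7),
        random_tree(9, atoms=("C", "O"), bonds=("single",), seed=11),
    ]
    return graphs
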