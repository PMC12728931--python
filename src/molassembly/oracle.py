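"""Brute-force assembly-index oracle for small graphs.

Reference implementation used only to validate the optimized search: a
plain exhaustive recursion over duplicate removals with no size ordering,
no addition-chain bound and no state table — correctness comes from
exhaustion alone.  Candidate occurrences (all connected edge subsets with
at least two edges, restricted to bonds whose label is not unique, since a
uniquely-labeled bond can never sit in two label-preserving isomorphic
copies) are enumerated once up front and grouped with the oracle's own
label-aware permutation backtracking — independent of the tree
canonization / VF2 machinery the optimized path uses.

Intentionally exponential; refuses graphs beyond a small edge cap.
"""

from __future__ import annotations

from .graph import MolecularGraph, connected_components, mask_edges

__all__ = ["oracle_ma", "oracle_best_s"]

_DEFAULT_CAP = 12


def _subset_profile(g: MolecularGraph, sub: int):
    """Precomputed matching data for one edge subset: adjacency, per-vertex
    invariant signatures, their sorted multiset, and a matching order."""
    adj: dict[int, list[tuple[int, str]]] = {}
    for e in mask_edges(sub):
        u, v, _ = g.bonds[e]
        lbl = g.bond_labels[e][2]
        adj.setdefault(u, []).append((v, lbl))
        adj.setdefault(v, []).append((u, lbl))
    sigs = {
        v: (g.atoms[v], tuple(sorted(l for _, l in nbrs)))
        for v, nbrs in adj.items()
    }
    order = sorted(adj, key=lambda v: (-len(adj[v]), sigs[v]))
    return adj, sigs, sorted(sigs.values()), order


def _labeled_iso(profile_a, profile_b) -> bool:
    """Label-preserving isomorphism of two edge-subset fragments, by naive
    backtracking over vertex bijections."""
    adj_a, sig_a, multiset_a, verts_a = profile_a
    adj_b, sig_b, multiset_b, _ = profile_b
    if len(adj_a) != len(adj_b) or multiset_a != multiset_b:
        return False

    mapping: dict[int, int] = {}
    used: set[int] = set()

    def compatible(va: int, vb: int) -> bool:
        if sig_a[va] != sig_b[vb]:
            return False
        for wa, lbl in adj_a[va]:
            if wa in mapping:
                wb = mapping[wa]
                if not any(x == wb and l == lbl for x, l in adj_b[vb]):
                    return False
        return True

    def extend(i: int) -> bool:
        if i == len(verts_a):
            return True
        va = verts_a[i]
        for vb in adj_b:
            if vb in used:
                continue
            if compatible(va, vb):
                mapping[va] = vb
                used.add(vb)
                if extend(i + 1):
                    return True
                del mapping[va]
                used.discard(vb)
        return False

    return extend(0)


def _connected_subset_masks(g: MolecularGraph, within: int) -> list[int]:
    """All connected edge subsets (>= 2 edges) of the mask *within*."""
    edge_adj = g.edge_adjacency
    out: list[int] = []
    level = {1 << e for e in mask_edges(within)}
    while level:
        nxt: set[int] = set()
        for sub in level:
            boundary = 0
            for e in mask_edges(sub):
                boundary |= edge_adj[e]
            boundary &= within & ~sub
            for e in mask_edges(boundary):
                nxt.add(sub | (1 << e))
        out.extend(s for s in nxt if s.bit_count() >= 2)
        level = nxt
    return out


def _occurrence_classes(g: MolecularGraph) -> list[list[int]]:
    """Connected subsets grouped into isomorphism classes (>= 2 members)."""
    label_counts: dict[tuple, int] = {}
    for lbl in g.bond_labels:
        label_counts[lbl] = label_counts.get(lbl, 0) + 1
    within = 0
    for e, lbl in enumerate(g.bond_labels):
        if label_counts[lbl] >= 2:
            within |= 1 << e
    subs = _connected_subset_masks(g, within)

    # Bucket by the bond-label multiset first: a subset alone in its bucket
    # has no isomorphic partner and needs no matching at all.  Buckets with
    # several members are resolved by explicit matching.
    buckets: dict[tuple, list[int]] = {}
    for sub in subs:
        labels = tuple(sorted(g.bond_labels[e] for e in mask_edges(sub)))
        buckets.setdefault((sub.bit_count(), labels), []).append(sub)
    by_sig: dict[tuple, list[list[int]]] = {}
    profiles: dict[int, tuple] = {}
    for key, members in buckets.items():
        if len(members) < 2:
            continue
        groups = by_sig.setdefault(key, [])
        for sub in members:
            profiles[sub] = _subset_profile(g, sub)
            for grp in groups:
                if _labeled_iso(profiles[grp[0]], profiles[sub]):
                    grp.append(sub)
                    break
            else:
                groups.append([sub])
    return [
        grp
        for groups in by_sig.values()
        for grp in groups
        if len(grp) >= 2
    ]


def _split_mask(g: MolecularGraph, mask: int) -> list[int]:
    return connected_components(g, mask)


def oracle_best_s(g: MolecularGraph, max_edges: int = _DEFAULT_CAP) -> int:
    """Max duplicate sum via exhaustive removal recursion."""
    if g.n_edges > max_edges:
        raise ValueError(
            f"oracle refuses graphs with more than {max_edges} edges"
        )
    init = tuple(
        m
        for m in connected_components(g, g.full_mask)
        if m.bit_count() >= 2
    )
    classes = _occurrence_classes(g)
    if not classes:
        return 0

    def best(fragments: tuple[int, ...]) -> int:
        best_s = 0
        union = 0
        for f in fragments:
            union |= f
        for occs in classes:
            contained = [
                o
                for o in occs
                if o & union == o and any(o & f == o for f in fragments)
            ]
            if len(contained) < 2:
                continue
            k = contained[0].bit_count()
            for i, a in enumerate(contained):
                fa = next(f for f in fragments if a & f == a)
                for b in contained[i + 1 :]:
                    if a & b:
                        continue
                    fb = next(f for f in fragments if b & f == b)
                    rest = [f for f in fragments if f != fa and f != fb]
                    if fa == fb:
                        remn = _split_mask(g, fa & ~(a | b))
                    else:
                        remn = _split_mask(g, fa & ~a) + _split_mask(g, fb & ~b)
                    child = tuple(
                        rest + [r for r in remn if r.bit_count() >= 2] + [a]
                    )
                    s = (k - 1) + best(child)
                    if s > best_s:
                        best_s = s
        return best_s

    return best(init)


def oracle_ma(g: MolecularGraph, max_edges: int = _DEFAULT_CAP) -> int:
    """Exact assembly index by exhaustive search; independent of the
    optimized search's ordering, bound and state table."""
    n_comp = len(connected_components(g, g.full_mask))
    return g.n_edges - n_comp - oracle_best_s(g, max_edges=max_edges)
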