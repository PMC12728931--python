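"""Isomorphism testing and canonical keys for connected fragments.

Acyclic fragments (the overwhelming majority in organic molecules) get an
exact linear-time canonical string: an AHU encoding rooted at the tree
center, with atom labels on vertices and bond orders on the child edges.
Cyclic fragments get a cheap invariant *bucket* key (label multisets, degree
sequence, cycle rank); equal bucket keys are necessary but not sufficient for
isomorphism, and class identity inside a bucket is resolved by an explicit
VF2 match (networkx).
"""

from __future__ import annotations

from dataclasses import dataclass

from .graph import FragmentView, MolecularGraph, mask_edges

__all__ = [
    "FragmentKey",
    "is_acyclic",
    "tree_key",
    "cyclic_isomorphic",
    "class_key",
    "ClassRegistry",
]


@dataclass(frozen=True)
class FragmentKey:
    """Canonical key of a fragment.

    ``kind == "tree-canonical"`` keys are exact: equal iff isomorphic.
    ``kind == "cyclic-bucket"`` keys are an invariant filter only.
    """

    kind: str
    key: str


def _fragment_adjacency(
    g: MolecularGraph, mask: int
) -> dict[int, list[tuple[int, str]]]:
    """Adjacency of the subgraph induced by *mask*: v -> [(nbr, bond order)]."""
    adj: dict[int, list[tuple[int, str]]] = {}
    bonds = g.bonds
    while mask:
        low = mask & -mask
        mask ^= low
        u, v, order = bonds[low.bit_length() - 1]
        a = adj.get(u)
        if a is None:
            adj[u] = [(v, order)]
        else:
            a.append((v, order))
        a = adj.get(v)
        if a is None:
            adj[v] = [(u, order)]
        else:
            a.append((u, order))
    return adj


def _is_connected_adj(adj: dict[int, list[tuple[int, str]]]) -> bool:
    if not adj:
        return True
    start = next(iter(adj))
    seen = {start}
    stack = [start]
    while stack:
        v = stack.pop()
        for w, _ in adj[v]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return len(seen) == len(adj)


def is_acyclic(f: FragmentView, *, assume_connected: bool = False) -> bool:
    """True iff the connected fragment is a tree (edge count = vertices - 1)."""
    adj = _fragment_adjacency(f.graph, f.mask)
    if not assume_connected and not _is_connected_adj(adj):
        raise ValueError("fragment is disconnected")
    return f.size == len(adj) - 1 if adj else True


def _tree_centers(adj: dict[int, list[tuple[int, str]]]) -> list[int]:
    """Center vertex (or two centers) of a tree, by leaf peeling."""
    if len(adj) == 1:
        return list(adj)
    degree = {v: len(nbrs) for v, nbrs in adj.items()}
    layer = [v for v, d in degree.items() if d == 1]
    remaining = len(adj)
    while remaining > 2:
        remaining -= len(layer)
        nxt = []
        for v in layer:
            degree[v] = 0
            for w, _ in adj[v]:
                if degree[w] > 1:
                    degree[w] -= 1
                    if degree[w] == 1:
                        nxt.append(w)
        layer = nxt
    return sorted(v for v, d in degree.items() if d > 0)


def _tree_key_from_adj(
    g: MolecularGraph, adj: dict[int, list[tuple[int, str]]]
) -> str:
    def encode(v: int, parent: int) -> str:
        parts = sorted(
            order + encode(w, v) for w, order in adj[v] if w != parent
        )
        label = g.atoms[v]
        if parts:
            return label + "(" + ",".join(parts) + ")"
        return label

    return min(encode(c, -1) for c in _tree_centers(adj))


def tree_key(f: FragmentView) -> FragmentKey:
    """Exact canonical key for an acyclic connected fragment.

    Two acyclic fragments get equal keys iff they are isomorphic as labeled
    graphs.  For a bicentral tree the lexicographically smaller of the two
    center-rooted encodings is taken.
    """
    adj = _fragment_adjacency(f.graph, f.mask)
    if not _is_connected_adj(adj):
        raise ValueError("fragment is disconnected")
    if adj and f.size != len(adj) - 1:
        raise ValueError("fragment is cyclic; tree_key requires a tree")
    return FragmentKey("tree-canonical", _tree_key_from_adj(f.graph, adj))


def _bucket_key(g: MolecularGraph, mask: int, adj=None) -> str:
    if adj is None:
        adj = _fragment_adjacency(g, mask)
    n_edges = mask.bit_count()
    cycle_rank = n_edges - len(adj) + 1
    vdeg = sorted(f"{g.atoms[v]}:{len(nbrs)}" for v, nbrs in adj.items())
    elab = sorted(
        "".join(g.bond_labels[e]) for e in mask_edges(mask)
    )
    return f"cyc|{n_edges}|{cycle_rank}|{','.join(vdeg)}|{','.join(elab)}"


def _vertex_signatures(
    g: MolecularGraph, adj: dict[int, list[tuple[int, str]]]
) -> dict[int, tuple]:
    return {
        v: (g.atoms[v], len(nbrs), tuple(sorted(o for _, o in nbrs)))
        for v, nbrs in adj.items()
    }


def cyclic_isomorphic(f1: FragmentView, f2: FragmentView) -> bool:
    """Label-preserving graph isomorphism between two connected fragments.

    VF2-style backtracking over vertex bijections, pruned by per-vertex
    invariants (atom label, degree, incident bond orders) and extended along
    a connected order so partial maps fail fast.  Works for acyclic
    fragments too, but those are better served by :func:`tree_key`.
    """
    if f1.size != f2.size:
        return False
    g1, g2 = f1.graph, f2.graph
    adj1 = _fragment_adjacency(g1, f1.mask)
    adj2 = _fragment_adjacency(g2, f2.mask)
    if len(adj1) != len(adj2):
        return False
    sig1 = _vertex_signatures(g1, adj1)
    sig2 = _vertex_signatures(g2, adj2)
    if sorted(sig1.values()) != sorted(sig2.values()):
        return False

    # Connected matching order: each new vertex (after the first) touches an
    # already-mapped one, so edge constraints bite immediately.
    order: list[int] = []
    placed: set[int] = set()
    start = min(adj1, key=lambda v: (sig1[v], v))
    stack = [start]
    while stack:
        v = stack.pop()
        if v in placed:
            continue
        placed.add(v)
        order.append(v)
        for w, _ in sorted(adj1[v]):
            if w not in placed:
                stack.append(w)

    mapping: dict[int, int] = {}
    used: set[int] = set()

    def feasible(va: int, vb: int) -> bool:
        if sig1[va] != sig2[vb]:
            return False
        nbrs_b = adj2[vb]
        for wa, bond in adj1[va]:
            wb = mapping.get(wa)
            if wb is not None and not any(
                x == wb and o == bond for x, o in nbrs_b
            ):
                return False
        return True

    def extend(i: int) -> bool:
        if i == len(order):
            return True
        va = order[i]
        for vb in adj2:
            if vb not in used and feasible(va, vb):
                mapping[va] = vb
                used.add(vb)
                if extend(i + 1):
                    return True
                del mapping[va]
                used.remove(vb)
        return False

    return extend(0)


def class_key(f: FragmentView) -> FragmentKey:
    """Key used to group fragments into isomorphism classes.

    Acyclic fragments: the exact tree key.  Cyclic fragments: the invariant
    bucket key; final class identity inside a bucket must be resolved with
    :func:`cyclic_isomorphic` (see :class:`ClassRegistry`).
    """
    adj = _fragment_adjacency(f.graph, f.mask)
    if not _is_connected_adj(adj):
        raise ValueError("fragment is disconnected")
    n_edges = f.size
    if not adj or n_edges == len(adj) - 1:
        return FragmentKey("tree-canonical", _tree_key_from_adj(f.graph, adj))
    return FragmentKey("cyclic-bucket", _bucket_key(f.graph, f.mask))


class ClassRegistry:
    """Assigns stable integer class ids to fragments of one graph.

    Equal ids <=> isomorphic fragments.  Tree keys resolve directly; cyclic
    buckets keep representative masks and fall back to explicit VF2 matches,
    so bucket collisions are harmless.
    """

    def __init__(self, graph: MolecularGraph):
        self.graph = graph
        self._tree_ids: dict[str, int] = {}
        self._buckets: dict[str, list[tuple[int, int]]] = {}
        self._keys: list[FragmentKey] = []

    def __len__(self) -> int:
        return len(self._keys)

    def key_of(self, class_id: int) -> FragmentKey:
        return self._keys[class_id]

    def classify(self, mask: int, *, assume_connected: bool = False) -> int:
        """Class id of the connected fragment *mask*.

        ``assume_connected`` skips the connectivity check for callers (like
        the duplicate enumerator) whose masks are connected by construction.
        """
        g = self.graph
        if assume_connected:
            adj = _fragment_adjacency(g, mask)
            if mask.bit_count() == len(adj) - 1:
                key = FragmentKey(
                    "tree-canonical", _tree_key_from_adj(g, adj)
                )
            else:
                key = FragmentKey("cyclic-bucket", _bucket_key(g, mask, adj))
        else:
            key = class_key(FragmentView(g, mask))
        if key.kind == "tree-canonical":
            cid = self._tree_ids.get(key.key)
            if cid is None:
                cid = len(self._keys)
                self._tree_ids[key.key] = cid
                self._keys.append(key)
            return cid
        bucket = self._buckets.setdefault(key.key, [])
        mine = FragmentView(self.graph, mask)
        for rep_mask, cid in bucket:
            if cyclic_isomorphic(FragmentView(self.graph, rep_mask), mine):
                return cid
        cid = len(self._keys)
        bucket.append((mask, cid))
        self._keys.append(key)
        return cid
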