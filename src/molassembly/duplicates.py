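"""Enumeration of duplicatable subgraph classes and their growth DAG.

A *duplicatable subgraph* is a connected subgraph with at least two
edge-disjoint isomorphic occurrences.  Enumeration runs once, breadth-wise:
all connected 2-edge subgraphs of the retained (non-unique-label) bonds form
level 2; each subsequent level grows every occurrence by one adjacent edge.
Occurrences are grouped into isomorphism classes; only classes with >= 2
occurrences are grown further, since a class with a single occurrence can
never seed a duplicate.  Classes with >= 2 occurrences but no edge-disjoint
pair are kept in the DAG (they are grown, matching the breadth-wise sweep)
but flagged non-matchable and never offered to the search.

The search re-uses this one-time enumeration for every assembly state:
occurrence masks are simply filtered against the state's current fragments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

from .canon import ClassRegistry, FragmentKey
from .graph import MolecularGraph, mask_edges

__all__ = [
    "DuplicateClass",
    "DuplicateDAG",
    "DuplicateTable",
    "enumerate_duplicates",
    "valid_pairs",
    "available_duplicates",
]


@dataclass
class DuplicateClass:
    """One isomorphism class of connected subgraphs with >= 2 occurrences."""

    id: int
    size: int
    key: FragmentKey
    occurrences: list[int]
    matchable: bool = False
    rank: int = -1  # position in the global (size desc, key asc) order

    def has_disjoint_pair(self) -> bool:
        occ = self.occurrences
        for i, a in enumerate(occ):
            for b in occ[i + 1 :]:
                if a & b == 0:
                    return True
        return False


@dataclass
class DuplicateDAG:
    """Growth DAG: parent -> children that have exactly one more edge.

    Each non-root class stores only the first parent encountered.
    """

    parent: dict[int, int] = field(default_factory=dict)
    children: dict[int, list[int]] = field(default_factory=dict)

    def add_edge(self, parent_id: int, child_id: int) -> None:
        if child_id not in self.parent:
            self.parent[child_id] = parent_id
            self.children.setdefault(parent_id, []).append(child_id)


@dataclass
class DuplicateTable:
    """Result of :func:`enumerate_duplicates`.

    ``classes`` holds the matchable classes sorted by (size descending, key
    ascending); ``rank`` on each class is its position in that order, so the
    search's monotone-order rule "never remove a larger class after a
    smaller one" is simply ``rank >= last_rank``.
    """

    graph: MolecularGraph
    classes: list[DuplicateClass]
    all_classes: list[DuplicateClass]
    dag: DuplicateDAG
    cover_mask: int

    @property
    def max_size(self) -> int:
        return self.classes[0].size if self.classes else 0


def enumerate_duplicates(g: MolecularGraph, retained: int) -> DuplicateTable:
    """Enumerate every duplicatable subgraph class of the retained bonds."""
    registry = ClassRegistry(g)
    edge_adj = g.edge_adjacency

    by_class: dict[int, DuplicateClass] = {}
    dag = DuplicateDAG()
    seen_masks: set[int] = set()

    bond_labels = g.bond_labels
    label_ids: dict[tuple, int] = {}
    edge_label_id = []
    for lbl in bond_labels:
        edge_label_id.append(label_ids.setdefault(lbl, len(label_ids)))

    def cheap_sig(mask: int) -> tuple:
        ids = []
        while mask:
            low = mask & -mask
            mask ^= low
            ids.append(edge_label_id[low.bit_length() - 1])
        ids.sort()
        return tuple(ids)

    def classify_level(masks: Iterator[tuple[int, int]]) -> list[DuplicateClass]:
        """Group (mask, parent_class_id) pairs into classes; keep >=2-occ ones."""
        # First pass: bucket by the bond-label multiset.  A mask alone in its
        # bucket has no isomorphic partner at this level, so it can never
        # seed a duplicate class and needs no canonical key at all.
        fresh: list[tuple[int, int, tuple]] = []
        sig_count: dict[tuple, int] = {}
        for mask, parent_cid in masks:
            if mask in seen_masks:
                continue
            seen_masks.add(mask)
            sig = cheap_sig(mask)
            sig_count[sig] = sig_count.get(sig, 0) + 1
            fresh.append((mask, parent_cid, sig))
        level: dict[int, DuplicateClass] = {}
        pending_parent: dict[int, int] = {}
        for mask, parent_cid, sig in fresh:
            if sig_count[sig] < 2:
                continue
            cid = registry.classify(mask, assume_connected=True)
            cls = level.get(cid)
            if cls is None:
                cls = DuplicateClass(
                    id=cid,
                    size=mask.bit_count(),
                    key=registry.key_of(cid),
                    occurrences=[],
                )
                level[cid] = cls
                if parent_cid >= 0:
                    pending_parent[cid] = parent_cid
            cls.occurrences.append(mask)
        kept = []
        for cid, cls in level.items():
            if len(cls.occurrences) >= 2:
                cls.occurrences.sort()
                cls.matchable = cls.has_disjoint_pair()
                by_class[cid] = cls
                if cid in pending_parent:
                    dag.add_edge(pending_parent[cid], cid)
                kept.append(cls)
        return kept

    # Level 2: adjacent retained-edge pairs.
    def seeds() -> Iterator[tuple[int, int]]:
        for e in mask_edges(retained):
            bit = 1 << e
            nbrs = edge_adj[e] & retained
            for f in mask_edges(nbrs):
                if f > e:
                    yield bit | (1 << f), -1

    frontier = classify_level(seeds())

    while frontier:
        def grown() -> Iterator[tuple[int, int]]:
            for cls in frontier:
                for occ in cls.occurrences:
                    boundary = 0
                    for e in mask_edges(occ):
                        boundary |= edge_adj[e]
                    boundary &= retained & ~occ
                    for e in mask_edges(boundary):
                        yield occ | (1 << e), cls.id

        frontier = classify_level(grown())

    all_classes = sorted(by_class.values(), key=lambda c: (-c.size, c.key.key, c.id))
    matchable = [c for c in all_classes if c.matchable]
    for rank, cls in enumerate(matchable):
        cls.rank = rank

    cover = 0
    for cls in all_classes:
        for occ in cls.occurrences:
            cover |= occ
    return DuplicateTable(g, matchable, all_classes, dag, cover)


def valid_pairs(
    cls: DuplicateClass, fragments: Sequence[int]
) -> list[tuple[int, int]]:
    """Edge-disjoint occurrence pairs of *cls* valid in the given state.

    Each occurrence must lie entirely inside one current fragment (the two
    occurrences may sit in different fragments, which is what lets joint
    assembly spaces share structure across molecules).  Pairs are normalised
    ``a < b`` by mask comparison.
    """
    union = 0
    for f in fragments:
        union |= f
    contained = []
    for occ in cls.occurrences:
        if occ & union == occ and any(occ & f == occ for f in fragments):
            contained.append(occ)
    pairs = []
    for i, a in enumerate(contained):
        for b in contained[i + 1 :]:
            if a & b == 0:
                pairs.append((a, b))
    return pairs


def available_duplicates(
    table: DuplicateTable,
    fragments: Sequence[int],
    max_rank: int = 0,
) -> Iterator[tuple[DuplicateClass, tuple[int, int]]]:
    """All (class, pair) removal options for a state, in global rank order.

    Only classes with ``rank >= max_rank`` are offered: along any pathway the
    chosen class ranks are non-decreasing in the size-descending order, i.e.
    duplicate sizes never increase.  The first yielded element therefore
    determines the state's m (maximum permitted duplicate size).
    """
    for cls in table.classes[max_rank:]:
        for pair in valid_pairs(cls, fragments):
            yield cls, pair
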