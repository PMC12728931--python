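"""Top-down assembly-state search for the exact molecular assembly index.

The assembly index MA of a molecular graph with N bonds and c edge-bearing
components is ``MA = N - c - S_max``, where S_max is the largest *duplicate
sum* reachable by iterated duplicate removal: each step picks two
edge-disjoint isomorphic connected occurrences of a duplicatable subgraph
(each inside a single current fragment, possibly different fragments),
deletes both occurrences' edges, appends one copy of the duplicate as a new
standalone fragment, and adds ``k - 1`` to S for a k-bond duplicate.  A
duplicate of k bonds glued on as a prebuilt unit costs one join instead of
k, hence the saving.

Three ingredients keep the recursion tractable:

* a monotone removal order — classes are sorted by size descending and a
  pathway may never pick a class ranked before its last one, which both
  prunes permutations of the same removal multiset and caps the duplicate
  size m available to every descendant state;
* dynamic programming — states (sorted fragment masks + last rank) are
  hashed, and a state is only re-expanded when revisited with a strictly
  higher S;
* branch and bound — the conditional addition-chain bound (``bounds``
  module) upper-bounds the residual S of a state given its fragment sizes
  and m, so states that cannot beat the incumbent are dropped.  The bound
  is applied once when a child is generated (with the parent's class size
  as cap) and again when the child is expanded (with its exact m).

The search is anytime: every state's S yields a valid MA upper bound
``N - c - S``, recorded in a monotone trace; on exhaustion the best bound
is exact.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Optional, Sequence

from .bounds import conditional_smax_bound, refined_split_bound
from .duplicates import DuplicateClass, DuplicateTable, enumerate_duplicates
from .graph import (
    MolecularGraph,
    connected_components,
    mask_edges,
    remove_unique_bonds,
)

__all__ = [
    "SearchConfig",
    "AssemblyState",
    "PathwayStep",
    "AssemblyResult",
    "BudgetExhausted",
    "disjoint_set_split",
    "apply_removal",
    "hash_state",
    "search",
    "compute_ma",
    "reconstruct_pathway",
]


@dataclass(frozen=True)
class SearchConfig:
    """Tunable knobs of the assembly search.

    ``max_seconds``/``max_states`` bound the wall clock and the number of
    expanded states (both optional; exhaustion without limits proves the MA
    exact).  The pruning toggles exist to demonstrate that the heuristics
    are lossless; leave them on for real work.  ``use_split_bound`` enables
    the two-part conditional-chain refinement, which tightens pruning at
    the price of per-state bookkeeping of the bonds coverable at size m.
    """

    max_seconds: Optional[float] = None
    max_states: Optional[int] = None
    use_bound: bool = True
    use_state_table: bool = True
    use_split_bound: bool = False
    track_pathway: bool = True


@dataclass(frozen=True)
class AssemblyState:
    """A search node: sorted fragment masks, duplicate sum, last class rank.

    ``fragments[0]`` is the copy of the last-removed duplicate (for the
    initial state, the first component).  Single-edge fragments are
    building blocks and are never stored.
    """

    fragments: tuple[int, ...]
    S: int
    last_rank: int


@dataclass(frozen=True)
class PathwayStep:
    """One duplicate removal: the copy kept, the remnants left behind."""

    duplicate: int
    remnants: tuple[int, ...]
    k: int
    pair: tuple[int, int]
    class_id: int


@dataclass
class AssemblyResult:
    ma: int
    best_s: int
    converged: bool
    n_bonds: int
    n_components: int
    trace: list[tuple[float, int]]
    pathway: list[PathwayStep]
    stats: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "ma": self.ma,
            "best_s": self.best_s,
            "converged": self.converged,
            "n_bonds": self.n_bonds,
            "n_components": self.n_components,
            "trace": [[round(t, 4), ub] for t, ub in self.trace],
            "pathway": [
                {
                    "duplicate_edges": list(mask_edges(st.duplicate)),
                    "remnant_edges": [list(mask_edges(r)) for r in st.remnants],
                    "k": st.k,
                }
                for st in self.pathway
            ],
            "stats": self.stats,
        }


class BudgetExhausted(Exception):
    """Raised internally when the time/state budget runs out."""


def disjoint_set_split(g: MolecularGraph, mask: int) -> list[int]:
    """Split a remnant edge mask into connected-fragment masks.

    Union-find over the endpoints of the set bits (practically linear in the
    number of edges); output ordered by ascending minimum edge index.
    Singleton-edge fragments are returned — the caller drops them from
    stored states.
    """
    return connected_components(g, mask)


def _split_fast(edge_adj: Sequence[int], mask: int) -> list[int]:
    """Bitset-BFS variant of disjoint_set_split for the hot path."""
    comps = []
    while mask:
        low = mask & -mask
        comp = low
        frontier = low
        mask ^= low
        while frontier:
            grow = 0
            f = frontier
            while f:
                lo = f & -f
                grow |= edge_adj[lo.bit_length() - 1]
                f ^= lo
            grow &= mask
            comp |= grow
            mask &= ~grow
            frontier = grow
        comps.append(comp)
    return comps


def hash_state(state: AssemblyState) -> tuple:
    """Hashable key of a state: (last rank, sorted fragment masks).

    The full mask tuple is the key itself, so hash collisions are resolved
    exactly by the dictionary.
    """
    return (state.last_rank, state.fragments)


def apply_removal(
    g: MolecularGraph,
    state: AssemblyState,
    cls: DuplicateClass,
    pair: tuple[int, int],
) -> tuple[AssemblyState, PathwayStep]:
    """Remove a duplicate pair from a state.

    Both occurrences' edges are deleted from their containing fragments,
    the remnants are split into connected fragments (single-edge remnants
    are dropped from the stored state), and one copy of the duplicate — the
    smaller mask of the pair — becomes the new ``fragments[0]``.  ``S``
    grows by ``k - 1``.
    """
    a, b = pair
    frag_a = next((f for f in state.fragments if a & f == a), None)
    frag_b = next((f for f in state.fragments if b & f == b), None)
    if frag_a is None or frag_b is None or a & b:
        raise ValueError("occurrence pair is not valid for this state")
    edge_adj = g.edge_adjacency
    if frag_a == frag_b:
        remnants = _split_fast(edge_adj, frag_a & ~(a | b))
    else:
        remnants = _split_fast(edge_adj, frag_a & ~a)
        remnants += _split_fast(edge_adj, frag_b & ~b)
    copy = a if a < b else b
    rest = [f for f in state.fragments if f != frag_a and f != frag_b]
    kept = [r for r in remnants if r.bit_count() >= 2]
    child = AssemblyState(
        (copy, *sorted(rest + kept)), state.S + cls.size - 1, cls.rank
    )
    step = PathwayStep(copy, tuple(remnants), cls.size, (a, b), cls.id)
    return child, step


def reconstruct_pathway(parents: dict, best_key: tuple) -> list[PathwayStep]:
    """Walk parent pointers from the best state back to the initial state.

    Steps come out in removal order; replaying them from the initial state
    reproduces the best state's fragment multiset (checked in tests), and
    their ``k - 1`` values sum to the best duplicate sum.
    """
    steps: list[PathwayStep] = []
    key = best_key
    seen = set()
    while key in parents:
        if key in seen:
            raise RuntimeError("internal inconsistency: parent-pointer cycle")
        seen.add(key)
        parent_key, step = parents[key]
        steps.append(step)
        key = parent_key
    steps.reverse()
    return steps


class _Searcher:
    def __init__(self, g: MolecularGraph, config: SearchConfig):
        self.g = g
        self.config = config
        self.n_bonds = g.n_edges
        components = connected_components(g, g.full_mask)
        self.n_components = len(components)
        self.initial = tuple(sorted(c for c in components if c.bit_count() >= 2))
        self.table: DuplicateTable = enumerate_duplicates(g, remove_unique_bonds(g))
        self.edge_adj = g.edge_adjacency
        self.best_S = 0
        self.initial_key = (0, self.initial)
        self.best_key = self.initial_key
        self.states: dict[tuple, int] = {self.initial_key: 0}
        self.parents: dict[tuple, tuple] = {}
        self.trace: list[tuple[float, int]] = []
        self.stats = {
            "expanded": 0,
            "children": 0,
            "pruned_bound": 0,
            "pruned_table": 0,
        }
        self._bound_cache: dict[tuple, int] = {}
        self._t0 = 0.0

    def _bound(self, sizes: tuple[int, ...], m: int, coverable_at_m: int) -> int:
        key = (sizes, m, coverable_at_m)
        val = self._bound_cache.get(key)
        if val is None:
            if self.config.use_split_bound and coverable_at_m >= 0:
                val = refined_split_bound(sizes, m, coverable_at_m)
            else:
                val = conditional_smax_bound(sizes, m)
            self._bound_cache[key] = val
        return val

    def run(self) -> AssemblyResult:
        self._t0 = time.perf_counter()
        self.trace.append((0.0, self.n_bonds - self.n_components))
        converged = True
        if self.initial and self.table.classes:
            try:
                self._expand(self.initial, 0, 0)
            except BudgetExhausted:
                converged = False
        ma = self.n_bonds - self.n_components - self.best_S
        pathway: list[PathwayStep] = []
        if self.config.track_pathway:
            pathway = reconstruct_pathway(self.parents, self.best_key)
        elapsed = time.perf_counter() - self._t0
        if self.trace[-1][1] != ma:
            self.trace.append((elapsed, ma))
        return AssemblyResult(
            ma=ma,
            best_s=self.best_S,
            converged=converged,
            n_bonds=self.n_bonds,
            n_components=self.n_components,
            trace=self.trace,
            pathway=pathway,
            stats=self.stats,
        )

    def _check_budget(self) -> None:
        cfg = self.config
        n = self.stats["expanded"]
        if cfg.max_states is not None and n >= cfg.max_states:
            raise BudgetExhausted
        if (
            cfg.max_seconds is not None
            and n % 64 == 0
            and time.perf_counter() - self._t0 > cfg.max_seconds
        ):
            raise BudgetExhausted

    def _coverable_at(self, size: int, fragments, union: int) -> int:
        """Bonds of the state coverable by occurrences of classes of size m."""
        cover = 0
        for cls in self.table.classes:
            if cls.size != size:
                continue
            for occ in cls.occurrences:
                if occ & union == occ and any(occ & f == occ for f in fragments):
                    cover |= occ
        return cover.bit_count()

    def _expand(self, fragments: tuple[int, ...], last_rank: int, S: int) -> None:
        self.stats["expanded"] += 1
        self._check_budget()
        if S > self.best_S:
            self.best_S = S
            self.best_key = (last_rank, fragments)
            self.trace.append(
                (
                    time.perf_counter() - self._t0,
                    self.n_bonds - self.n_components - S,
                )
            )

        union = 0
        for f in fragments:
            union |= f

        cfg = self.config
        bound_checked = not cfg.use_bound
        for cls in self.table.classes[last_rank:]:
            contained = []
            for occ in cls.occurrences:
                if occ & union == occ:
                    for f in fragments:
                        if occ & f == occ:
                            contained.append(occ)
                            break
            if len(contained) < 2:
                continue
            pairs = []
            for i, a in enumerate(contained):
                for b in contained[i + 1 :]:
                    if a & b == 0:
                        pairs.append((a, b))
            if not pairs:
                continue
            if not bound_checked:
                # First matchable class fixes m for this state.
                sizes = tuple(sorted(f.bit_count() for f in fragments))
                cov = (
                    self._coverable_at(cls.size, fragments, union)
                    if cfg.use_split_bound
                    else -1
                )
                if S + self._bound(sizes, cls.size, cov) <= self.best_S:
                    self.stats["pruned_bound"] += 1
                    return
                bound_checked = True
                total = sum(sizes)
            if cfg.use_bound:
                # Class-level prune: every child of this class has total size
                # total - k split among fragments, and merging fragments only
                # loosens the conditional bound, so one single-fragment
                # evaluation over-estimates every child of the class.
                k = cls.size
                if (
                    S + k - 1 + self._bound((total - k,), k, -1)
                    <= self.best_S
                ):
                    self.stats["pruned_bound"] += 1
                    continue
            self._descend(fragments, last_rank, S, cls, pairs)

    def _descend(self, fragments, last_rank, S, cls, pairs) -> None:
        cfg = self.config
        parent_key = (last_rank, fragments)
        k = cls.size
        child_S = S + k - 1
        rank = cls.rank
        edge_adj = self.edge_adj
        for a, b in pairs:
            self.stats["children"] += 1
            frag_a = frag_b = None
            for f in fragments:
                if a & f == a:
                    frag_a = f
                if b & f == b:
                    frag_b = f
            if frag_a == frag_b:
                remnants = _split_fast(edge_adj, frag_a & ~(a | b))
            else:
                remnants = _split_fast(edge_adj, frag_a & ~a)
                remnants += _split_fast(edge_adj, frag_b & ~b)
            copy = a if a < b else b
            rest = [f for f in fragments if f != frag_a and f != frag_b]
            kept = [r for r in remnants if r.bit_count() >= 2]
            child_fragments = tuple(sorted(rest + kept + [copy]))
            key = (rank, child_fragments)
            prev = self.states.get(key)
            if prev is not None and prev >= child_S and cfg.use_state_table:
                self.stats["pruned_table"] += 1
                continue
            if cfg.use_bound:
                child_sizes = tuple(
                    sorted(f.bit_count() for f in child_fragments)
                )
                if child_S + self._bound(child_sizes, k, -1) <= self.best_S:
                    self.stats["pruned_bound"] += 1
                    continue
            if prev is None or prev < child_S:
                self.states[key] = child_S
                if cfg.track_pathway:
                    self.parents[key] = (
                        parent_key,
                        PathwayStep(copy, tuple(remnants), k, (a, b), cls.id),
                    )
            self._expand(child_fragments, rank, child_S)


def search(g: MolecularGraph, config: SearchConfig | None = None) -> AssemblyResult:
    """Run the exact assembly search on a molecular graph.

    Returns an :class:`AssemblyResult`; ``converged`` is true when the state
    space was exhausted, in which case ``ma`` is the exact assembly index.
    With a budget, ``ma`` is the best (anytime) upper bound found.
    """
    config = config or SearchConfig()
    if config.max_seconds is not None and config.max_seconds <= 0:
        raise ValueError("max_seconds must be positive")
    if config.max_states is not None and config.max_states <= 0:
        raise ValueError("max_states must be positive")
    return _Searcher(g, config).run()


def compute_ma(g: MolecularGraph, config: SearchConfig | None = None) -> int:
    """The assembly index of *g* (exact when the search converges)."""
    return search(g, config).ma
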