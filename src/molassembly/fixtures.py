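"""Synthetic fixture generators for offline testing.

Everything here is a pure function of its spec: labeled paths/cycles/stars,
seeded random labeled trees, peptides built from one-letter codes, a small
dictionary of named molecules, and an exhaustive generator of all connected
labeled graphs up to isomorphism over a tiny alphabet (the workhorse of the
oracle-equivalence suite).
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass
from typing import Iterator, Sequence

from .canon import FragmentView, class_key, cyclic_isomorphic
from .graph import MolecularGraph, parse_smiles
from .peptides import AMINO_ACIDS, peptide_graph

__all__ = [
    "FixtureSpec",
    "NAMED_SMILES",
    "load_specs",
    "generate",
    "path_graph",
    "cycle_graph",
    "star_graph",
    "random_tree",
    "binary_chain",
    "exhaustive_small_graphs",
]

NAMED_SMILES: dict[str, str] = {
    "benzoic_acid": "OC(=O)c1ccccc1",
    **{f"aa_{code}": smi for code, smi in AMINO_ACIDS.items()},
}


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative fixture: generation is a pure function of this spec.

    Specs serialize to/from plain JSON objects so a test suite's graphs can
    live in a small config file (see :func:`load_specs`).
    """

    kind: str  # path | cycle | star | random_tree | peptide | named
    n: int = 0
    atoms: tuple[str, ...] = ("C",)
    bonds: tuple[str, ...] = ("single",)
    seed: int = 0
    name: str = ""

    @classmethod
    def from_dict(cls, data: dict) -> "FixtureSpec":
        return cls(
            kind=data["kind"],
            n=int(data.get("n", 0)),
            atoms=tuple(data.get("atoms", ("C",))),
            bonds=tuple(data.get("bonds", ("single",))),
            seed=int(data.get("seed", 0)),
            name=data.get("name", ""),
        )


def load_specs(path) -> list[FixtureSpec]:
    """Read a JSON list of fixture specs from *path*."""
    import json

    with open(path) as fh:
        return [FixtureSpec.from_dict(d) for d in json.load(fh)]


def path_graph(
    n: int, atoms: Sequence[str] = ("C",), bonds: Sequence[str] = ("single",)
) -> MolecularGraph:
    """Chain of *n* bonds; atom/bond labels cycle through the alphabets."""
    if n < 0:
        raise ValueError("n must be >= 0")
    vs = tuple(atoms[i % len(atoms)] for i in range(n + 1))
    es = tuple((i, i + 1, bonds[i % len(bonds)]) for i in range(n))
    return MolecularGraph(vs, es)


def binary_chain(n: int, index: int) -> MolecularGraph:
    """Chain of *n* bonds over one atom type and two bond types.

    Bond i is single/double according to bit i of *index*; the family of
    all such chains maps onto the n-bit binary numbers.
    """
    if not 0 <= index < (1 << n):
        raise ValueError("index out of range for chain length")
    orders = tuple(
        "double" if (index >> i) & 1 else "single" for i in range(n)
    )
    return MolecularGraph(
        tuple("C" for _ in range(n + 1)),
        tuple((i, i + 1, orders[i]) for i in range(n)),
    )


def cycle_graph(
    n: int, atoms: Sequence[str] = ("C",), bonds: Sequence[str] = ("single",)
) -> MolecularGraph:
    if n < 3:
        raise ValueError("cycle needs >= 3 edges")
    vs = tuple(atoms[i % len(atoms)] for i in range(n))
    es = tuple((i, (i + 1) % n, bonds[i % len(bonds)]) for i in range(n))
    return MolecularGraph(vs, es)


def star_graph(
    n: int, atoms: Sequence[str] = ("C",), bonds: Sequence[str] = ("single",)
) -> MolecularGraph:
    vs = (atoms[0],) + tuple(atoms[(i + 1) % len(atoms)] for i in range(n))
    es = tuple((0, i + 1, bonds[i % len(bonds)]) for i in range(n))
    return MolecularGraph(vs, es)


def random_tree(
    n: int,
    atoms: Sequence[str] = ("C",),
    bonds: Sequence[str] = ("single",),
    seed: int = 0,
) -> MolecularGraph:
    """Seeded random labeled tree with *n* edges (random attachment)."""
    rng = random.Random(seed)
    vs = [rng.choice(list(atoms)) for _ in range(n + 1)]
    es = []
    for v in range(1, n + 1):
        es.append((rng.randrange(v), v, rng.choice(list(bonds))))
    return MolecularGraph(tuple(vs), tuple(es))


def generate(spec: FixtureSpec) -> MolecularGraph:
    """Deterministic graph for a fixture spec."""
    if spec.kind == "path":
        return path_graph(spec.n, spec.atoms, spec.bonds)
    if spec.kind == "cycle":
        return cycle_graph(spec.n, spec.atoms, spec.bonds)
    if spec.kind == "star":
        return star_graph(spec.n, spec.atoms, spec.bonds)
    if spec.kind == "random_tree":
        return random_tree(spec.n, spec.atoms, spec.bonds, spec.seed)
    if spec.kind == "peptide":
        return peptide_graph(spec.name)
    if spec.kind == "named":
        try:
            return parse_smiles(NAMED_SMILES[spec.name])
        except KeyError:
            raise ValueError(f"unknown named fixture {spec.name!r}") from None
    raise ValueError(f"unknown fixture kind {spec.kind!r}")


# ---------------------------------------------------------------------------
# Exhaustive enumeration of small labeled graphs up to isomorphism
# ---------------------------------------------------------------------------

def _skeletons(max_edges: int) -> list[tuple[int, tuple[tuple[int, int], ...]]]:
    """All connected unlabeled graphs with 1..max_edges edges, up to iso.

    Grown edge-by-edge; deduplicated with the package's own canonical
    machinery on single-label stand-ins (the exhaustive test re-validates
    that machinery against permutation brute force separately).
    """
    reps: list[tuple[MolecularGraph, int]] = []  # (graph, full mask)
    keys_seen: dict = {}

    def register(nv: int, edges: tuple[tuple[int, int], ...]) -> bool:
        g = MolecularGraph(
            tuple("C" for _ in range(nv)),
            tuple((u, v, "single") for u, v in edges),
        )
        fv = FragmentView(g, g.full_mask)
        key = class_key(fv)
        bucket = keys_seen.setdefault((key.kind, key.key), [])
        if key.kind == "tree-canonical":
            if bucket:
                return False
        else:
            for other in bucket:
                if cyclic_isomorphic(other, fv):
                    return False
        bucket.append(fv)
        return True

    out: list[tuple[int, tuple[tuple[int, int], ...]]] = []
    frontier = [(2, ((0, 1),))]
    register(2, ((0, 1),))
    out.append((2, ((0, 1),)))
    for _level in range(1, max_edges):
        nxt = []
        for nv, edges in frontier:
            present = set(edges)
            # New edge between existing vertices.
            for u in range(nv):
                for v in range(u + 1, nv):
                    if (u, v) not in present:
                        cand = tuple(sorted(edges + ((u, v),)))
                        if register(nv, cand):
                            nxt.append((nv, cand))
            # New pendant vertex.
            for u in range(nv):
                cand = tuple(sorted(edges + ((u, nv),)))
                if register(nv + 1, cand):
                    nxt.append((nv + 1, cand))
        out.extend(nxt)
        frontier = nxt
    return out


def _automorphisms(nv: int, edges: tuple[tuple[int, int], ...]) -> list[tuple[int, ...]]:
    """All vertex automorphisms of an unlabeled skeleton (backtracking)."""
    adj = [set() for _ in range(nv)]
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    deg = [len(a) for a in adj]
    autos: list[tuple[int, ...]] = []
    perm = [-1] * nv
    used = [False] * nv

    def extend(i: int) -> None:
        if i == nv:
            autos.append(tuple(perm))
            return
        for j in range(nv):
            if used[j] or deg[j] != deg[i]:
                continue
            ok = True
            for w in adj[i]:
                if w < i and perm[w] not in adj[j]:
                    ok = False
                    break
            if ok:
                # also ensure non-adjacency is preserved for mapped vertices
                for w in range(i):
                    if w not in adj[i] and perm[w] in adj[j]:
                        ok = False
                        break
            if ok:
                perm[i] = j
                used[j] = True
                extend(i + 1)
                used[j] = False
                perm[i] = -1

    extend(0)
    return autos


def exhaustive_small_graphs(
    max_edges: int,
    atoms: Sequence[str] = ("C", "N"),
    bonds: Sequence[str] = ("single", "double"),
) -> Iterator[MolecularGraph]:
    """All connected labeled graphs with 1..max_edges edges, up to iso.

    For every unlabeled skeleton, every assignment of atom and bond labels
    is enumerated and deduplicated by its minimum over the skeleton's
    automorphism group, so each isomorphism class is yielded exactly once.
    """
    if max_edges > 7:
        raise ValueError("exhaustive generation is limited to 7 edges")
    atoms = tuple(atoms)
    bonds = tuple(bonds)
    for nv, edges in _skeletons(max_edges):
        autos = _automorphisms(nv, edges)
        if len(autos) > 24 and len(edges) == nv - 1:
            # High-symmetry trees (stars, spiders): min-over-Aut is quadratic
            # in the orbit size; the exact tree key dedupes in linear time.
            seen_keys: set[str] = set()
            for vlab in itertools.product(atoms, repeat=nv):
                for elab in itertools.product(bonds, repeat=len(edges)):
                    g = MolecularGraph(
                        vlab,
                        tuple(
                            (u, v, elab[k]) for k, (u, v) in enumerate(edges)
                        ),
                    )
                    key = class_key(FragmentView(g, g.full_mask)).key
                    if key not in seen_keys:
                        seen_keys.add(key)
                        yield g
            continue
        edge_index = {e: i for i, e in enumerate(edges)}
        # Per automorphism: inverse vertex and edge-position permutations,
        # so one group element transforms vertex and edge labels coherently.
        transforms = []
        for perm in autos:
            pinv = [0] * nv
            for i, p in enumerate(perm):
                pinv[p] = i
            ep = [
                edge_index[tuple(sorted((perm[u], perm[v])))]
                for u, v in edges
            ]
            epinv = [0] * len(edges)
            for i, p in enumerate(ep):
                epinv[p] = i
            transforms.append((tuple(pinv), tuple(epinv)))
        seen: set[tuple] = set()
        ne = len(edges)
        for vlab in itertools.product(range(len(atoms)), repeat=nv):
            for elab in itertools.product(range(len(bonds)), repeat=ne):
                canon = min(
                    (
                        tuple(vlab[pinv[j]] for j in range(nv)),
                        tuple(elab[epinv[j]] for j in range(ne)),
                    )
                    for pinv, epinv in transforms
                )
                if canon in seen:
                    continue
                seen.add(canon)
                yield MolecularGraph(
                    tuple(atoms[i] for i in vlab),
                    tuple((u, v, bonds[elab[k]]) for k, (u, v) in enumerate(edges)),
                )
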