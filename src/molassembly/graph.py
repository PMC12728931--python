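"""Molecular-graph data model and bond-level preprocessing.

A molecule is a hydrogen-suppressed, vertex- and edge-labeled graph with a
fixed edge indexing (input order).  Fragments of the molecule are represented
as *edge masks*: Python integers used as bitsets over the edge indices
``0..N-1``, which makes overlap tests, removal and hashing single integer
operations.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Iterator

__all__ = [
    "BOND_ORDERS",
    "LabelOptions",
    "MolecularGraph",
    "FragmentView",
    "ParseError",
    "parse_smiles",
    "parse_molblock",
    "remove_unique_bonds",
    "connected_components",
    "mask_edges",
    "mask_of",
]

#: Recognised bond-order categories.  Aromatic bonds are their own category by
#: default (a benzene ring is six mutually duplicatable bonds); kekulization is
#: available through :class:`LabelOptions`.
BOND_ORDERS = ("single", "double", "triple", "aromatic")


class ParseError(ValueError):
    """Raised when a SMILES string or MOL block cannot be parsed."""


@dataclass(frozen=True)
class LabelOptions:
    """Conventions for turning chemistry into graph labels.

    kekulize
        If true, aromatic systems are kekulized and ring bonds alternate
        single/double instead of carrying a uniform ``aromatic`` label.
    use_charge
        If true, formal charges become part of the atom label (``"N+1"``);
        by default atoms are typed by element symbol alone.
    """

    kekulize: bool = False
    use_charge: bool = False


def _bond_label(la: str, lb: str, order: str) -> tuple[str, str, str]:
    """Canonical (unordered-endpoint) label of a bond."""
    if la > lb:
        la, lb = lb, la
    return (la, lb, order)


@dataclass(frozen=True)
class MolecularGraph:
    """Hydrogen-suppressed labeled molecular graph with stable edge indices.

    Parameters
    ----------
    atoms
        Atom labels, indexed by vertex id.
    bonds
        ``(u, v, order)`` triples; the position in this tuple is the edge
        index used by every mask in the package.
    """

    atoms: tuple[str, ...]
    bonds: tuple[tuple[int, int, str], ...]

    def __post_init__(self) -> None:
        seen: set[tuple[int, int]] = set()
        for u, v, order in self.bonds:
            if u == v:
                raise ValueError(f"self-loop on vertex {u}")
            if not (0 <= u < len(self.atoms) and 0 <= v < len(self.atoms)):
                raise ValueError(f"bond ({u},{v}) references unknown vertex")
            if order not in BOND_ORDERS:
                raise ValueError(f"unknown bond order {order!r}")
            key = (min(u, v), max(u, v))
            if key in seen:
                raise ValueError(f"duplicate bond between {u} and {v}")
            seen.add(key)

    @property
    def n_vertices(self) -> int:
        return len(self.atoms)

    @property
    def n_edges(self) -> int:
        """Number of bonds N (the assembly accounting runs over edges)."""
        return len(self.bonds)

    @cached_property
    def full_mask(self) -> int:
        return (1 << self.n_edges) - 1

    @cached_property
    def bond_labels(self) -> tuple[tuple[str, str, str], ...]:
        return tuple(
            _bond_label(self.atoms[u], self.atoms[v], order)
            for u, v, order in self.bonds
        )

    @cached_property
    def vertex_adjacency(self) -> tuple[tuple[tuple[int, int], ...], ...]:
        """Per vertex: tuple of (edge index, neighbour vertex)."""
        adj: list[list[tuple[int, int]]] = [[] for _ in self.atoms]
        for e, (u, v, _order) in enumerate(self.bonds):
            adj[u].append((e, v))
            adj[v].append((e, u))
        return tuple(tuple(a) for a in adj)

    @cached_property
    def edge_adjacency(self) -> tuple[int, ...]:
        """Per edge: mask of edges sharing a vertex with it (itself excluded)."""
        vertex_masks = [0] * self.n_vertices
        for e, (u, v, _order) in enumerate(self.bonds):
            bit = 1 << e
            vertex_masks[u] |= bit
            vertex_masks[v] |= bit
        out = []
        for e, (u, v, _order) in enumerate(self.bonds):
            out.append((vertex_masks[u] | vertex_masks[v]) & ~(1 << e))
        return tuple(out)

    @cached_property
    def n_components(self) -> int:
        """Number of connected components that carry at least one edge.

        Isolated atoms are ignored: a bare building block contributes no
        joining steps, so only edge-bearing components enter the
        ``MA = N - c - S`` accounting.
        """
        return len(connected_components(self, self.full_mask))

    def edge_vertices(self, mask: int) -> set[int]:
        """Vertices covered by the set bits of *mask*."""
        verts: set[int] = set()
        for e in mask_edges(mask):
            u, v, _ = self.bonds[e]
            verts.add(u)
            verts.add(v)
        return verts

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"MolecularGraph(|V|={self.n_vertices}, |E|={self.n_edges})"


@dataclass(frozen=True)
class FragmentView:
    """A fragment: a molecular graph together with an edge mask into it."""

    graph: MolecularGraph
    mask: int

    @property
    def size(self) -> int:
        """Fragment size L = number of bonds."""
        return self.mask.bit_count()

    def edges(self) -> Iterator[int]:
        return mask_edges(self.mask)

    def vertices(self) -> set[int]:
        return self.graph.edge_vertices(self.mask)

    def is_connected(self) -> bool:
        return len(connected_components(self.graph, self.mask)) <= 1


def mask_edges(mask: int) -> Iterator[int]:
    """Iterate set bit positions of an edge mask, ascending."""
    while mask:
        low = mask & -mask
        yield low.bit_length() - 1
        mask ^= low


def mask_of(edges: Iterable[int]) -> int:
    m = 0
    for e in edges:
        m |= 1 << e
    return m


# ---------------------------------------------------------------------------
# Parsing (RDKit-backed)
# ---------------------------------------------------------------------------

_RDKIT_ORDER = {
    "SINGLE": "single",
    "DOUBLE": "double",
    "TRIPLE": "triple",
    "AROMATIC": "aromatic",
}


def _from_rdkit(mol, opts: LabelOptions) -> MolecularGraph:
    from rdkit import Chem

    mol = Chem.RemoveAllHs(mol)  # also strips isotopic hydrogens
    if opts.kekulize:
        Chem.Kekulize(mol, clearAromaticFlags=True)
    atoms = []
    for atom in mol.GetAtoms():
        label = atom.GetSymbol()
        if opts.use_charge and atom.GetFormalCharge():
            label = f"{label}{atom.GetFormalCharge():+d}"
        atoms.append(label)
    bonds = []
    for bond in mol.GetBonds():
        order = _RDKIT_ORDER.get(bond.GetBondType().name)
        if order is None:
            raise ParseError(f"unsupported bond type {bond.GetBondType().name}")
        bonds.append((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), order))
    return MolecularGraph(tuple(atoms), tuple(bonds))


def parse_smiles(text: str, opts: LabelOptions | None = None) -> MolecularGraph:
    """Parse a SMILES string into a hydrogen-suppressed molecular graph.

    Dot-disconnected SMILES yield a multi-component graph.  Edge indices
    follow RDKit's bond ordering for the input, which is deterministic for a
    given string.
    """
    from rdkit import Chem

    opts = opts or LabelOptions()
    mol = Chem.MolFromSmiles(text.strip(), sanitize=True)
    if mol is None:
        raise ParseError(f"could not parse SMILES {text.strip()!r}")
    return _from_rdkit(mol, opts)


def parse_molblock(text: str, opts: LabelOptions | None = None) -> MolecularGraph:
    """Parse a MOL/SDF connection table (V2000/V3000); hydrogens are stripped."""
    from rdkit import Chem

    opts = opts or LabelOptions()
    mol = Chem.MolFromMolBlock(text, sanitize=True, removeHs=True)
    if mol is None:
        raise ParseError("could not parse MOL block")
    return _from_rdkit(mol, opts)


# ---------------------------------------------------------------------------
# Preprocessing and components
# ---------------------------------------------------------------------------

def remove_unique_bonds(g: MolecularGraph) -> int:
    """Mask of bonds whose label occurs at least twice.

    A bond whose (endpoint labels, order) label is unique in the molecule can
    never belong to two edge-disjoint isomorphic subgraphs, so duplicate
    enumeration skips it.  Single pass, O(V+E).  Removed bonds still count
    toward N in the assembly-index formula.
    """
    counts: dict[tuple[str, str, str], int] = {}
    for lbl in g.bond_labels:
        counts[lbl] = counts.get(lbl, 0) + 1
    mask = 0
    for e, lbl in enumerate(g.bond_labels):
        if counts[lbl] >= 2:
            mask |= 1 << e
    return mask


def connected_components(g: MolecularGraph, mask: int) -> list[int]:
    """Split an edge mask into connected-fragment masks.

    Union-find over the endpoints of the set bits; output is ordered by the
    smallest contained edge index.
    """
    if mask == 0:
        return []
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    for e in mask_edges(mask):
        u, v, _ = g.bonds[e]
        for w in (u, v):
            if w not in parent:
                parent[w] = w
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv

    comps: dict[int, int] = {}
    for e in mask_edges(mask):
        root = find(g.bonds[e][0])
        comps[root] = comps.get(root, 0) | (1 << e)
    return sorted(comps.values(), key=lambda m: (m & -m).bit_length())
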