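"""Joint assembly spaces and the Joint Assembly Overlap similarity.

The joint assembly index of a set of molecules is the assembly index of
their disjoint union: the minimum number of joining operations that build
the whole set simultaneously, with fragments shared freely across
molecules.  For two identical molecules it equals the index of one — the
second copy carries no new information — and this sub-additivity is what
the Jaccard-like similarity

    JAO(A, B) = (MA_A + MA_B - MA_{A,B}) / MA_{A,B}

turns into a score in [0, 1]: 1 for identical molecules, 0 when the pair
shares no constructible substructure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .canon import FragmentView, cyclic_isomorphic
from .graph import MolecularGraph
from .search import AssemblyResult, SearchConfig, search

__all__ = ["JaoScore", "join_graphs", "joint_assembly_index", "jao", "compression_ratio"]


@dataclass(frozen=True)
class JaoScore:
    """JAO between two molecules, with the indices it was computed from.

    ``exact`` is false when any of the three searches stopped on budget: in
    that regime ``ma_ab`` is an upper bound, so if the individual indices
    are exact the reported jao is a lower bound on the true value.
    """

    ma_a: int
    ma_b: int
    ma_ab: int
    jao: float
    exact: bool

    def to_dict(self) -> dict:
        return {
            "ma_a": self.ma_a,
            "ma_b": self.ma_b,
            "ma_ab": self.ma_ab,
            "jao": self.jao,
            "exact": self.exact,
        }


def join_graphs(mols: Sequence[MolecularGraph]) -> MolecularGraph:
    """Disjoint union of molecular graphs with re-indexed vertices/edges.

    The building-block alphabet of the joint space is implicitly the union
    of the members' atom and bond types.
    """
    if not mols:
        raise ValueError("join_graphs requires at least one molecule")
    atoms: list[str] = []
    bonds: list[tuple[int, int, str]] = []
    for m in mols:
        off = len(atoms)
        atoms.extend(m.atoms)
        bonds.extend((u + off, v + off, o) for u, v, o in m.bonds)
    return MolecularGraph(tuple(atoms), tuple(bonds))


def joint_assembly_index(
    mols: Sequence[MolecularGraph], config: SearchConfig | None = None
) -> AssemblyResult:
    """Assembly search over the disjoint union of *mols*.

    Duplicates may match across components, so shared scaffolds are built
    once and reused.
    """
    return search(join_graphs(mols), config)


def jao(
    a: MolecularGraph,
    b: MolecularGraph,
    config: SearchConfig | None = None,
) -> JaoScore:
    """Joint Assembly Overlap of two molecules (three assembly searches)."""
    if a.n_vertices == 0 or b.n_vertices == 0:
        raise ValueError("jao requires two non-empty molecules")
    res_a = search(a, config)
    res_b = search(b, config)
    res_ab = joint_assembly_index([a, b], config)
    exact = res_a.converged and res_b.converged and res_ab.converged
    if res_ab.ma == 0:
        # Only single-building-block molecules reach MA_{A,B} = 0.
        if cyclic_isomorphic(
            FragmentView(a, a.full_mask), FragmentView(b, b.full_mask)
        ):
            value = 1.0
        else:
            raise ZeroDivisionError(
                "JAO undefined: joint assembly index is 0 for non-isomorphic inputs"
            )
    else:
        value = (res_a.ma + res_b.ma - res_ab.ma) / res_ab.ma
    return JaoScore(res_a.ma, res_b.ma, res_ab.ma, value, exact)


def compression_ratio(
    mols: Sequence[MolecularGraph], config: SearchConfig | None = None
) -> float:
    """1 - MA_joint / sum(individual MAs): reuse across a molecule set.

    Budget-limited searches make this an estimate (each index is then an
    upper bound).
    """
    individual = sum(search(m, config).ma for m in mols)
    joint = joint_assembly_index(mols, config).ma
    if individual == 0:
        return 0.0
    return 1.0 - joint / individual
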