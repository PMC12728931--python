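"""Conditional addition-chain bounds for branch-and-bound pruning.

Removing a duplicate of k bonds saves k-1 joining steps, so the residual
duplicate sum S obtainable from an assembly state is capped by how fast
fragment sizes can be "halved" under the current maximum duplicate size m.
This is exactly the conditional addition-chain problem: an addition chain in
which a designated integer x <= m must be used, and no larger summand may
appear.  For a single fragment of L bonds the chain view gives

    S(L, x) <= L - ceil(L / x) - ceil(log2 x)

and for a multi-fragment state the logarithmic term (the cost of building x
itself) is paid only once across fragments.  The bound used for pruning is
the maximum of that expression over x in {2..m}, clamped at zero.  It is
admissible: pruning with it never discards an optimal pathway.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Sequence

__all__ = [
    "ceil_log2",
    "addition_chain_length",
    "chain_bound_single",
    "conditional_smax_bound",
    "refined_split_bound",
]

_ADDITION_CHAIN_LIMIT = 4096


def ceil_log2(n: int) -> int:
    """Smallest t with 2**t >= n.  The minimum addition-chain length of any
    integer n is at least this."""
    if n < 1:
        raise ValueError("ceil_log2 requires n >= 1")
    return (n - 1).bit_length()


@lru_cache(maxsize=None)
def addition_chain_length(n: int) -> int:
    """Exact minimal addition-chain length l(n).

    Iterative-deepening DFS over strictly increasing chains
    ``1 = a_0 < a_1 < ... < a_r = n`` with ``a_i = a_j + a_k``.  Exponential
    in the worst case but instant for the sizes used here (n <= 4096); a
    uniform chain of n bonds has assembly index exactly l(n).
    """
    if n < 1:
        raise ValueError("addition_chain_length requires n >= 1")
    if n > _ADDITION_CHAIN_LIMIT:
        raise ValueError(f"n exceeds configured limit {_ADDITION_CHAIN_LIMIT}")
    if n == 1:
        return 0

    lower = ceil_log2(n)

    def extend(chain: list[int], depth_left: int) -> bool:
        last = chain[-1]
        if last == n:
            return True
        if depth_left == 0 or last << depth_left < n:
            return False
        # Largest sums first: reaches doubling-heavy optima quickly.
        sums = sorted(
            {a + chain[-1] for a in chain}
            | {a + b for i, a in enumerate(chain) for b in chain[i:]},
            reverse=True,
        )
        for s in sums:
            if last < s <= n:
                chain.append(s)
                if extend(chain, depth_left - 1):
                    return True
                chain.pop()
        return False

    depth = lower
    while True:
        if extend([1], depth):
            return depth
        depth += 1


def chain_bound_single(L: int, m: int) -> int:
    """Max duplicate sum for one fragment of L bonds at duplicate-size cap m.

    ``L - ceil(L/m) - ceil(log2 m)``; may be negative (callers clamp at 0).
    """
    if L < 1:
        raise ValueError("fragment size must be >= 1")
    if m < 2:
        raise ValueError("duplicate-size cap must be >= 2")
    return L - -(L // -m) - ceil_log2(m)


def conditional_smax_bound(sizes: Sequence[int], m: int) -> int:
    """Admissible upper bound on the residual duplicate sum of a state.

    ``max over x in 2..m of [ -ceil(log2 x) + sum_i (L_i - ceil(L_i/x)) ]``,
    clamped at 0.  The log term is shared across fragments: the capped
    duplicate needs to be assembled only once.
    """
    if not sizes:
        return 0
    if m < 2:
        return 0
    best = 0
    m_eff = min(m, max(sizes))
    for x in range(2, max(m_eff, 2) + 1):
        total = -ceil_log2(x)
        for L in sizes:
            total += L - -(L // -x)
        if total > best:
            best = total
    return best


def refined_split_bound(sizes: Sequence[int], m: int, L_m: int) -> int:
    """Two-part refinement of the conditional bound.

    Only ``L_m`` of the state's bonds are coverable by duplicates of the
    maximum size m; the rest can use duplicates of size at most m-1.  The
    bound sums a cap-m conditional chain over ``L_m`` and a cap-(m-1) chain
    over the remainder, paying the logarithmic assembly term once.  Tighter
    than or equal to :func:`conditional_smax_bound`, and still admissible.
    """
    total = sum(sizes)
    if not (0 <= L_m <= total):
        raise ValueError("L_m must lie in [0, sum(sizes)]")
    if L_m == total:
        return conditional_smax_bound(sizes, m)
    if m < 3:
        # No size-(m-1) duplicates exist below m=3; remainder saves nothing.
        return conditional_smax_bound(sizes, m)
    if L_m == 0:
        return conditional_smax_bound(sizes, m - 1)
    rest = total - L_m
    best = 0
    for x in range(2, m + 1):
        part_m = L_m - -(L_m // -x) if x <= m else 0
        cap_rest = min(x, m - 1)
        part_rest = rest - -(rest // -cap_rest)
        val = part_m + part_rest - ceil_log2(x)
        if val > best:
            best = val
    return best
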