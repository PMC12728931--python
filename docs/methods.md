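# Methods

## Model

A molecule is modeled as a hydrogen-suppressed labeled graph: vertices
carry element symbols, edges carry a bond-order category (single, double,
triple, aromatic).  The assembly index MA of a set of such graphs is the
minimum number of joining operations that builds all of them from
single-bond building blocks, where a joining operation glues two
previously built fragments along shared atoms and every built fragment
may be reused any number of times for free.

The search computes MA top-down.  A *duplicatable subgraph* of the
current structure is a connected subgraph with two edge-disjoint,
label-isomorphic occurrences, each lying inside a single fragment of the
current state (the two occurrences may sit in different fragments, which
is how joint spaces share structure across molecules).  A removal deletes
both occurrences' edges and appends one copy of the duplicate as a new
standalone fragment; removing a k-bond duplicate contributes k - 1 to the
pathway's duplicate sum S, because gluing a prebuilt k-bond fragment
costs one join instead of k.  With N total bonds and c edge-bearing
components,

    MA = N - c - S_max.

Identities that pin the accounting down, all enforced in tests:

* a uniform chain of n bonds has MA equal to the minimal addition-chain
  length l(n) (both sides computed independently up to n = 20);
* the joint MA of two copies of a molecule equals the MA of one (the
  second copy adds no information), which fixes the `- c` term;
* a single bond and a lone atom have MA = 0 — c counts only components
  that carry at least one edge, so free building blocks cost nothing;
* benzoic acid (aromatic ring as one bond type) has MA = 6.

An alternative reading of the removal step — delete only one occurrence
and leave the witness in place — is provably wrong: for a uniform 7-bond
chain it yields S = 3 and MA = 3, while l(7) = 4 (the "witness" is then a
subgraph of a remaining fragment, not a built pool member).  The
delete-both-keep-one-copy semantics reproduces every identity above.

## Labels

Atoms are typed by element symbol only; formal charge can be added to the
label via `LabelOptions(use_charge=True)`.  Stereochemistry, isotopes and
tautomer state are ignored.  Aromatic bonds are their own bond-order
category rather than kekulized alternating bonds, so the six bonds of a
benzene ring are mutually duplicatable; this choice is calibrated by
MA(benzoic acid) = 6 and is configurable (`LabelOptions(kekulize=True)`).
Bond labels are (unordered endpoint elements, order) triples.

## Enumeration

Bonds whose label occurs only once are removed from consideration first
(single pass; such a bond can never belong to two label-isomorphic
disjoint subgraphs).  All duplicatable subgraph classes are then
enumerated once, breadth-wise: connected 2-edge subgraphs seed the sweep,
and every occurrence of a class with at least two occurrences is grown by
one adjacent edge.  Masks alone in their bond-label-multiset bucket are
discarded before canonization — they cannot have an isomorphic partner.
Classes are identified by an exact AHU tree key (rooted at the tree
center; bicentral trees take the lexicographically smaller of the two
rooted encodings) when acyclic, otherwise by an invariant bucket key
(size, cycle rank, label multisets, degree sequence) refined by explicit
VF2-style backtracking; bucket collisions are expected and harmless.
Classes with occurrences but no edge-disjoint pair are kept in the growth
DAG but never offered to the search.  The enumeration is done once; every
search state filters the precomputed occurrence masks against its current
fragments with integer-mask operations.

## Search

States are (sorted fragment masks, last-removed-class rank, S); fragments
of one edge are building blocks and are dropped.  Classes are globally
sorted by size descending; a pathway may only remove classes ranked at or
after its last removal, so duplicate sizes never increase along a pathway
and permutations of the same removal multiset are explored once.  This
ordering rule, the state table (re-expansion only on strictly higher S)
and the branch-and-bound below are validated as lossless by exhaustive
comparison with an unrestricted brute-force recursion on all 679,063
connected labeled graphs with up to 7 edges over a 2-atom x 2-bond
alphabet, plus seeded random labeled trees.

The bound: under a duplicate-size cap m, fragment sizes can at best
shrink along a conditional addition chain, giving the admissible bound

    S_residual <= max over x in 2..m of
                  [ -ceil(log2 x) + sum_i (L_i - ceil(L_i / x)) ]

clamped at zero, with the logarithmic term (the cost of first building
the duplicate) paid once across fragments.  A state is pruned when its
achieved S plus this bound cannot beat the incumbent.  The bound is
applied to each generated child (with the parent class size as cap, plus
a cheaper single-fragment over-estimate that can discard a whole class's
children at once) and again on expansion with the state's exact m.  A
two-part refinement — separate chains for the bonds coverable at size m
and for the remainder at cap m - 1 — is implemented behind
`SearchConfig(use_split_bound=True)`, default off: its per-state
bookkeeping of coverable bonds usually costs more than the extra pruning
saves, matching its marginal value in practice.

Every state's S yields a valid upper bound N - c - S on MA, so the search
is anytime: improvements are recorded in a monotone trace, budget-stopped
runs return the best bound with `converged=False`, and exhaustion proves
exactness.  Pathways are reconstructed from parent pointers in the state
table; replaying the reported steps from the initial state reproduces the
best state's fragments and duplicate sum (a test checks this replay
identity on every fixture).

## Joint spaces and JAO

The joint assembly index of a molecule set is the MA of the disjoint
union of their graphs; duplicate occurrences may pair across components.
JAO(A, B) = (MA_A + MA_B - MA_AB) / MA_AB lies in [0, 1] because
max(MA_A, MA_B) <= MA_AB <= MA_A + MA_B.  When a budget stops the joint
search, MA_AB is an upper bound, so with exact individual indices the
reported JAO is a lower bound; the score carries an `exact` flag.  The
degenerate MA_AB = 0 (two single-building-block inputs) is defined as
JAO = 1 for isomorphic inputs and is an error otherwise.

Peptide fixtures are built from one-letter codes with an embedded residue
topology table: neutral side chains, free N/C termini, proline closing
its pyrrolidine ring onto the backbone nitrogen, no stereochemistry.
These conventions reproduce the tripeptide JAO values the package's
acceptance checks assert (ACD/ADC 0.667, STV/SVT 0.615, EFG/EGF 0.75).

## Synthetic data and what the tests show

The fixture generators produce labeled paths, cycles, stars, seeded
random trees (random-attachment, pure function of the seed), peptides,
and — the workhorse — every connected labeled graph up to 7 edges over a
2-atom x 2-bond alphabet, enumerated per unlabeled skeleton and
deduplicated by automorphism orbit (high-symmetry trees switch to exact
tree-key deduplication).  These fixtures exercise every code path of
enumeration and search at sizes where an independent brute-force oracle
is feasible; they do not emulate real molecules' label diversity, ring
systems beyond 7 bonds, or sizes where memory pressure matters, so
passing them certifies correctness of the combinatorics, not performance
on pharmaceutical-scale inputs.  Chemistry enters through RDKit parsing,
which is exercised by the molecule-level fixtures (benzoic acid, the
amino-acid and tripeptide builders).

Problem sizes used by the default suites: exhaustive oracle equivalence
to 7 edges; duplicate-enumeration brute-force comparison to 4 edges plus
a deterministic slice of the 5-edge level (its networkx-based reference
is far slower than the code under test); bound admissibility on all
reachable states of a fixed fixture list with an exhaustive cap-m
recursion; 200 random labeled trees to 10 edges; addition chains to
n = 20.

## Numerical and tie-break choices

* Edge indices follow input order; all determinism statements are
  relative to it.  Equal-size classes are ordered by canonical key, then
  by discovery order (cyclic classes in one bucket share a key).
* The duplicate copy kept after a removal is the smaller occurrence mask
  of the pair; co-optimal pathways resolve to the first found under the
  deterministic (size, rank, occurrence-order) child ordering.
* Bound values clamp at zero; pruning is strict (`S + bound <= best_S`),
  keeping one optimal pathway reachable.
* `addition_chain_length` is an iterative-deepening DFS over strictly
  increasing chains, exact and cached, refusing n > 4096.
* Degenerate inputs: graphs with no edges, lone atoms and single bonds
  return MA = 0; disconnected inputs are handled by the `- c` term;
  empty molecule lists and non-positive budgets raise.

## Limitations

Search cost grows exponentially with bond count; exact convergence at
desk scale reaches roughly 40-50 bonds for organic molecules (seconds to
minutes in this pure-Python implementation, e.g. the 50-bond EFG/EGF
joint space at about 600k states) — an order of magnitude below tuned
C++ implementations of the same algorithm.  Beyond that the anytime
bound is the intended mode.  Highly symmetric graphs with large vertex
degree (dense crystals, fused ring systems with one bond type) explode
the occurrence lists during enumeration; approximate candidate
generation for such inputs is out of scope.  Atom typing ignores charge by default, so salts and zwitterions
fold onto their neutral skeletons unless `use_charge` is set.
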