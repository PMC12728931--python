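# molassembly

Exact **molecular assembly indices** (MA) and the **Joint Assembly
Overlap** (JAO) similarity metric for molecular graphs.

The assembly index of a molecule is the fewest joining operations needed
to construct its hydrogen-suppressed molecular graph from single-bond
building blocks, when any previously assembled fragment may be reused at
no extra cost.  It measures the minimal informational constraints needed
to build a structure and is used in biosignature detection, chemical
complexity and cheminformatics.  For a graph with N bonds,

```
MA = N - c - S_max
```

where c is the number of (edge-bearing) connected components and S_max is
the largest *duplicate sum* over fragmentation pathways: repeatedly find
two edge-disjoint isomorphic connected subgraphs, delete both and keep one
copy as a standalone fragment — a duplicate of k bonds saves k - 1 joins.
For a uniform chain of n identical bonds this reduces exactly to the
minimal addition-chain problem, MA = l(n).

The search is exact: duplicatable subgraphs are enumerated once (tree
canonization for acyclic fragments, VF2-style matching for cyclic ones)
and a depth-first recursion over assembly states is pruned with

* largest-duplicates-first ordering, which also caps the duplicate size m
  available to all descendant states,
* a hash table of assembly states (re-expanded only on a strictly better
  duplicate sum), and
* an admissible *conditional addition-chain* lower bound,
  `S <= max_x [ -ceil(log2 x) + sum_i (L_i - ceil(L_i / x)) ]` over
  duplicate sizes `x <= m` and fragment sizes `L_i`.

The same machinery runs on disconnected multi-molecule inputs, giving
**joint assembly spaces** in which shared substructure is built once and
reused across molecules, and from them the Jaccard-like similarity

```
JAO(A, B) = (MA_A + MA_B - MA_{A,B}) / MA_{A,B}  in [0, 1].
```

## Worked example

```python
from molassembly import parse_smiles, search

result = search(parse_smiles("OC(=O)c1ccccc1"))   # benzoic acid
print(result.ma, result.best_s, result.converged)
```

prints `6 2 True`: benzoic acid has 9 bonds, and one removal of a
duplicated 3-bond aromatic arc (saving 2 joins) is optimal, so
MA = 9 - 1 - 2 = 6.  The `examples/` scripts are short narrative
walk-throughs; `examples/jao_similarity.py` prints

```
ACD vs ADC: MA_A=10 MA_B=10 MA_joint=12  JAO=0.667 (exact=True)
STV vs SVT: MA_A=10 MA_B=11 MA_joint=13  JAO=0.615 (exact=True)
```

— transposed tripeptides share all residues, and two thirds of the
ACD/ADC joint construction is reusable, yet the JAO stays far below the
near-1 scores local fingerprint similarities give such pairs.
`examples/joint_space.py` and `examples/anytime_trace.py` show fragment
reuse across amino-acid sets and the anytime upper-bound trace on a joint
space too large to finish at desk scale.

## Command line

```
molassembly compute --smiles molecules.smi --json out.json
molassembly joint   --smiles set.smi
molassembly jao     --smiles pair.smi [--timeout 60] [--max-states N]
```

Exit code 0 means every search converged (exact results); 3 means a
budget was hit and the reported values are anytime upper bounds.

## Layout

* `molassembly.graph` — labeled molecular graphs, SMILES/MOL parsing,
  unique-bond preprocessing, edge-mask utilities
* `molassembly.canon` — tree canonization and VF2-style matching
* `molassembly.duplicates` — duplicatable-subgraph enumeration and DAG
* `molassembly.bounds` — addition chains and conditional chain bounds
* `molassembly.search` — the branch-and-bound/DP assembly search
* `molassembly.jointspace` / `molassembly.peptides` — joint spaces, JAO,
  peptide fixtures
* `molassembly.oracle` / `molassembly.fixtures` — brute-force reference
  and synthetic-graph generators backing the test suite

See `docs/methods.md` for the model, algorithmic choices and limitations.
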