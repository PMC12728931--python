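"""Joint assembly space of a small set of amino acids.

Building several molecules in one joint space lets shared substructures
(the alpha-amino-acid backbone, small alkyl fragments) be assembled once
and reused, so the joint assembly index is far below the sum of the
individual ones.  The compression ratio quantifies that reuse.
"""

from molassembly import (
    SearchConfig,
    compute_ma,
    joint_assembly_index,
    peptide_graph,
)

config = SearchConfig(track_pathway=False)
codes = ["G", "A", "S", "C", "D"]
mols = [peptide_graph(c) for c in codes]

individual = [compute_ma(m, config) for m in mols]
joint = joint_assembly_index(mols, config)

print("amino acids:", ", ".join(codes))
print("individual MAs:", individual, "sum =", sum(individual))
print(f"joint MA = {joint.ma} (exact: {joint.converged})")
print(f"compression = {1 - joint.ma / sum(individual):.0%} of the joining "
      "steps are saved by sharing fragments across molecules")
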