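"""Anytime behaviour on a joint space too large to finish at desk scale.

The search keeps a valid upper bound on the assembly index at all times:
every pathway found so far proves "buildable in this many steps".  On a
budget it returns the best bound with converged=False; given more budget
the bound only improves.  Here: the joint space of all 20 standard amino
acids under a small state budget.
"""

from molassembly import AMINO_ACIDS, SearchConfig, joint_assembly_index, parse_smiles

mols = [parse_smiles(s) for s in AMINO_ACIDS.values()]
result = joint_assembly_index(
    mols, SearchConfig(max_states=20_000, track_pathway=False)
)

print(f"20 amino acids jointly: {result.n_bonds} bonds in {result.n_components} molecules")
print(f"best upper bound on the joint MA: {result.ma} (converged: {result.converged})")
print("upper-bound trace (elapsed s, bound):")
for t, ub in result.trace[:10]:
    print(f"  {t:7.3f}  {ub}")
if len(result.trace) > 10:
    print(f"  ... {len(result.trace) - 10} more improvements, "
          f"final bound {result.trace[-1][1]}")
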