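"""Joint Assembly Overlap between transposed tripeptides.

JAO(A, B) = (MA_A + MA_B - MA_{A,B}) / MA_{A,B} compares how much of the
construction of two molecules can be shared: 1 for identical molecules, 0
when nothing is reusable.  Tripeptides with swapped residues share all
their residues but not their backbone order, so the JAO sits well below
the near-1 values that fingerprint similarities assign to such pairs.
"""

from molassembly import SearchConfig, jao, peptide_graph

config = SearchConfig(track_pathway=False)

for a, b in [("ACD", "ADC"), ("STV", "SVT")]:
    score = jao(peptide_graph(a), peptide_graph(b), config)
    print(
        f"{a} vs {b}: MA_A={score.ma_a} MA_B={score.ma_b} "
        f"MA_joint={score.ma_ab}  JAO={score.jao:.3f} (exact={score.exact})"
    )
print("A JAO of 0.667 means two thirds of the joint construction is shared.")
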