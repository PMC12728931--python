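"""Peptide fixtures: build linear peptides from one-letter residue codes.

Residues are assembled N-to-C with standard neutral topologies, free
termini (N-terminal amine, C-terminal carboxylic acid) and no
stereochemistry — the graphs are hydrogen-suppressed so protonation state
never enters the labels.  The embedded table makes tripeptide similarity
experiments reproducible without any external structure download.
"""

from __future__ import annotations

from .graph import LabelOptions, MolecularGraph, parse_smiles

__all__ = ["AMINO_ACIDS", "RESIDUE_SIDE_CHAINS", "peptide_smiles", "peptide_graph"]

#: Side-chain SMILES attached at the alpha carbon (empty for glycine;
#: proline is special-cased: its side chain closes a ring onto the backbone
#: nitrogen).
RESIDUE_SIDE_CHAINS: dict[str, str] = {
    "A": "C",
    "R": "CCCNC(=N)N",
    "N": "CC(N)=O",
    "D": "CC(=O)O",
    "C": "CS",
    "E": "CCC(=O)O",
    "Q": "CCC(N)=O",
    "G": "",
    "H": "Cc1c[nH]cn1",
    "I": "C(C)CC",
    "L": "CC(C)C",
    "K": "CCCCN",
    "M": "CCSC",
    "F": "Cc1ccccc1",
    "P": None,  # ring-closing special case
    "S": "CO",
    "T": "C(C)O",
    "W": "Cc1c[nH]c2ccccc12",
    "Y": "Cc1ccc(O)cc1",
    "V": "C(C)C",
}

#: Free amino acids (one-letter code -> SMILES), for joint-space experiments.
AMINO_ACIDS: dict[str, str] = {
    code: None for code in RESIDUE_SIDE_CHAINS  # filled below
}


def peptide_smiles(code: str) -> str:
    """SMILES of the linear peptide given by one-letter *code* (N to C)."""
    if not code:
        raise ValueError("empty peptide code")
    parts: list[str] = []
    for letter in code:
        letter = letter.upper()
        if letter not in RESIDUE_SIDE_CHAINS:
            raise ValueError(f"unknown residue code {letter!r}")
        if letter == "P":
            # Pyrrolidine ring: backbone N + 3 CH2 + alpha C.
            parts.append("N3CCCC3C(=O)")
        elif letter == "G":
            parts.append("NCC(=O)")
        else:
            parts.append(f"NC({RESIDUE_SIDE_CHAINS[letter]})C(=O)")
    return "".join(parts) + "O"


def peptide_graph(code: str, opts: LabelOptions | None = None) -> MolecularGraph:
    """Hydrogen-suppressed molecular graph of the peptide *code*."""
    return parse_smiles(peptide_smiles(code), opts)


for _code in list(AMINO_ACIDS):
    AMINO_ACIDS[_code] = peptide_smiles(_code)
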