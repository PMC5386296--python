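"""Residue naming and the 23-class contact alphabet.

The pair-potential alphabet extends the 20 standard amino acids with the
three phosphorylated classes pS, pT and pY, derived from the PDB residue
names SEP, TPO and PTR.
"""

from __future__ import annotations

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

#: phospho residue name -> unmodified one-letter code
PHOSPHO_RESNAMES = {"SEP": "S", "TPO": "T", "PTR": "Y"}

#: one-letter code -> phospho class label
PHOSPHO_CLASS = {"S": "pS", "T": "pT", "Y": "pY"}

STANDARD_AA = tuple(sorted(AA3_TO_1.values()))

#: ordered 23-class alphabet: 20 amino acids then pS, pT, pY
ALPHABET = STANDARD_AA + ("pS", "pT", "pY")

PHOSPHORYLATABLE = frozenset("STY")


def residue_class(aa: str, phospho: bool = False) -> str:
    """Return the contact-alphabet class of a residue.

    Parameters
    ----------
    aa : one-letter amino acid code of the 20 standard residues.
    phospho : whether the residue carries a phosphate; only S, T and Y
        may be phosphorylated.
    """
    if aa not in AA1_TO_3:
        raise ValueError(f"unknown amino acid code {aa!r}")
    if phospho:
        if aa not in PHOSPHO_CLASS:
            raise ValueError(f"residue {aa!r} cannot be phosphorylated")
        return PHOSPHO_CLASS[aa]
    return aa


def base_aa(cls: str) -> str:
    """Unmodified amino acid underlying an alphabet class (pS -> S)."""
    if cls in AA1_TO_3:
        return cls
    for aa, p in PHOSPHO_CLASS.items():
        if p == cls:
            return aa
    raise ValueError(f"unknown residue class {cls!r}")
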