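"""Residue and nucleotide alphabets, name tables and modified-component mapping.

The protein alphabet is the 20 standard amino acids; the RNA alphabet is the
four ribonucleotides A, C, G, U.  Everything else (modified components without
a parent mapping, unknown ligand-like residues inside a polymer) is collapsed
to the sentinel :data:`UNKNOWN`, which participates in contact geometry but is
excluded from all alphabet-indexed statistics.
"""

from __future__ import annotations

# Amino acids ordered hydrophobic -> polar -> charged, the customary ordering
# for interface-propensity tables.
AMINO_ACIDS: tuple[str, ...] = tuple("GAVLIPFWMSTCYQNDEKRH")
NUCLEOTIDES: tuple[str, ...] = ("A", "C", "G", "U")

#: Sentinel one-letter code for residues outside the standard alphabets.
UNKNOWN = "X"

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
NT_INDEX = {nt: i for i, nt in enumerate(NUCLEOTIDES)}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: Standard RNA component ids map to themselves.
RNA_COMPONENTS = {"A": "A", "C": "C", "G": "G", "U": "U"}

# Parent mapping for modified components commonly seen in tRNA-containing
# complexes, plus selenomethionine on the protein side.  Deliberately small:
# anything absent here becomes UNKNOWN rather than being guessed.
MODIFIED_PROTEIN_PARENT = {
    "MSE": "M",   # selenomethionine
    "SEP": "S",   # phosphoserine
    "TPO": "T",   # phosphothreonine
    "PTR": "Y",   # phosphotyrosine
    "CSO": "C",   # S-hydroxycysteine
    "CME": "C",   # S,S-(2-hydroxyethyl)thiocysteine
    "MLY": "K",   # N-dimethyllysine
    "HYP": "P",   # 4-hydroxyproline
}
MODIFIED_RNA_PARENT = {
    "PSU": "U",   # pseudouridine
    "H2U": "U",   # dihydrouridine
    "5MU": "U",   # ribothymidine (rT)
    "4SU": "U",   # 4-thiouridine
    "UR3": "U",   # 3-methyluridine
    "70U": "U",   # 5-methylaminomethyl-2-thiouridine
    "1MA": "A",   # 1-methyladenosine
    "MIA": "A",   # 2-methylthio-N6-isopentenyladenosine
    "T6A": "A",   # N6-threonylcarbamoyladenosine
    "2MA": "A",   # 2-methyladenosine
    "5MC": "C",   # 5-methylcytidine
    "OMC": "C",   # 2'-O-methylcytidine
    "1MG": "G",   # 1-methylguanosine
    "2MG": "G",   # N2-methylguanosine
    "M2G": "G",   # N2,N2-dimethylguanosine
    "7MG": "G",   # 7-methylguanosine
    "OMG": "G",   # 2'-O-methylguanosine
    "G7M": "G",   # N7-methylguanosine (5'-form)
    "QUO": "G",   # queuosine
    "YYG": "G",   # wybutosine
}


def map_modified_components(raw_code: str, kind: str) -> str:
    """Map a 3-character (or shorter) component id to its parent one-letter code.

    Parameters
    ----------
    raw_code
        Chemical-component id as found in the structure file (e.g. ``PSU``).
    kind
        ``"protein"`` or ``"rna"``.

    Returns
    -------
    str
        The parent standard one-letter code, or :data:`UNKNOWN` when no
        mapping is known.
    """
    code = raw_code.strip().upper()
    if kind == "protein":
        if code in THREE_TO_ONE:
            return THREE_TO_ONE[code]
        return MODIFIED_PROTEIN_PARENT.get(code, UNKNOWN)
    if kind == "rna":
        if code in RNA_COMPONENTS:
            return RNA_COMPONENTS[code]
        return MODIFIED_RNA_PARENT.get(code, UNKNOWN)
    raise ValueError(f"kind must be 'protein' or 'rna', got {kind!r}")


def is_modified(raw_code: str, kind: str) -> bool:
    """True when ``raw_code`` maps to a parent through the modification table."""
    code = raw_code.strip().upper()
    if kind == "protein":
        return code in MODIFIED_PROTEIN_PARENT
    return code in MODIFIED_RNA_PARENT
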