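"""Shared chemical/biological reference data.

Reference tables used across the package: Bondi van der Waals radii for
heavy atoms, theoretical maximum solvent accessibilities per residue type
(Tien et al. 2013, "theoretical" column), idealised heavy-atom compositions
of amino-acid side chains, and the universal genetic code.

Radii and max-SASA tables are defaults; both can be overridden from a file
where the public API accepts a ``radii`` / ``max_sasa`` mapping.
"""

from __future__ import annotations

# Bondi (1964) van der Waals radii, Å, heavy atoms + H for completeness.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
}

# Theoretical maximum SASA per residue type (Tien et al. 2013), Å².
MAX_SASA: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

# Heavy side-chain atoms per residue type, listed CB-outward. The synthetic
# generator lays these out as a linear chain (idealised composition, not
# real topology or rotamers).
SIDE_CHAIN_ATOMS: dict[str, tuple[str, ...]] = {
    "ALA": ("CB",),
    "ARG": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "ASN": ("CB", "CG", "OD1", "ND2"),
    "ASP": ("CB", "CG", "OD1", "OD2"),
    "CYS": ("CB", "SG"),
    "GLN": ("CB", "CG", "CD", "OE1", "NE2"),
    "GLU": ("CB", "CG", "CD", "OE1", "OE2"),
    "GLY": (),
    "HIS": ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "LYS": ("CB", "CG", "CD", "CE", "NZ"),
    "MET": ("CB", "CG", "SD", "CE"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("CB", "CG", "CD"),
    "SER": ("CB", "OG"),
    "THR": ("CB", "OG1", "CG2"),
    "TRP": ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "VAL": ("CB", "CG1", "CG2"),
}

AA3_TO_AA1: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_AA3: dict[str, str] = {v: k for k, v in AA3_TO_AA1.items()}

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
GAP: str = "-"
# Alphabet of the interface substitution matrix: 20 amino acids + gap.
MATRIX_ALPHABET: str = AMINO_ACIDS + GAP

_BASES = "TCAG"
_CODE = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"

# Universal genetic code; '*' marks stop codons.
GENETIC_CODE: dict[str, str] = {
    a + b + c: _CODE[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}
STOP_CODONS: frozenset[str] = frozenset(
    c for c, aa in GENETIC_CODE.items() if aa == "*"
)
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")
)
CODONS_FOR_AA: dict[str, tuple[str, ...]] = {
    aa: tuple(sorted(c for c, a in GENETIC_CODE.items() if a == aa))
    for aa in set(GENETIC_CODE.values())
    if aa != "*"
}

NUCLEOTIDES: str = "ACGT"


def element_of(atom_name: str) -> str:
    """Infer the element symbol from a PDB heavy-atom name.

    Works for standard amino-acid heavy atoms (and simple hydrogens),
    whose names begin with the element letter, e.g. ``NH1`` -> ``N``.
    """
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")
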