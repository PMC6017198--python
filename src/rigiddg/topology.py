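"""Residue-level chemistry tables for the 20 standard amino acids.

Covalent bond lists drive constraint-graph construction; the "locked" bond
sets mark partial-double/resonant bonds (peptide, carbonyl, carboxylate,
amide, guanidinium, aromatic rings) that allow no torsional rotation.
"""

from __future__ import annotations

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
STANDARD_AA1 = frozenset(ONE_TO_THREE)

# Atoms kept when a residue is truncated to glycine.
BACKBONE_ATOMS = frozenset({
    "N", "CA", "C", "O", "OXT",
    "H", "H1", "H2", "H3", "HN", "HA", "HA2", "HA3", "HXT",
})

# Heavy-atom bonds shared by every residue (OXT only on C-terminal residues).
_BACKBONE_BONDS = [("N", "CA"), ("CA", "C"), ("C", "O"), ("C", "OXT")]

_SIDECHAIN_BONDS = {
    "ALA": [("CA", "CB")],
    "ARG": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "NE"),
            ("NE", "CZ"), ("CZ", "NH1"), ("CZ", "NH2")],
    "ASN": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "ND2")],
    "ASP": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")],
    "CYS": [("CA", "CB"), ("CB", "SG")],
    "GLN": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"),
            ("CD", "NE2")],
    "GLU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"),
            ("CD", "OE2")],
    "GLY": [],
    "HIS": [("CA", "CB"), ("CB", "CG"), ("CG", "ND1"), ("CG", "CD2"),
            ("ND1", "CE1"), ("CD2", "NE2"), ("CE1", "NE2")],
    "ILE": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")],
    "LEU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")],
    "LYS": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "CE"),
            ("CE", "NZ")],
    "MET": [("CA", "CB"), ("CB", "CG"), ("CG", "SD"), ("SD", "CE")],
    "PHE": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ")],
    "PRO": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "N")],
    "SER": [("CA", "CB"), ("CB", "OG")],
    "THR": [("CA", "CB"), ("CB", "OG1"), ("CB", "CG2")],
    "TRP": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "NE1"), ("NE1", "CE2"), ("CD2", "CE2"), ("CD2", "CE3"),
            ("CE2", "CZ2"), ("CE3", "CZ3"), ("CZ2", "CH2"), ("CZ3", "CH2")],
    "TYR": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ"),
            ("CZ", "OH")],
    "VAL": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2")],
}

RESIDUE_BONDS = {
    res: _BACKBONE_BONDS + bonds for res, bonds in _SIDECHAIN_BONDS.items()
}

_RING_LOCKED = {
    "HIS": [("CG", "ND1"), ("CG", "CD2"), ("ND1", "CE1"), ("CD2", "NE2"),
            ("CE1", "NE2")],
    "PHE": [("CG", "CD1"), ("CG", "CD2"), ("CD1", "CE1"), ("CD2", "CE2"),
            ("CE1", "CZ"), ("CE2", "CZ")],
    "TRP": [("CG", "CD1"), ("CG", "CD2"), ("CD1", "NE1"), ("NE1", "CE2"),
            ("CD2", "CE2"), ("CD2", "CE3"), ("CE2", "CZ2"), ("CE3", "CZ3"),
            ("CZ2", "CH2"), ("CZ3", "CH2")],
    "TYR": [("CG", "CD1"), ("CG", "CD2"), ("CD1", "CE1"), ("CD2", "CE2"),
            ("CE1", "CZ"), ("CE2", "CZ")],
}
_PLANAR_LOCKED = {
    "ARG": [("NE", "CZ"), ("CZ", "NH1"), ("CZ", "NH2")],
    "ASN": [("CG", "OD1"), ("CG", "ND2")],
    "ASP": [("CG", "OD1"), ("CG", "OD2")],
    "GLN": [("CD", "OE1"), ("CD", "NE2")],
    "GLU": [("CD", "OE1"), ("CD", "OE2")],
}

# Carbonyl / carboxyl-terminus bonds are locked in every residue.
LOCKED_BONDS: dict[str, frozenset[frozenset[str]]] = {}
for _res in RESIDUE_BONDS:
    locked = [("C", "O"), ("C", "OXT")]
    locked += _RING_LOCKED.get(_res, [])
    locked += _PLANAR_LOCKED.get(_res, [])
    LOCKED_BONDS[_res] = frozenset(frozenset(b) for b in locked)

# Van der Waals radii by element (A); used for SASA and hydrophobic tethers.
VDW_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
             "P": 1.80, "SE": 1.90}
DEFAULT_VDW_RADIUS = 1.70

# Theoretical maximum solvent accessibility per residue type (Tien et al.
# theoretical values, A^2), the denominator of relative SASA.
MAX_SASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW_RADIUS)
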