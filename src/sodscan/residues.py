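"""Chemical reference tables for the 20 standard amino acids.

Covers van der Waals radii, chi-dihedral atom definitions, ideal
internal-coordinate recipes for side-chain construction, covalent
connectivity (for 1-2/1-3/1-4 contact exclusions) and hydrogen-bond
donor/acceptor chemistry. Values are conventional stereochemical-dictionary
numbers; the radius table follows Bondi.
"""

from __future__ import annotations

__all__ = [
    "DEFAULT_VDW_RADII",
    "CHI_ATOMS",
    "chi_count",
    "SIDECHAIN_RECIPES",
    "CB_PLACEMENT",
    "residue_bonds",
    "SIDECHAIN_DONORS",
    "SIDECHAIN_ACCEPTORS",
    "BACKBONE_DONOR",
    "BACKBONE_ACCEPTOR",
    "STANDARD_AA",
    "AA_THREE_TO_ONE",
]

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

AA_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_ONE_TO_THREE = {v: k for k, v in AA_THREE_TO_ONE.items()}

# Bondi radii for the elements routinely seen in protein crystal structures.
# Selenium (selenomethionine) is deliberately absent from the default table;
# pass an extended table to assign_vdw_radii for Se-containing entries.
DEFAULT_VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "ZN": 1.39,
    "CU": 1.40,
    "FE": 1.40,
    "MG": 1.73,
    "CA": 1.70,
    "MN": 1.40,
    "NA": 2.27,
    "K": 2.75,
}

# Four-atom definitions of the side-chain chi dihedrals, chi1 first.
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ALA": [],
    "GLY": [],
    "ARG": [
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "CD"),
        ("CB", "CG", "CD", "NE"),
        ("CG", "CD", "NE", "CZ"),
    ],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "CD"),
        ("CB", "CG", "CD", "OE1"),
    ],
    "GLU": [
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "CD"),
        ("CB", "CG", "CD", "OE1"),
    ],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "CD"),
        ("CB", "CG", "CD", "CE"),
        ("CG", "CD", "CE", "NZ"),
    ],
    "MET": [
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "SD"),
        ("CB", "CG", "SD", "CE"),
    ],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}


def chi_count(amino_acid: str) -> int:
    try:
        return len(CHI_ATOMS[amino_acid.upper()])
    except KeyError:
        raise KeyError(f"not a standard amino acid: {amino_acid!r}") from None


# CB placement from backbone atoms: torsion(C, N, CA, CB) fixed at the
# L-amino-acid value, tetrahedral N-CA-CB angle.
CB_PLACEMENT = {"refs": ("C", "N", "CA"), "length": 1.53, "angle": 110.5, "torsion": -122.6}

# Side-chain construction recipes beyond CB. Each entry places one heavy
# atom d from three already-placed reference atoms (a, b, c) with d bonded
# to c. torsion is either a fixed dihedral in degrees or ["chi", k, offset]
# meaning chi_k + offset. Lengths/angles are conventional ideal values.
_chi = lambda k, off=0.0: ("chi", k, off)  # noqa: E731

SIDECHAIN_RECIPES: dict[str, list[tuple]] = {
    "ALA": [],
    "GLY": [],
    "SER": [("OG", ("N", "CA", "CB"), 1.42, 111.1, _chi(1))],
    "CYS": [("SG", ("N", "CA", "CB"), 1.81, 114.4, _chi(1))],
    "THR": [
        ("OG1", ("N", "CA", "CB"), 1.43, 109.6, _chi(1)),
        ("CG2", ("N", "CA", "CB"), 1.52, 110.5, _chi(1, -122.0)),
    ],
    "VAL": [
        ("CG1", ("N", "CA", "CB"), 1.53, 110.5, _chi(1)),
        ("CG2", ("N", "CA", "CB"), 1.53, 110.5, _chi(1, 122.0)),
    ],
    "ILE": [
        ("CG1", ("N", "CA", "CB"), 1.53, 110.4, _chi(1)),
        ("CG2", ("N", "CA", "CB"), 1.53, 110.5, _chi(1, -122.0)),
        ("CD1", ("CA", "CB", "CG1"), 1.52, 113.8, _chi(2)),
    ],
    "LEU": [
        ("CG", ("N", "CA", "CB"), 1.53, 116.3, _chi(1)),
        ("CD1", ("CA", "CB", "CG"), 1.52, 110.5, _chi(2)),
        ("CD2", ("CA", "CB", "CG"), 1.52, 110.5, _chi(2, 122.0)),
    ],
    "ASP": [
        ("CG", ("N", "CA", "CB"), 1.52, 112.6, _chi(1)),
        ("OD1", ("CA", "CB", "CG"), 1.25, 118.4, _chi(2)),
        ("OD2", ("CA", "CB", "CG"), 1.25, 118.4, _chi(2, 180.0)),
    ],
    "ASN": [
        ("CG", ("N", "CA", "CB"), 1.52, 112.6, _chi(1)),
        ("OD1", ("CA", "CB", "CG"), 1.23, 120.8, _chi(2)),
        ("ND2", ("CA", "CB", "CG"), 1.33, 116.4, _chi(2, 180.0)),
    ],
    "GLU": [
        ("CG", ("N", "CA", "CB"), 1.52, 114.1, _chi(1)),
        ("CD", ("CA", "CB", "CG"), 1.52, 112.6, _chi(2)),
        ("OE1", ("CB", "CG", "CD"), 1.25, 118.4, _chi(3)),
        ("OE2", ("CB", "CG", "CD"), 1.25, 118.4, _chi(3, 180.0)),
    ],
    "GLN": [
        ("CG", ("N", "CA", "CB"), 1.52, 114.1, _chi(1)),
        ("CD", ("CA", "CB", "CG"), 1.52, 112.6, _chi(2)),
        ("OE1", ("CB", "CG", "CD"), 1.23, 120.8, _chi(3)),
        ("NE2", ("CB", "CG", "CD"), 1.33, 116.4, _chi(3, 180.0)),
    ],
    "MET": [
        ("CG", ("N", "CA", "CB"), 1.52, 114.1, _chi(1)),
        ("SD", ("CA", "CB", "CG"), 1.80, 112.7, _chi(2)),
        ("CE", ("CB", "CG", "SD"), 1.79, 100.9, _chi(3)),
    ],
    "LYS": [
        ("CG", ("N", "CA", "CB"), 1.52, 114.1, _chi(1)),
        ("CD", ("CA", "CB", "CG"), 1.52, 111.3, _chi(2)),
        ("CE", ("CB", "CG", "CD"), 1.52, 111.3, _chi(3)),
        ("NZ", ("CG", "CD", "CE"), 1.49, 111.9, _chi(4)),
    ],
    "ARG": [
        ("CG", ("N", "CA", "CB"), 1.52, 114.1, _chi(1)),
        ("CD", ("CA", "CB", "CG"), 1.52, 111.3, _chi(2)),
        ("NE", ("CB", "CG", "CD"), 1.46, 112.0, _chi(3)),
        ("CZ", ("CG", "CD", "NE"), 1.33, 124.2, _chi(4)),
        ("NH1", ("CD", "NE", "CZ"), 1.33, 120.0, 0.0),
        ("NH2", ("CD", "NE", "CZ"), 1.33, 120.0, 180.0),
    ],
    "HIS": [
        ("CG", ("N", "CA", "CB"), 1.49, 113.8, _chi(1)),
        ("ND1", ("CA", "CB", "CG"), 1.38, 122.7, _chi(2)),
        ("CD2", ("CA", "CB", "CG"), 1.35, 131.2, _chi(2, 180.0)),
        ("CE1", ("CB", "CG", "ND1"), 1.32, 109.3, 180.0),
        ("NE2", ("CG", "ND1", "CE1"), 1.32, 108.4, 0.0),
    ],
    "PHE": [
        ("CG", ("N", "CA", "CB"), 1.50, 113.8, _chi(1)),
        ("CD1", ("CA", "CB", "CG"), 1.39, 120.7, _chi(2)),
        ("CD2", ("CA", "CB", "CG"), 1.39, 120.7, _chi(2, 180.0)),
        ("CE1", ("CB", "CG", "CD1"), 1.39, 120.7, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.39, 120.7, 180.0),
        ("CZ", ("CG", "CD1", "CE1"), 1.39, 120.0, 0.0),
    ],
    "TYR": [
        ("CG", ("N", "CA", "CB"), 1.51, 113.9, _chi(1)),
        ("CD1", ("CA", "CB", "CG"), 1.39, 120.8, _chi(2)),
        ("CD2", ("CA", "CB", "CG"), 1.39, 120.8, _chi(2, 180.0)),
        ("CE1", ("CB", "CG", "CD1"), 1.39, 121.2, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.39, 121.2, 180.0),
        ("CZ", ("CG", "CD1", "CE1"), 1.38, 119.6, 0.0),
        ("OH", ("CD1", "CE1", "CZ"), 1.38, 119.9, 180.0),
    ],
    "TRP": [
        ("CG", ("N", "CA", "CB"), 1.50, 113.6, _chi(1)),
        ("CD1", ("CA", "CB", "CG"), 1.37, 126.9, _chi(2)),
        ("CD2", ("CA", "CB", "CG"), 1.43, 126.6, _chi(2, 180.0)),
        ("NE1", ("CB", "CG", "CD1"), 1.38, 110.2, 180.0),
        ("CE2", ("CG", "CD1", "NE1"), 1.37, 109.0, 0.0),
        ("CE3", ("CD1", "CG", "CD2"), 1.40, 133.9, 180.0),
        ("CZ2", ("CD1", "NE1", "CE2"), 1.40, 130.4, 180.0),
        ("CZ3", ("CG", "CD2", "CE3"), 1.39, 118.8, 180.0),
        ("CH2", ("NE1", "CE2", "CZ2"), 1.37, 117.5, 180.0),
    ],
    "PRO": [
        ("CG", ("N", "CA", "CB"), 1.49, 104.5, _chi(1)),
        ("CD", ("CA", "CB", "CG"), 1.51, 105.6, _chi(2)),
    ],
}

# Ring-closure and hetero bonds not implied by the construction recipes.
_EXTRA_BONDS: dict[str, list[tuple[str, str]]] = {
    "HIS": [("CD2", "NE2")],
    "PHE": [("CD2", "CE2"), ("CE2", "CZ")],
    "TYR": [("CD2", "CE2"), ("CE2", "CZ")],
    "TRP": [("CD2", "CE2"), ("CE3", "CZ3"), ("CZ3", "CH2"), ("CZ2", "CH2")],
    "PRO": [("CD", "N")],
}

_BACKBONE_BONDS = [("N", "CA"), ("CA", "C"), ("C", "O"), ("C", "OXT")]


def residue_bonds(amino_acid: str) -> list[tuple[str, str]]:
    """Covalent heavy-atom bonds within one residue (backbone + side chain)."""
    aa = amino_acid.upper()
    bonds = list(_BACKBONE_BONDS)
    if aa != "GLY":
        bonds.append(("CA", "CB"))
    for entry in SIDECHAIN_RECIPES.get(aa, []):
        name, refs = entry[0], entry[1]
        bonds.append((refs[2], name))
    bonds.extend(_EXTRA_BONDS.get(aa, []))
    return bonds


# Hydrogen-bond chemistry: donor/acceptor heavy atoms with their covalent
# antecedent (used for the angular criterion in heavy-atom mode).
BACKBONE_DONOR = ("N", "CA")
BACKBONE_ACCEPTOR = ("O", "C")

SIDECHAIN_DONORS: dict[str, list[tuple[str, str]]] = {
    "ARG": [("NE", "CD"), ("NH1", "CZ"), ("NH2", "CZ")],
    "ASN": [("ND2", "CG")],
    "CYS": [("SG", "CB")],
    "GLN": [("NE2", "CD")],
    "HIS": [("ND1", "CG"), ("NE2", "CE1")],
    "LYS": [("NZ", "CE")],
    "SER": [("OG", "CB")],
    "THR": [("OG1", "CB")],
    "TRP": [("NE1", "CD1")],
    "TYR": [("OH", "CZ")],
}

SIDECHAIN_ACCEPTORS: dict[str, list[tuple[str, str]]] = {
    "ASN": [("OD1", "CG")],
    "ASP": [("OD1", "CG"), ("OD2", "CG")],
    "GLN": [("OE1", "CD")],
    "GLU": [("OE1", "CD"), ("OE2", "CD")],
    "HIS": [("ND1", "CG"), ("NE2", "CE1")],
    "MET": [("SD", "CG")],
    "SER": [("OG", "CB")],
    "THR": [("OG1", "CB")],
    "TYR": [("OH", "CZ")],
}
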