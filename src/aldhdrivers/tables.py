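"""Bundled reference tables for amino-acid and atomic properties.

All tables cover exactly the 20 standard amino acids. Sources are the
standard textbook values used across structural bioinformatics: van der
Waals radii (Bondi), theoretical maximum accessible surface areas
(Tien et al. 2013), and isoelectric point / molecular weight / molecular
volume compilations.
"""

from __future__ import annotations

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Five-group side-chain classification.
AA_GROUP5 = {
    **{aa: "hydrophobic" for aa in "AFILMVWY"},
    **{aa: "polar" for aa in "NQST"},
    **{aa: "negative" for aa in "DE"},
    **{aa: "positive" for aa in "HKR"},
    **{aa: "special" for aa in "CGP"},
}
GROUP5_VOCAB = ("hydrophobic", "polar", "negative", "positive", "special")

# Seven-group classification used for neighbour-window frequencies.
NEIGHBOUR_GROUPS = {
    "hydrophobic": frozenset("ALM"),
    "aliphatic": frozenset("IV"),
    "aromatic": frozenset("FYW"),
    "long_polar": frozenset("EQKR"),
    "short_polar": frozenset("HSTC"),
    "short_charged_polar": frozenset("DN"),
    "structure_breaking": frozenset("GP"),
}

# Isoelectric point (pH units), molecular weight (Da), molecular volume (A^3).
AA_PROPERTIES = {
    "A": (6.00, 89.09, 88.6),
    "C": (5.07, 121.16, 108.5),
    "D": (2.77, 133.10, 111.1),
    "E": (3.22, 147.13, 138.4),
    "F": (5.48, 165.19, 189.9),
    "G": (5.97, 75.07, 60.1),
    "H": (7.59, 155.16, 153.2),
    "I": (6.02, 131.17, 166.7),
    "K": (9.74, 146.19, 168.6),
    "L": (5.98, 131.17, 166.7),
    "M": (5.74, 149.21, 162.9),
    "N": (5.41, 132.12, 114.1),
    "P": (6.30, 115.13, 112.7),
    "Q": (5.65, 146.15, 143.8),
    "R": (10.76, 174.20, 173.4),
    "S": (5.68, 105.09, 89.0),
    "T": (5.60, 119.12, 116.1),
    "V": (5.96, 117.15, 140.0),
    "W": (5.89, 204.23, 227.8),
    "Y": (5.66, 181.19, 193.6),
}

# Van der Waals radii by element (A).
VDW_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "P": 1.8, "H": 1.2}
DEFAULT_VDW_RADIUS = 1.7

# Theoretical maximum accessible surface area per residue type (A^2),
# used to normalise SASA into relative solvent accessibility.
MAX_ASA = {
    "A": 129.0, "C": 167.0, "D": 193.0, "E": 223.0, "F": 240.0,
    "G": 104.0, "H": 224.0, "I": 197.0, "K": 236.0, "L": 201.0,
    "M": 224.0, "N": 195.0, "P": 159.0, "Q": 225.0, "R": 274.0,
    "S": 155.0, "T": 172.0, "V": 174.0, "W": 285.0, "Y": 263.0,
}

PHARMACOPHORE_CLASSES = (
    "hydrophobic", "aromatic", "positive", "negative",
    "acceptor", "donor", "sulfur", "neutral",
)

# Explicit side-chain atom assignments; atoms not matched here fall through
# to element-based rules (S -> sulfur, C -> hydrophobic, else neutral).
_POSITIVE_ATOMS = {
    ("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("ARG", "CZ"), ("HIS", "ND1"), ("HIS", "NE2"),
}
_NEGATIVE_ATOMS = {
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
}
_AROMATIC_ATOMS = {
    ("PHE", a) for a in ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
} | {
    ("TYR", a) for a in ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
} | {
    ("TRP", a) for a in ("CG", "CD1", "CD2", "NE1", "CE2", "CE3",
                          "CZ2", "CZ3", "CH2")
} | {
    ("HIS", a) for a in ("CG", "CD2", "CE1")
}
_ACCEPTOR_ATOMS = {
    ("ASN", "OD1"), ("GLN", "OE1"), ("SER", "OG"), ("THR", "OG1"),
    ("TYR", "OH"),
}
_DONOR_ATOMS = {
    ("ASN", "ND2"), ("GLN", "NE2"),
}


def pharmacophore_class(resname: str, atom_name: str, element: str = "") -> str:
    """Assign one of the eight pharmacophore classes to an atom.

    Backbone N is a hydrogen-bond donor and backbone O an acceptor for
    every residue type; side-chain atoms use the explicit table above,
    and anything unmatched falls back to element rules.
    """
    resname = resname.upper()
    atom_name = atom_name.upper()
    element = (element or atom_name[:1]).upper()
    key = (resname, atom_name)
    if element == "S":
        return "sulfur"
    if key in _POSITIVE_ATOMS:
        return "positive"
    if key in _NEGATIVE_ATOMS:
        return "negative"
    if key in _AROMATIC_ATOMS:
        return "aromatic"
    if atom_name == "O" or atom_name == "OXT" or key in _ACCEPTOR_ATOMS:
        return "acceptor"
    if atom_name == "N" or key in _DONOR_ATOMS:
        return "donor"
    if element == "C":
        return "hydrophobic"
    return "neutral"
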