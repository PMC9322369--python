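"""Physical constants and residue tables shared across the package."""

# Gas constant in kcal/(mol K); 2.3*R*T at 300 K = 1.3712 kcal/mol.
R_KCAL = 0.0019872

# Coulomb constant in kcal A / (mol e^2).
COULOMB_K = 332.0637

BACKBONE_ATOMS = ("N", "CA", "C", "O", "H")

# Backbone partial charges (e) used for the main-chain/side-chain electrostatic
# coupling. Amide H is optional; most inputs lack it.
BACKBONE_PARTIAL_CHARGES = {"C": 0.4, "O": -0.4, "N": -0.2, "H": 0.2}

# vdW radii (A) for backbone atoms; pair minimum = r_side + r_backbone.
BACKBONE_VDW_RADII = {"N": 1.6, "CA": 1.8, "C": 1.7, "O": 1.5, "H": 1.0}

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

STANDARD_RESIDUES = frozenset(AA3_TO_1)

# Default residue classification: united side chains are nonpolar, polar, or
# ionizable. HIS is ionizable by default; the class table is configurable.
DEFAULT_RESIDUE_CLASSES = {
    "ALA": "nonpolar", "VAL": "nonpolar", "LEU": "nonpolar", "ILE": "nonpolar",
    "PHE": "nonpolar", "MET": "nonpolar", "TRP": "nonpolar", "PRO": "nonpolar",
    "GLY": "nonpolar",
    "SER": "polar", "THR": "polar", "ASN": "polar", "GLN": "polar",
    "TYR": "polar", "CYS": "polar",
    "ASP": "ionizable", "GLU": "ionizable",
    "LYS": "ionizable", "ARG": "ionizable", "HIS": "ionizable",
}

# Acid (-1) / base (+1) signs for ionizable residues.
IONIZABLE_SIGNS = {"ASP": -1, "GLU": -1, "LYS": 1, "ARG": 1, "HIS": 1}

# Intrinsic water pKa values (textbook defaults; only the shift
# pKa_intrinsic - pKa_water enters the folding electrostatics).
DEFAULT_PKA_WATER = {"ASP": 3.9, "GLU": 4.3, "HIS": 6.5, "LYS": 10.5, "ARG": 12.5}

# Per-residue vdW radius (A) of the united side-chain particle; pair minimum
# distance = r_i + r_j. Rough size ordering of side-chain volumes.
DEFAULT_SIDE_VDW_RADII = {
    "GLY": 1.2, "ALA": 1.6, "SER": 1.7, "CYS": 1.8, "THR": 1.8, "PRO": 1.9,
    "VAL": 1.9, "ASP": 1.9, "ASN": 1.9, "ILE": 2.0, "LEU": 2.0, "MET": 2.1,
    "GLN": 2.1, "GLU": 2.1, "HIS": 2.2, "LYS": 2.2, "PHE": 2.3, "ARG": 2.3,
    "TYR": 2.4, "TRP": 2.5,
}

# Distance (A) from CA to the side-chain heavy-atom centroid, used when
# synthesising ideal structures (approximate per-type values).
CA_TO_SIDE_CENTROID = {
    "ALA": 1.53, "SER": 1.90, "CYS": 2.07, "THR": 1.90, "VAL": 1.97,
    "LEU": 2.60, "ILE": 2.30, "PRO": 1.85, "MET": 2.95, "PHE": 3.40,
    "TYR": 3.80, "TRP": 3.90, "ASP": 2.46, "GLU": 3.10, "ASN": 2.50,
    "GLN": 3.10, "HIS": 3.10, "LYS": 3.50, "ARG": 4.10,
}
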