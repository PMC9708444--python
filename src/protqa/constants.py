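"""Embedded physical and chemical constants.

Everything here is standard reference data: amino-acid codes, van der
Waals radii, Engh-Huber-style ideal backbone geometry, Gly-X-Gly maximal
solvent accessibilities, and side-chain chi-angle atom definitions.
"""

from __future__ import annotations

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
STANDARD_AA = frozenset(AA3_TO_1)

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# Heavy-atom van der Waals radii (A).  Implicit-hydrogen values; the clash
# overlap threshold absorbs the missing H.
ELEMENT_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
DEFAULT_RADIUS = 1.70

# Theoretical Gly-X-Gly maximal accessible surface areas (A^2),
# Tien et al. 2013 theoretical set; used to normalise residue SASA.
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

# Ideal backbone covalent geometry (bond lengths in A, angles in degrees)
# with the spread used for covalent G-score z-values.
IDEAL_BOND_LENGTHS = {
    ("N", "CA"): 1.458,
    ("CA", "C"): 1.525,
    ("C", "N"): 1.329,   # peptide bond, C(i)-N(i+1)
    ("C", "O"): 1.231,
}
IDEAL_BOND_ANGLES = {
    ("N", "CA", "C"): 111.2,
    ("CA", "C", "N"): 116.2,  # CA(i)-C(i)-N(i+1)
    ("C", "N", "CA"): 121.7,  # C(i)-N(i+1)-CA(i+1)
}
SIGMA_BOND_LENGTH = 0.02   # A
SIGMA_BOND_ANGLE = 2.0     # degrees

# Carbonyl oxygen and CB placement (see decoygen.build_chain).
CA_C_O_ANGLE = 120.8
CA_CB_LENGTH = 1.529
N_CA_CB_ANGLE = 110.5
# Improper torsion C-N-CA-CB; -120 deg gives L-amino-acid chirality
# (checked against ideal residue templates).
C_N_CA_CB_TORSION = -120.0

# Chi-angle atom quadruples per residue type.  chi_k is the torsion over
# CHI_ATOMS[aa][k].  GLY and ALA have none.
CHI_ATOMS = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}

# Atom placed by the synthetic builder to realise chi1 (4th atom of the
# chi1 quadruple) and its CB-X bond length.
CHI1_STUB = {
    aa: quads[0][3] for aa, quads in CHI_ATOMS.items()
}
CHI1_STUB_LENGTH = {
    "SER": 1.417, "THR": 1.433, "CYS": 1.808,
}
CHI1_STUB_LENGTH_DEFAULT = 1.530  # C-C
CB_CB_X_ANGLE = 114.0

# Coarse modal chi1 per residue type (degrees) used to stub side chains in
# the synthetic builder: gauche-minus for most types, the common exceptions
# listed explicitly.
MODAL_CHI1 = {
    "SER": 64.0, "THR": 62.0, "VAL": 175.0, "ILE": -65.0, "PRO": 30.0,
}
MODAL_CHI1_DEFAULT = -65.0

# Chain-break heuristic: peptide C(i)-N(i+1) distance beyond this is a break.
CHAIN_BREAK_CN = 2.5  # A

GDT_CUTOFFS = (1.0, 2.0, 4.0, 8.0)
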