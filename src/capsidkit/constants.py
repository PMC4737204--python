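"""Physical constants, unit conversions, and per-element/per-residue tables.

All coordinates are orthogonal angstroms; energies are kcal/mol; the only
places other units appear (J, m^3, GPa) are the compressibility conversions
collected here.
"""

from __future__ import annotations

# --- thermodynamic constants -------------------------------------------------

#: Boltzmann constant, kcal mol^-1 K^-1 (molar form, for energies per mole)
KB_KCAL_MOL_K = 1.98720425864e-3

#: Boltzmann constant, J K^-1 (absolute form, for single-system fluctuations)
KB_J_K = 1.380649e-23

#: cubic angstrom -> cubic metre
A3_TO_M3 = 1e-30

#: Pa^-1 -> GPa^-1
INV_PA_TO_INV_GPA = 1e9

#: kcal/mol -> J (per molecule): 4184 J/kcal / Avogadro
KCAL_MOL_TO_J = 4184.0 / 6.02214076e23

#: default simulation temperature, K
DEFAULT_TEMPERATURE_K = 300.0

# --- atomic data --------------------------------------------------------------

#: van der Waals radii (angstrom), element symbols upper-case.
#: Bondi-style values; the set covers everything found in protein PDB files.
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "NA": 2.27,
    "MG": 1.73,
    "K": 2.75,
    "CA": 2.31,
    "ZN": 1.39,
    "FE": 1.40,
    "MN": 1.40,
}

#: atomic masses (Da)
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
    "F": 18.998,
    "CL": 35.45,
    "BR": 79.904,
    "I": 126.904,
    "NA": 22.990,
    "MG": 24.305,
    "K": 39.098,
    "CA": 40.078,
    "ZN": 65.38,
    "FE": 55.845,
    "MN": 54.938,
}

#: average residue masses (Da) of amino-acid residues *in a chain*
#: (monoisotopic-free, water already removed); used for sequence-based
#: molecular weights when only backbone coordinates are available.
RESIDUE_MASSES = {
    "ALA": 71.0788, "ARG": 156.1875, "ASN": 114.1038, "ASP": 115.0886,
    "CYS": 103.1388, "GLN": 128.1307, "GLU": 129.1155, "GLY": 57.0519,
    "HIS": 137.1411, "ILE": 113.1594, "LEU": 113.1594, "LYS": 128.1741,
    "MET": 131.1926, "PHE": 147.1766, "PRO": 97.1167, "SER": 87.0782,
    "THR": 101.1051, "TRP": 186.2132, "TYR": 163.1760, "VAL": 99.1326,
}

#: mass of one water molecule (Da), added once per chain for the termini
WATER_MASS = 18.0153

#: 1-letter <-> 3-letter amino-acid codes
AA_1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AA_3TO1 = {v: k for k, v in AA_1TO3.items()}

#: residue names classified as water
WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP3"})

# --- dodecahedron geometry ----------------------------------------------------

# Face normals of two adjacent dodecahedron faces subtend arccos(1/sqrt(5)).
# The inradius r and the distance d between adjacent face centers (all at
# radius r along their normals) satisfy d = 2 r sin(theta/2).
import math

FACE_ANGLE = math.acos(1.0 / math.sqrt(5.0))
#: d/r for adjacent dodecahedron face centers at inradius r
NEIGHBOR_DISTANCE_OVER_INRADIUS = 2.0 * math.sin(FACE_ANGLE / 2.0)
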