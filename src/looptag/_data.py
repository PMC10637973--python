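"""Static chemistry tables used across the package.

All values are standard reference data: three-to-one letter residue codes,
average residue masses, van der Waals radii, per-residue maximum solvent
accessibilities (theoretical Gly-X-Gly values, Tien et al. 2013), and the
polar/charged atom templates used for contact detection.
"""

from __future__ import annotations

# Three-letter -> one-letter for the 20 standard amino acids.
AA3_TO_1: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

AA1_TO_3: dict[str, str] = {v: k for k, v in AA3_TO_1.items()}

# Common modified residues mapped to their parent standard residue.
MODIFIED_PARENT: dict[str, str] = {
    "MSE": "MET",  # selenomethionine
    "SEC": "CYS",  # selenocysteine (closest structural parent for sequence use)
    "PYL": "LYS",
    "SEP": "SER", "TPO": "THR", "PTR": "TYR",  # phosphorylated
    "CSO": "CYS", "OCS": "CYS", "CME": "CYS",
    "MLY": "LYS", "KCX": "LYS",
    "HYP": "PRO",
    "FME": "MET",
}

WATER_CODES = frozenset({"HOH", "DOD", "WAT"})

# Nucleotide residue codes (to detect non-protein polymers).
NUCLEOTIDE_CODES = frozenset({
    "A", "C", "G", "U", "I", "DA", "DC", "DG", "DT", "DU", "DI",
})

AMINO_ACID_CODES = frozenset(AA3_TO_1) | frozenset(MODIFIED_PARENT)

# Average (isotope-abundance weighted) masses of the free amino acids, Da.
# Peptide mass = sum(residue) - (n-1) * water.
AVG_AA_MASS: dict[str, float] = {
    "A": 89.09, "R": 174.20, "N": 132.12, "D": 133.10, "C": 121.16,
    "Q": 146.15, "E": 147.13, "G": 75.07, "H": 155.15, "I": 131.17,
    "L": 131.17, "K": 146.19, "M": 149.21, "F": 165.19, "P": 115.13,
    "S": 105.09, "T": 119.12, "W": 204.23, "Y": 181.19, "V": 117.15,
}
WATER_MASS = 18.02
UNKNOWN_AA_MASS = 110.0  # generic residue mass for 'X'

# Van der Waals radii (Bondi), Å; used by the accessibility sampler.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "D": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "SE": 1.90, "ZN": 1.39, "CD": 1.58, "MG": 1.73, "CA": 2.31,
    "NA": 2.27, "K": 2.75, "FE": 1.56, "MN": 1.61, "CU": 1.40,
}
DEFAULT_VDW_RADIUS = 1.70

# Theoretical maximum accessible surface per residue type (Å²),
# Tien et al. 2013, used for relative-SASA exposure calls.
MAX_SASA: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}
DEFAULT_MAX_SASA = 200.0

# Hydrogen-bond capable heavy atoms per residue (side chains; the backbone
# amide N is a donor and carbonyl O an acceptor for every residue).
SIDECHAIN_DONORS: dict[str, tuple[str, ...]] = {
    "ARG": ("NE", "NH1", "NH2"),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "HIS": ("ND1", "NE2"),
    "LYS": ("NZ",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TRP": ("NE1",),
    "TYR": ("OH",),
}
SIDECHAIN_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "ASN": ("OD1",),
    "ASP": ("OD1", "OD2"),
    "GLN": ("OE1",),
    "GLU": ("OE1", "OE2"),
    "HIS": ("ND1", "NE2"),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
}

# Charged groups for salt-bridge detection.
BASIC_ATOMS: dict[str, tuple[str, ...]] = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
}
ACIDIC_ATOMS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}

BASIC_RESIDUES = frozenset(BASIC_ATOMS)
ACIDIC_RESIDUES = frozenset(ACIDIC_ATOMS)

VALID_AA1 = frozenset(AA1_TO_3) | {"X"}
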