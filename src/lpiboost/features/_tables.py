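"""Residue property tables used by the protein descriptors.

All tables are keyed by one-letter amino-acid codes over the 20 standard
residues.  Autocorrelation scales are standardised (mean 0, sd 1 across the
20 residues) before use, so only their relative spacing matters.
"""

from __future__ import annotations

import numpy as np

AA = "ACDEFGHIKLMNPQRSTVWY"  # lexicographic one-letter order
AA_INDEX = {a: i for i, a in enumerate(AA)}

# --- Scales used for pseudo amino-acid composition and the physicochemical
# residue distance (hydrophobicity, Hopp-Woods hydrophilicity, side-chain
# mass), the standard triplet for sequence-order correlation factors.
HYDROPHOBICITY = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19,
    "G": 0.48, "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06,
    "M": 0.64, "N": -0.78, "P": 0.12, "Q": -0.85, "R": -2.53,
    "S": -0.18, "T": -0.05, "V": 1.08, "W": 0.81, "Y": 0.26,
}
HYDROPHILICITY = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5,
    "G": 0.0, "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8,
    "M": -1.3, "N": 0.2, "P": 0.0, "Q": 0.2, "R": 3.0,
    "S": 0.3, "T": -0.4, "V": -1.5, "W": -3.4, "Y": -2.3,
}
SIDE_CHAIN_MASS = {
    "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0,
    "G": 1.0, "H": 82.0, "I": 57.0, "K": 73.0, "L": 57.0,
    "M": 75.0, "N": 58.0, "P": 42.0, "Q": 72.0, "R": 101.0,
    "S": 31.0, "T": 45.0, "V": 43.0, "W": 130.0, "Y": 107.0,
}

# --- Eight physicochemical scales for the autocorrelation descriptors
# (240 = 8 scales x 30 lags per statistic).
FLEXIBILITY = {
    "A": 0.357, "C": 0.346, "D": 0.511, "E": 0.497, "F": 0.314,
    "G": 0.544, "H": 0.323, "I": 0.462, "K": 0.466, "L": 0.365,
    "M": 0.295, "N": 0.463, "P": 0.509, "Q": 0.493, "R": 0.529,
    "S": 0.507, "T": 0.444, "V": 0.386, "W": 0.305, "Y": 0.420,
}
POLARIZABILITY = {
    "A": 0.046, "C": 0.128, "D": 0.105, "E": 0.151, "F": 0.290,
    "G": 0.000, "H": 0.230, "I": 0.186, "K": 0.219, "L": 0.186,
    "M": 0.221, "N": 0.134, "P": 0.131, "Q": 0.180, "R": 0.291,
    "S": 0.062, "T": 0.108, "V": 0.140, "W": 0.409, "Y": 0.298,
}
FREE_ENERGY_SOLUTION = {
    "A": -0.368, "C": 4.530, "D": 2.060, "E": 1.770, "F": 1.060,
    "G": -0.525, "H": 0.000, "I": 0.791, "K": 0.000, "L": 1.070,
    "M": 0.656, "N": 0.000, "P": -2.240, "Q": 0.731, "R": -1.030,
    "S": -0.524, "T": 0.000, "V": 0.401, "W": 1.600, "Y": 4.910,
}
ACCESSIBLE_SURFACE_AREA = {
    "A": 115.0, "C": 135.0, "D": 150.0, "E": 190.0, "F": 210.0,
    "G": 75.0, "H": 195.0, "I": 175.0, "K": 200.0, "L": 170.0,
    "M": 185.0, "N": 160.0, "P": 145.0, "Q": 180.0, "R": 225.0,
    "S": 115.0, "T": 140.0, "V": 155.0, "W": 255.0, "Y": 230.0,
}
RESIDUE_VOLUME = {
    "A": 52.6, "C": 68.3, "D": 68.4, "E": 84.7, "F": 113.9,
    "G": 36.3, "H": 91.9, "I": 102.0, "K": 105.1, "L": 102.0,
    "M": 97.7, "N": 75.7, "P": 73.6, "Q": 89.7, "R": 109.1,
    "S": 54.9, "T": 71.2, "V": 85.1, "W": 135.4, "Y": 116.2,
}
STERIC_PARAMETER = {
    "A": 0.52, "C": 0.62, "D": 0.76, "E": 0.68, "F": 0.70,
    "G": 0.00, "H": 0.70, "I": 1.02, "K": 0.68, "L": 0.98,
    "M": 0.78, "N": 0.76, "P": 0.36, "Q": 0.68, "R": 0.68,
    "S": 0.53, "T": 0.50, "V": 0.76, "W": 0.70, "Y": 0.70,
}

AUTOCORRELATION_SCALES = {
    "hydrophobicity": HYDROPHOBICITY,
    "hydrophilicity": HYDROPHILICITY,
    "flexibility": FLEXIBILITY,
    "polarizability": POLARIZABILITY,
    "free_energy_solution": FREE_ENERGY_SOLUTION,
    "accessible_surface_area": ACCESSIBLE_SURFACE_AREA,
    "residue_volume": RESIDUE_VOLUME,
    "steric_parameter": STERIC_PARAMETER,
}

# --- Composition/transition/distribution: seven physicochemical groupings,
# three classes each, partitioning the 20 residues.
CTD_GROUPS = {
    "hydrophobicity": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "vdw_volume": ("GASTPDC", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "secondary_structure": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solvent_accessibility": ("ALFCGIVW", "RKQEND", "MSPTHY"),
}

# --- Conjoint-triad classes (dipole / side-chain volume clustering).
CONJOINT_CLASSES = ("AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C")

# --- Grantham (1974) residue composition, polarity and volume, with the
# published weights; distances are scaled so that Leu-Ile comes out at 5 and
# the matrix mean sits near 100.
_GRANTHAM_C = {
    "A": 0.0, "C": 2.75, "D": 1.38, "E": 0.92, "F": 0.0,
    "G": 0.74, "H": 0.58, "I": 0.0, "K": 0.33, "L": 0.0,
    "M": 0.0, "N": 1.33, "P": 0.39, "Q": 0.89, "R": 0.65,
    "S": 1.42, "T": 0.71, "V": 0.0, "W": 0.13, "Y": 0.20,
}
_GRANTHAM_P = {
    "A": 8.1, "C": 5.5, "D": 13.0, "E": 12.3, "F": 5.2,
    "G": 9.0, "H": 10.4, "I": 5.2, "K": 11.3, "L": 4.9,
    "M": 5.7, "N": 11.6, "P": 8.0, "Q": 10.5, "R": 10.5,
    "S": 9.2, "T": 8.6, "V": 5.9, "W": 5.4, "Y": 6.2,
}
_GRANTHAM_V = {
    "A": 31.0, "C": 55.0, "D": 54.0, "E": 83.0, "F": 132.0,
    "G": 3.0, "H": 96.0, "I": 111.0, "K": 119.0, "L": 111.0,
    "M": 105.0, "N": 56.0, "P": 32.5, "Q": 85.0, "R": 124.0,
    "S": 32.0, "T": 61.0, "V": 84.0, "W": 170.0, "Y": 136.0,
}
_GRANTHAM_ALPHA = 1.833
_GRANTHAM_BETA = 0.1018
_GRANTHAM_GAMMA = 0.000399
_GRANTHAM_SCALE = 50.723


def scale_vector(table: dict[str, float], standardize: bool = True
                 ) -> np.ndarray:
    """Residue table as a vector in canonical order, optionally z-scored
    over the 20 residues (population sd)."""
    v = np.array([table[a] for a in AA], dtype=float)
    if standardize:
        v = (v - v.mean()) / v.std()
    return v


def grantham_distance_matrix() -> np.ndarray:
    """20x20 Grantham chemical distance (symmetric, zero diagonal)."""
    c = scale_vector(_GRANTHAM_C, standardize=False)
    p = scale_vector(_GRANTHAM_P, standardize=False)
    v = scale_vector(_GRANTHAM_V, standardize=False)
    d2 = (_GRANTHAM_ALPHA * np.subtract.outer(c, c) ** 2
          + _GRANTHAM_BETA * np.subtract.outer(p, p) ** 2
          + _GRANTHAM_GAMMA * np.subtract.outer(v, v) ** 2)
    return _GRANTHAM_SCALE * np.sqrt(d2)


def physicochemical_distance_matrix() -> np.ndarray:
    """20x20 composite residue distance built from z-scored hydrophobicity,
    hydrophilicity and side-chain mass (euclidean over the three scales,
    divided by sqrt(3) so a one-sd difference on every scale gives 1)."""
    scales = [scale_vector(HYDROPHOBICITY),
              scale_vector(HYDROPHILICITY),
              scale_vector(SIDE_CHAIN_MASS)]
    d2 = sum(np.subtract.outer(s, s) ** 2 for s in scales)
    return np.sqrt(d2 / 3.0)
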