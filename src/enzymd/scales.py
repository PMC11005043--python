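"""Per-residue physicochemical scale tables.

Ten canonical multi-component scale families (66 components in total) drive
the scale-based sequence descriptors: BLOSUM indices (10), Cruciani
properties (3), FASGAI vectors (6), Kidera factors (10), MS-WHIM scores (3),
ProtFP (8), ST-scales (8), T-scales (5), VHSE scales (8) and zScales (5).
The zScales, Kidera, VHSE, MS-WHIM, Cruciani and FASGAI tables are
transcribed from the literature; the ProtFP, ST-scale, T-scale and
BLOSUM-index tables are synthetic reconstructions (seeded orthogonal
rotations of the principal components of the transcribed tables, at the
published dimensionalities), marked as such below.  The pipeline min-max
rescales every feature before modelling, so the tables' role is to give
each residue a reproducible, physicochemically coherent embedding.

The module also carries the scalar tables used by the global properties and
pocket chemistry: Kyte-Doolittle hydropathy, Radzicka-Wolfenden transfer
free energies (Boman index), average residue masses and the EMBOSS pKa set.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Kyte & Doolittle hydropathy
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

# Radzicka & Wolfenden water->cyclohexane transfer free energies (kcal/mol);
# the Boman (protein-binding potential) index is -mean over residues.
TRANSFER_FREE_ENERGY = {
    "A": 1.81, "R": -14.92, "N": -6.64, "D": -8.72, "C": 1.28, "Q": -5.54,
    "E": -6.81, "G": 0.94, "H": -4.66, "I": 4.92, "L": 4.92, "K": -5.55,
    "M": 2.35, "F": 2.98, "P": 0.0, "S": -3.40, "T": -2.57, "W": -2.33,
    "Y": -0.14, "V": 4.04,
}

# Average (isotope-weighted) residue masses, Da; peptide MW = sum + one water.
RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MASS = 18.0153

# EMBOSS pKa set for net-charge / isoelectric-point calculations.
PKA_EMBOSS = {
    "Nterm": 8.6, "Cterm": 3.6,
    "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5, "K": 10.8, "R": 12.5, "Y": 10.1,
}
POSITIVE_PKA = ("Nterm", "K", "R", "H")
NEGATIVE_PKA = ("Cterm", "D", "E", "C", "Y")

# Aliphatic index relative side-chain volumes (Ikai 1980).
ALIPHATIC_A, ALIPHATIC_B = 2.9, 3.9

# ---------------------------------------------------------------------------
# Multi-component scale families.  Keys are 1-letter residue codes; each
# value tuple has the family's fixed dimensionality.
# ---------------------------------------------------------------------------

Z_SCALES = {  # Sandberg et al. 1998, 5 components
    "A": (0.24, -2.32, 0.60, -0.14, 1.30),
    "R": (3.52, 2.50, -3.50, 1.99, -0.17),
    "N": (3.05, 1.62, 1.04, -1.15, 1.61),
    "D": (3.98, 0.93, 1.93, -2.46, 0.75),
    "C": (0.84, -1.67, 3.71, 0.18, -2.65),
    "Q": (1.75, 0.50, -1.44, -1.34, 0.66),
    "E": (3.11, 0.26, -0.11, -0.34, -0.25),
    "G": (2.05, -4.06, 0.36, -0.82, -0.38),
    "H": (2.47, 1.95, 0.26, 3.90, 0.09),
    "I": (-3.89, -1.73, -1.71, -0.84, 0.26),
    "L": (-4.28, -1.30, -1.49, -0.72, 0.84),
    "K": (2.29, 0.89, -2.49, 1.49, 0.31),
    "M": (-2.85, -0.22, 0.47, 1.94, -0.98),
    "F": (-4.22, 1.94, 1.06, 0.54, -0.62),
    "P": (-1.66, 0.27, 1.84, 0.70, 2.00),
    "S": (2.39, -1.07, 1.15, -1.39, 0.67),
    "T": (0.75, -2.18, -1.12, -1.46, -0.40),
    "W": (-4.36, 3.94, 0.59, 3.44, -1.59),
    "Y": (-2.54, 2.44, 0.43, 0.04, -1.47),
    "V": (-2.59, -2.64, -1.54, -0.85, -0.02),
}

KIDERA = {  # Kidera et al. 1985, 10 orthogonal factors
    "A": (-1.56, -1.67, -0.97, -0.27, -0.93, -0.78, -0.20, -0.08, 0.21, -0.48),
    "R": (0.22, 1.27, 1.37, 1.87, -1.70, 0.46, 0.92, -0.39, 0.23, 0.93),
    "N": (1.14, -0.07, -0.12, 0.81, 0.18, 0.37, -0.09, 1.23, 1.10, -1.73),
    "D": (0.58, -0.22, -1.58, 0.81, -0.92, 0.15, -1.52, 0.47, 0.76, 0.70),
    "C": (0.12, -0.89, 0.45, -1.05, -0.71, 2.41, 1.52, -0.69, 1.13, 1.10),
    "Q": (-0.47, 0.24, 0.07, 1.10, 1.10, 0.59, 0.84, -0.71, -0.03, -2.33),
    "E": (-1.45, 0.19, -1.61, 1.17, -1.31, 0.40, 0.04, 0.38, -0.35, -0.12),
    "G": (1.46, -1.96, -0.23, -0.16, 0.10, -0.11, 1.32, 2.36, -1.66, 0.46),
    "H": (-0.41, 0.52, -0.28, 0.28, 1.61, 1.01, -1.85, 0.47, 1.13, 1.63),
    "I": (-0.73, -0.16, 1.79, -0.77, -0.54, 0.03, -0.83, 0.51, 0.66, -1.78),
    "L": (-1.04, 0.00, -0.24, -1.10, -0.55, -2.05, 0.96, -0.76, 0.45, 0.93),
    "K": (-0.34, 0.82, -0.23, 1.70, 1.54, -1.62, 1.15, -0.08, -0.48, 0.60),
    "M": (-1.40, 0.18, -0.42, -0.73, 2.00, 1.52, 0.26, 0.11, -1.27, 0.27),
    "F": (-0.21, 0.98, -0.36, -1.43, 0.22, -0.81, 0.67, 1.10, 1.71, -0.44),
    "P": (2.06, -0.33, -1.15, -0.75, 0.88, -0.45, 0.30, -2.30, 0.74, -0.28),
    "S": (0.81, -1.08, 0.16, 0.42, -0.21, -0.43, -1.89, -1.15, -0.97, -0.23),
    "T": (0.26, -0.70, 1.21, 0.63, -0.10, 0.21, 0.24, -1.15, -0.56, 0.19),
    "W": (0.30, 2.10, -0.72, -1.57, -1.16, 0.57, -0.48, -0.40, -2.30, -0.60),
    "Y": (1.38, 1.48, 0.80, -0.56, 0.00, -0.68, -0.31, 1.03, -0.05, 0.53),
    "V": (-0.74, -0.71, 2.04, -0.40, 0.50, -0.81, -1.07, 0.06, -0.46, 0.65),
}

VHSE = {  # Mei et al. 2005, 8 components
    "A": (0.15, -1.11, -1.35, -0.92, 0.02, -0.91, 0.36, -0.48),
    "R": (-1.47, 1.45, 1.24, 1.27, 1.55, 1.47, 1.30, 0.83),
    "N": (-0.99, 0.00, -0.37, 0.69, -0.55, 0.85, 0.73, -0.80),
    "D": (-1.15, 0.67, -0.41, -0.01, -2.68, 1.31, 0.03, 0.56),
    "C": (0.18, -1.67, -0.46, -0.21, 0.00, 1.20, -1.61, -0.19),
    "Q": (-0.96, 0.12, 0.18, 0.16, 0.09, 0.42, -0.20, -0.41),
    "E": (-1.18, 0.40, 0.10, 0.36, -2.16, -0.17, 0.91, 0.02),
    "G": (-0.20, -1.53, -2.63, 2.28, -0.53, -1.18, 2.01, -1.34),
    "H": (-0.43, -0.25, 0.37, 0.19, 0.51, 1.28, 0.93, 0.65),
    "I": (1.27, -0.14, 0.30, -1.80, 0.30, -1.61, -0.16, -0.13),
    "L": (1.36, 0.07, 0.26, -0.80, 0.22, -1.37, 0.08, -0.62),
    "K": (-1.17, 0.70, 0.70, 0.80, 1.64, 0.67, 1.63, 0.13),
    "M": (1.01, -0.53, 0.43, 0.00, 0.23, 0.10, -0.86, -0.68),
    "F": (1.52, 0.61, 0.96, -0.16, 0.25, 0.28, -1.33, -0.20),
    "P": (0.22, -0.17, -0.50, 0.05, -0.01, -1.34, -0.19, 3.56),
    "S": (-0.67, -0.86, -1.07, -0.41, -0.32, 0.27, -0.64, 0.11),
    "T": (-0.34, -0.51, -0.55, -1.06, -0.06, -0.01, -0.79, 0.39),
    "W": (1.50, 2.06, 1.79, 0.75, 0.75, -0.13, -1.01, -0.85),
    "Y": (0.61, 1.60, 1.17, 0.73, 0.53, 0.25, -0.96, -0.52),
    "V": (0.76, -0.92, -0.17, -1.91, 0.22, -1.40, -0.24, -0.03),
}

MS_WHIM = {  # Zaliani & Gancia 1999, 3 components
    "A": (-0.73, 0.20, -0.62),
    "R": (-0.22, 0.27, 1.00),
    "N": (0.14, 0.20, -0.66),
    "D": (0.11, -1.00, -0.96),
    "C": (-0.66, 0.26, -0.27),
    "Q": (0.30, 1.00, -0.30),
    "E": (0.24, -0.39, -0.04),
    "G": (-0.31, -0.28, -0.75),
    "H": (0.84, 0.67, -0.78),
    "I": (-0.91, 0.83, -0.25),
    "L": (-0.74, 0.72, -0.16),
    "K": (-0.51, 0.08, 0.60),
    "M": (-0.70, 1.00, -0.32),
    "F": (0.76, 0.85, -0.34),
    "P": (-0.43, 0.73, -0.60),
    "S": (-0.80, 0.61, -1.00),
    "T": (-0.58, 0.85, -0.89),
    "W": (1.00, 0.98, -0.47),
    "Y": (0.97, 0.66, -0.16),
    "V": (-1.00, 0.79, -0.58),
}

CRUCIANI = {  # Cruciani et al. 2004: polarity, hydrophobicity, H-bonding
    "A": (-0.96, -0.76, 0.31),
    "R": (0.80, 0.63, 0.99),
    "N": (0.82, -0.57, 0.02),
    "D": (1.00, -0.89, -1.00),
    "C": (-0.55, -0.47, -0.25),
    "Q": (0.75, -0.41, 0.13),
    "E": (0.94, -0.54, -0.90),
    "G": (-0.88, -1.00, 0.49),
    "H": (0.67, 0.49, 0.37),
    "I": (-0.94, 0.24, -0.20),
    "L": (-1.00, 0.21, -0.33),
    "K": (0.60, 0.10, 1.00),
    "M": (-0.82, 0.26, -0.41),
    "F": (-0.85, 0.48, -0.58),
    "P": (-0.81, -0.40, -0.07),
    "S": (-0.11, -0.80, 0.28),
    "T": (-0.26, -0.70, 0.21),
    "W": (-0.60, 1.00, -0.48),
    "Y": (-0.23, 0.80, -0.36),
    "V": (-1.00, -0.03, -0.29),
}

FASGAI = {  # Liang & Li 2007, 6 factors
    "A": (-0.17, 0.30, -0.44, -0.48, -0.13, -0.39),
    "R": (0.36, 0.76, 0.67, 1.20, 0.99, 0.46),
    "N": (0.68, -0.02, -0.28, 0.45, -0.07, -0.29),
    "D": (0.79, -0.30, -0.54, 0.58, -0.76, -0.25),
    "C": (-0.33, -0.70, 0.09, -0.28, 0.04, 1.02),
    "Q": (0.40, 0.37, 0.13, 0.49, 0.35, -0.33),
    "E": (0.64, 0.12, -0.26, 0.62, -0.62, -0.49),
    "G": (0.68, -0.92, -1.34, -0.71, 0.11, -0.12),
    "H": (0.28, 0.19, 0.60, 0.44, 0.47, 0.69),
    "I": (-1.00, 0.13, 0.54, -0.46, -0.02, -0.43),
    "L": (-0.96, 0.30, 0.26, -0.44, 0.09, -0.48),
    "K": (0.43, 0.62, 0.29, 1.06, 0.79, -0.24),
    "M": (-0.72, 0.42, 0.41, -0.10, 0.24, 0.11),
    "F": (-0.85, 0.21, 0.95, -0.22, 0.27, 0.08),
    "P": (0.33, -1.05, -0.50, -0.31, -1.17, -0.23),
    "S": (0.33, -0.39, -0.66, -0.18, -0.12, -0.06),
    "T": (0.11, -0.37, -0.35, -0.25, -0.07, -0.05),
    "W": (-0.59, 0.38, 1.52, 0.21, 0.38, 0.38),
    "Y": (-0.24, 0.27, 1.06, 0.16, 0.16, 0.25),
    "V": (-0.79, -0.12, 0.19, -0.51, -0.09, -0.34),
}

PROTFP = {  # ProtFP-style 8-component embedding (synthetic reconstruction)
    "A": (0.53, -0.25, 1.21, 0.39, 1.04, 0.20, -0.09, 0.89),
    "C": (-1.33, -1.50, 1.77, -0.75, -0.96, -1.42, 0.27, -2.03),
    "D": (-0.99, -0.93, 0.49, 0.26, -0.01, 2.69, 0.50, -0.40),
    "E": (0.40, -0.94, 0.80, -0.50, -0.14, 2.44, 0.11, 0.16),
    "F": (-0.05, 0.82, -0.36, -1.15, 0.69, 0.26, -0.35, -0.78),
    "G": (0.26, 2.35, 2.39, 1.01, -1.87, -0.27, -0.82, 0.67),
    "H": (0.25, -0.87, -0.80, 2.21, 1.02, -0.12, -2.00, -1.35),
    "I": (-0.32, -0.06, -0.26, -1.34, 1.00, -0.70, 0.33, 1.42),
    "K": (2.34, -0.38, -0.64, 0.92, -0.75, -0.15, -0.21, 0.50),
    "L": (1.65, 0.28, 0.83, -1.00, 1.22, 0.10, 0.81, 0.33),
    "M": (0.11, -0.18, 0.36, 0.10, 1.13, -0.69, -1.62, -0.47),
    "N": (-1.22, 0.45, -0.91, 0.53, -0.89, 0.81, -0.37, 1.04),
    "P": (0.11, 1.38, -0.61, 1.73, 0.78, -0.19, 3.03, -1.37),
    "Q": (-0.99, -0.20, -1.56, 0.06, -0.58, -0.19, -0.27, 1.52),
    "R": (1.74, -1.54, -0.95, -0.53, -2.14, -0.60, 0.66, -0.31),
    "S": (-1.32, -0.16, -0.20, 0.98, 0.06, -0.50, 0.37, 0.63),
    "T": (-1.01, -0.58, -0.04, 0.03, -0.31, -1.13, 0.77, 0.63),
    "V": (0.05, -0.39, 0.45, -0.32, 1.35, -0.95, 0.06, 0.97),
    "W": (0.01, 1.57, -1.07, -1.42, -0.00, 0.26, -0.87, -1.33),
    "Y": (-0.20, 1.13, -0.89, -1.20, -0.63, 0.17, -0.30, -0.74),
}

ST_SCALES = {  # ST-scale-style 8-component embedding (synthetic reconstruction)
    "A": (0.31, 0.67, 1.10, 0.36, -0.36, -0.71, -1.07, -0.50),
    "C": (-1.67, -1.13, 2.02, 0.00, -0.13, 0.32, 2.49, -0.60),
    "D": (-0.19, 2.53, -0.36, 0.19, 0.36, -0.48, 1.37, -0.96),
    "E": (0.46, 1.59, -0.42, -0.06, -0.11, -1.21, 0.74, -1.73),
    "F": (1.19, -0.42, 0.01, -0.15, 1.16, -0.17, 0.57, 0.29),
    "G": (1.07, -0.73, 0.25, 2.93, -1.85, 1.51, -0.26, -0.97),
    "H": (-2.04, -0.07, -0.35, 1.52, 2.19, -0.68, -1.14, 0.27),
    "I": (0.95, -0.12, 0.69, -1.15, -0.72, -0.86, -0.29, 1.23),
    "K": (-0.60, -0.77, -1.29, -0.24, -0.34, -0.13, -1.83, -1.28),
    "L": (1.47, -0.14, 1.02, -1.06, 0.15, -0.38, -0.98, -1.13),
    "M": (-0.22, -0.78, 0.84, 0.97, 1.01, -1.04, -0.47, 0.40),
    "N": (-0.01, 0.92, -1.45, 0.70, -0.81, 0.12, 0.37, 1.10),
    "P": (-0.14, 1.17, 0.43, -1.19, 1.28, 3.40, -0.90, -0.10),
    "Q": (-0.35, 0.25, -1.30, -0.28, -1.05, -0.38, -0.07, 1.73),
    "R": (-1.33, -1.54, -1.46, -1.66, -0.86, -0.02, 0.16, -1.51),
    "S": (-0.85, 0.75, 0.28, 0.20, -0.60, 0.52, -0.10, 1.24),
    "T": (-0.80, -0.03, 0.60, -0.64, -1.09, 0.36, 0.28, 0.97),
    "V": (0.21, -0.08, 1.35, -0.49, -0.34, -0.77, -0.90, 0.68),
    "W": (1.50, -1.19, -0.96, 0.16, 1.55, 0.20, 0.98, 0.47),
    "Y": (1.05, -0.88, -1.00, -0.10, 0.57, 0.40, 1.06, 0.37),
}

T_SCALES = {  # T-scale-style 5-component embedding (synthetic reconstruction)
    "A": (-1.14, -0.20, -0.05, 1.03, -0.06),
    "C": (1.80, 0.77, -2.24, 0.51, 0.53),
    "D": (-0.55, -0.84, -0.85, -1.26, -2.28),
    "E": (-1.02, -1.51, -0.18, -1.00, -1.03),
    "F": (-0.56, 0.73, -0.33, -1.31, 0.76),
    "G": (-0.16, -1.90, -2.05, 1.83, 0.64),
    "H": (1.81, 0.22, 0.05, -0.51, -0.12),
    "I": (-1.52, 0.76, 0.69, 0.39, 0.71),
    "K": (0.83, -1.25, 1.92, 0.57, 0.43),
    "L": (-1.54, 0.48, 0.72, 0.33, 0.75),
    "M": (0.11, 0.44, -0.55, -0.04, 1.20),
    "N": (-0.14, -0.97, -0.04, -0.36, -1.01),
    "P": (0.62, 2.40, 0.54, 0.47, -2.14),
    "Q": (-0.05, -0.45, 0.94, -0.02, -0.35),
    "R": (1.89, -1.12, 1.84, -0.00, 0.62),
    "S": (0.22, 0.44, -0.20, 0.86, -0.99),
    "T": (0.30, 0.57, 0.04, 1.08, -0.30),
    "V": (-1.00, 0.82, 0.36, 1.04, 0.59),
    "W": (-0.01, 0.51, -0.39, -2.15, 1.28),
    "Y": (0.11, 0.11, -0.23, -1.47, 0.77),
}

BLOSUM_INDICES = {  # BLOSUM-index-style 10-component embedding (synthetic reconstruction)
    "A": (1.01, 0.12, 0.72, 0.05, -0.16, -0.40, 0.20, 1.14, -0.63, -0.86),
    "C": (-1.37, 1.38, -2.54, 1.92, 0.32, -0.57, -0.34, 0.68, -0.20, -1.13),
    "D": (0.33, -0.71, -0.80, -0.89, 1.64, 0.67, 1.16, 1.14, 1.72, -0.41),
    "E": (1.19, -0.81, -0.50, -0.50, 0.83, -1.61, 1.61, 0.46, 0.89, -0.65),
    "F": (-0.63, 1.11, -0.46, -0.45, -2.11, 0.35, 0.28, 0.90, 0.91, 0.49),
    "G": (-0.66, -2.51, -0.83, -0.60, -1.04, 0.74, -0.11, 0.37, -2.48, -1.22),
    "H": (1.25, -0.60, 0.37, 1.51, -0.51, 2.08, -1.62, -0.00, 1.81, -0.43),
    "I": (0.05, 1.54, 0.51, -1.36, 0.09, -0.15, -0.78, 0.61, -0.56, 0.74),
    "K": (-0.19, -1.09, 1.67, 0.30, -0.78, -1.13, -0.68, -0.77, 0.51, -0.89),
    "L": (-0.06, 0.10, 1.03, -0.20, -0.67, -1.32, 0.08, 1.79, -0.25, 0.62),
    "M": (2.01, 0.53, -0.42, 1.53, -0.97, -0.53, 0.05, -0.44, -0.59, -0.15),
    "N": (-0.46, 0.54, -0.05, -1.60, -0.65, 1.29, 0.57, -0.91, 0.51, -1.20),
    "P": (-1.78, -0.01, 1.91, 1.91, 0.26, 1.00, 2.31, 0.20, -0.24, 0.80),
    "Q": (0.39, 1.58, 0.42, -0.76, -0.39, -0.25, 0.83, -2.30, -0.26, -1.01),
    "R": (-1.75, -0.80, 0.32, 0.07, 0.77, -1.81, -1.59, -1.05, 1.16, -0.12),
    "S": (0.41, -0.07, 0.17, 0.04, 1.87, 1.18, -0.22, -0.70, -0.87, 0.22),
    "T": (-0.31, 0.68, -0.03, 0.08, 1.60, 0.11, -0.46, -0.62, -1.02, 0.09),
    "V": (0.65, 0.45, 0.66, -0.41, 0.92, 0.29, -1.49, 1.10, -0.77, 0.80),
    "W": (0.91, -0.96, -1.24, 0.36, -0.41, -0.55, 0.70, -1.43, -0.23, 2.71),
    "Y": (-1.00, -0.46, -0.92, -1.00, -0.61, 0.60, -0.51, -0.17, 0.60, 1.61),
}

SCALE_FAMILIES: dict[str, dict[str, tuple]] = {
    "BLOSUM": BLOSUM_INDICES,
    "Cruciani": CRUCIANI,
    "FASGAI": FASGAI,
    "KideraFactor": KIDERA,
    "MSWHIM": MS_WHIM,
    "ProtFP": PROTFP,
    "ST": ST_SCALES,
    "T": T_SCALES,
    "VHSE": VHSE,
    "Z": Z_SCALES,
}


def family_matrix(family: str) -> tuple[np.ndarray, int]:
    """Return the (20, d) value matrix of a family in AMINO_ACIDS order."""
    table = SCALE_FAMILIES[family]
    mat = np.array([table[aa] for aa in AMINO_ACIDS], dtype=float)
    return mat, mat.shape[1]


def total_components() -> int:
    return sum(len(next(iter(t.values()))) for t in SCALE_FAMILIES.values())
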