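"""Residue-level scales and constants used by the feature extractor.

Hopp-Woods hydrophilicity, Kyte-Doolittle hydropathy, flexibility, surface
accessibility and Janin scales come from Biopython's ProtParam data; the
remaining scales are standard published 20-value tables entered here.  The
pKa set matches the EMBOSS defaults used by its isoelectric-point tool.
"""

from __future__ import annotations

from Bio.SeqUtils import ProtParamData

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# EMBOSS default pKa values (iep)
PKA_NTERM = 8.6
PKA_CTERM = 3.6
PKA_POSITIVE = {"K": 10.8, "R": 12.5, "H": 6.5}
PKA_NEGATIVE = {"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}

HOPP_WOODS = dict(ProtParamData.hw)
KYTE_DOOLITTLE = dict(ProtParamData.kd)

EISENBERG = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
}
BULKINESS = {
    "A": 11.50, "R": 14.28, "N": 12.82, "D": 11.68, "C": 13.46,
    "Q": 14.45, "E": 13.57, "G": 3.40, "H": 13.69, "I": 21.40,
    "L": 21.40, "K": 15.71, "M": 16.25, "F": 19.80, "P": 17.43,
    "S": 9.47, "T": 15.77, "W": 21.67, "Y": 18.03, "V": 21.57,
}
POLARITY_ZIMMERMAN = {
    "A": 0.00, "R": 52.00, "N": 3.38, "D": 49.70, "C": 1.48,
    "Q": 3.53, "E": 49.90, "G": 0.00, "H": 51.60, "I": 0.13,
    "L": 0.13, "K": 49.50, "M": 1.43, "F": 0.35, "P": 1.58,
    "S": 1.67, "T": 1.66, "W": 2.10, "Y": 1.61, "V": 0.13,
}
POLARITY_GRANTHAM = {
    "A": 8.1, "R": 10.5, "N": 11.6, "D": 13.0, "C": 5.5,
    "Q": 10.5, "E": 12.3, "G": 9.0, "H": 10.4, "I": 5.2,
    "L": 4.9, "K": 11.3, "M": 5.7, "F": 5.2, "P": 8.0,
    "S": 9.2, "T": 8.6, "W": 5.4, "Y": 6.2, "V": 5.9,
}
HELIX_CHOU_FASMAN = {
    "A": 1.42, "R": 0.98, "N": 0.67, "D": 1.01, "C": 0.70,
    "Q": 1.11, "E": 1.51, "G": 0.57, "H": 1.00, "I": 1.08,
    "L": 1.21, "K": 1.16, "M": 1.45, "F": 1.13, "P": 0.57,
    "S": 0.77, "T": 0.83, "W": 1.08, "Y": 0.69, "V": 1.06,
}
SHEET_CHOU_FASMAN = {
    "A": 0.83, "R": 0.93, "N": 0.89, "D": 0.54, "C": 1.19,
    "Q": 1.10, "E": 0.37, "G": 0.75, "H": 0.87, "I": 1.60,
    "L": 1.30, "K": 0.74, "M": 1.05, "F": 1.38, "P": 0.55,
    "S": 0.75, "T": 1.19, "W": 1.37, "Y": 1.47, "V": 1.70,
}
FLEXIBILITY = dict(ProtParamData.Flex)
SURFACE_EMINI = dict(ProtParamData.em)
JANIN = dict(ProtParamData.ja)

# the nine per-residue scales averaged as physicochemical descriptors
SCALE_AVERAGES: dict[str, dict[str, float]] = {
    "hopp_woods": HOPP_WOODS,
    "eisenberg": EISENBERG,
    "bulkiness": BULKINESS,
    "polarity_zimmerman": POLARITY_ZIMMERMAN,
    "polarity_grantham": POLARITY_GRANTHAM,
    "helix_chou_fasman": HELIX_CHOU_FASMAN,
    "sheet_chou_fasman": SHEET_CHOU_FASMAN,
    "flexibility": FLEXIBILITY,
    "janin": JANIN,
}

# six reduced-alphabet residue groups (fractions are descriptors)
RESIDUE_GROUPS: dict[str, str] = {
    "aliphatic_hydrophobic": "AVLIM",
    "aromatic": "FWYH",
    "polar_uncharged": "STNQ",
    "positive": "KRH",
    "negative": "DE",
    "special": "CGP",
}

# hydrophobic-patch windows (positions whose mean Kyte-Doolittle >= cutoff)
PATCH_WINDOWS = (5, 7, 11)
PATCH_CUTOFF = 1.5

# molar extinction at 280 nm, reduced cysteines (Pace)
EXTINCTION = {"W": 5500.0, "Y": 1490.0}
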