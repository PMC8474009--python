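"""Physical constants and per-route instrument defaults.

All mass arithmetic in the package goes through this single table so that the
implementation and any internal consistency checks share one source of truth.
Masses are monoisotopic, in daltons, and reported to 5 decimals on output.
"""

from __future__ import annotations

#: Monoisotopic residue masses (peptide-bond residues, i.e. amino acid minus water).
RESIDUE_MASS: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

STANDARD_RESIDUES = frozenset(RESIDUE_MASS)

PROTON = 1.0072765
WATER = 18.0105646

#: Mass added by phosphorylation (HPO3).
PHOSPHO = 79.9663305

#: Full 13C/15N substitution deltas for stable-isotope labels.
HEAVY_DELTA: dict[str, float] = {
    "K": 8.01420,   # 13C6 15N2
    "R": 10.00827,  # 13C6 15N4
    "L": 7.01723,   # 13C6 15N1
    "P": 6.01385,   # 13C5 15N1
}

#: Residues that accept a phosphate.
PHOSPHO_ACCEPTORS = frozenset("STY")

#: Default collision-energy linear coefficients per precursor charge:
#: CE = slope * precursor_mz + intercept (eV), the common triple-quadrupole
#: parameterization.  Override via config for other instruments.
CE_COEFFICIENTS: dict[int, tuple[float, float]] = {
    2: (0.0339, 2.3597),
    3: (0.0295, 2.4141),
}

#: Light-peak apex height thresholds (counts) for calling an endogenous
#: peptide confidently detected, per enrichment route.
HEIGHT_THRESHOLD: dict[str, float] = {
    "pY": 250.0,
    "IMAC": 300.0,
}

#: Scheduled-method defaults per enrichment route.
METHOD_DEFAULTS: dict[str, dict[str, float]] = {
    "IMAC": {"duration_min": 160.0, "cycle_time_s": 3.0},
    "pY": {"duration_min": 120.0, "cycle_time_s": 1.5},
}
RT_WINDOW_MIN = 10.0
Q1_RESOLUTION = 0.4
Q3_RESOLUTION = 0.7

#: Mixture size bounds per route (minimum count of mixtures subject to these).
MIXTURE_BOUNDS: dict[str, tuple[int, int]] = {
    "IMAC": (43, 50),
    "pY": (31, 40),
    "IMACpY": (1, 10_000),  # always a single mixture
}

#: Equimolar peptide concentration in every mixture (pmol/ul).
MIXTURE_CONCENTRATION = 2.0
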