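"""Shared physical constants and assay design defaults.

Units used throughout the package: time in minutes, amounts in µmol,
concentrations in µmol/L, body weight in kg, volumes in L, enrichment as a
dimensionless fraction internally and in percent at the reporting surface.
"""

from __future__ import annotations

# IUPAC isotopic abundances (mole fraction of the heavy isotope).
NATURAL_ABUNDANCE_15N = 0.003663
NATURAL_ABUNDANCE_13C = 0.010816

# Molar mass of [15N]ammonium chloride (g/mol): 15N + 4 H + Cl.
MASS_15N = 15.0001089
MASS_14N = 14.0030740
MASS_H = 1.00794
MASS_CL = 35.453
MOLAR_MASS_15NH4CL = MASS_15N + 4 * MASS_H + MASS_CL  # ≈ 54.485 g/mol

# Assay design.
NOMINAL_DOSE_MG_PER_KG = 2.0
LEGACY_DOSE_MG_PER_KG = 20.0  # the 1996 oral ammonium chloride protocol
TIME_GRID_MIN = (0.0, 15.0, 30.0, 45.0, 60.0, 90.0, 120.0)
T_SPAN_MIN = 120.0

METABOLITES = ("urea", "citrulline", "arginine", "glutamine", "glycine", "glutamate")
UREA_CYCLE_METABOLITES = ("urea", "citrulline", "arginine")
ALTERNATIVE_METABOLITES = ("glutamine", "glycine", "glutamate")

MATRICES = ("plasma", "DBS")
ISOTOPOLOGUES = ("unlabeled", "15N", "13C", "15N2", "IS")
REPLICATES = (1, 2, 3)

# Typical fasting plasma pool concentrations (µmol/L) used for the
# label-amount bridge between enrichment AUCs and administered tracer.
DEFAULT_POOLS_UMOL_L = {
    "urea": 5000.0,
    "citrulline": 30.0,
    "arginine": 80.0,
    "glutamine": 600.0,
    "glycine": 250.0,
    "glutamate": 60.0,
}

# Distribution volume surrogate (total body water), L per kg body weight.
DEFAULT_V_DIST_L_PER_KG = 0.6

# Quality rules.
TRIPLICATE_OUTLIER_THRESHOLD = 0.30  # relative deviation vs mean of other two
STABILITY_CV_THRESHOLD = 0.10        # total-signal CV above which a metabolite
                                     # is excluded from semi-quantitative sums

# Monoisotopic m/z of protonated urea isotopologues, for mass-accuracy checks.
PROTON_MASS = 1.00727646
EXACT_MZ = {
    "urea": 61.03964,        # CH4N2O + H+
    "urea_15N": 62.03668,    # one 14N -> 15N
    "urea_13C": 62.04300,    # 12C -> 13C
}
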