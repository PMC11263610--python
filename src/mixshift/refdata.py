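"""Bundled reference statistics for the three-compound microcosm design.

Published summary statistics from a sediment-water microcosm study of
metformin (MFN), metolachlor (MET) and terbutryn (TER), spiked singly (ONE)
or as a mixture (MIX) under biotic and abiotic regimes. These serve as
inputs for recomputation checks (CI95 and DT50 ranges from k +/- SE and n;
biodegradation fraction from day-70 dissipation percentages) and as
realistic defaults for the synthetic generator.

All values are printed-precision: rates per day (3 decimals), dissipation
in integer percent. ``REFERENCE_FITS`` maps (compound, condition_type,
regime) to the reported slope estimate and the intervals printed alongside
it; ``REFERENCE_DISSIPATION_D70`` holds the day-70 system-wide dissipation
rows; ``INTERACTION_EXAMPLES`` holds published phylum-level (IC_ADD,
IC_MIX) pairs with the mixture-interaction category assigned to them.
"""

from __future__ import annotations

# (compound, condition_type, regime) ->
#   dict(k, se, n, ci95=(lo, hi), dt50=(lo, hi))   [printed values]
REFERENCE_FITS: dict[tuple[str, str, str], dict] = {
    ("MFN", "ONE", "abiotic"): dict(k=0.019, se=0.004, n=10, ci95=(0.017, 0.021), dt50=(30, 46)),
    ("MFN", "ONE", "biotic"):  dict(k=0.060, se=0.011, n=13, ci95=(0.054, 0.066), dt50=(10, 14)),
    ("MFN", "MIX", "abiotic"): dict(k=0.013, se=0.006, n=9,  ci95=(0.009, 0.017), dt50=(36, 99)),
    ("MFN", "MIX", "biotic"):  dict(k=0.059, se=0.008, n=15, ci95=(0.055, 0.063), dt50=(10, 14)),
    ("MET", "ONE", "abiotic"): dict(k=0.060, se=0.010, n=10, ci95=(0.054, 0.066), dt50=(10, 14)),
    ("MET", "ONE", "biotic"):  dict(k=0.045, se=0.004, n=15, ci95=(0.043, 0.047), dt50=(14, 17)),
    ("MET", "MIX", "abiotic"): dict(k=0.072, se=0.008, n=10, ci95=(0.067, 0.077), dt50=(9, 11)),
    ("MET", "MIX", "biotic"):  dict(k=0.054, se=0.003, n=15, ci95=(0.052, 0.056), dt50=(12, 14)),
    ("TER", "ONE", "abiotic"): dict(k=0.006, se=0.001, n=8,  ci95=(0.005, 0.007), dt50=(99, 139)),
    ("TER", "ONE", "biotic"):  dict(k=0.005, se=0.001, n=14, ci95=(0.004, 0.006), dt50=(116, 173)),
    ("TER", "MIX", "abiotic"): dict(k=0.009, se=0.004, n=6,  ci95=(0.006, 0.012), dt50=(53, 139)),
    ("TER", "MIX", "biotic"):  dict(k=0.005, se=0.002, n=12, ci95=(0.004, 0.006), dt50=(99, 231)),
}

# (compound, condition_type) ->
#   dict(d_abiotic, sd_abiotic, d_biotic, sd_biotic, b, b_sd)  at day 70, % of
#   the whole system.  Note: the MET MIX row is internally inconsistent as
#   printed (D_biotic < D_abiotic yet B reported positive); its B is best
#   read as a magnitude.
REFERENCE_DISSIPATION_D70: dict[tuple[str, str], dict] = {
    ("MFN", "ONE"): dict(d_abiotic=77, sd_abiotic=8,  d_biotic=97, sd_biotic=2, b=20, b_sd=8),
    ("MFN", "MIX"): dict(d_abiotic=71, sd_abiotic=5,  d_biotic=97, sd_biotic=4, b=27, b_sd=6),
    ("MET", "ONE"): dict(d_abiotic=99, sd_abiotic=0,  d_biotic=94, sd_biotic=1, b=-5, b_sd=1),
    ("MET", "MIX"): dict(d_abiotic=99, sd_abiotic=1,  d_biotic=98, sd_biotic=0, b=1,  b_sd=1),
    ("TER", "ONE"): dict(d_abiotic=23, sd_abiotic=7,  d_biotic=27, sd_biotic=3, b=4,  b_sd=8),
    ("TER", "MIX"): dict(d_abiotic=40, sd_abiotic=16, d_biotic=35, sd_biotic=7, b=-5, b_sd=17),
}

# Published phylum-level worked examples of the +/-64% interval rule:
# name -> (ic_add, ic_mix, matrix, category)
INTERACTION_EXAMPLES: dict[str, dict] = {
    "LCP-89":        dict(ic_add=1.5,  ic_mix=2.4,  matrix="sediment", category="additive"),
    "WPS-2":         dict(ic_add=-1.0, ic_mix=4.6,  matrix="sediment", category="antagonism_opposing"),
    "Dependentiae":  dict(ic_add=193.0, ic_mix=35.0, matrix="water",   category="antagonism_repressing"),
    "WS4":           dict(ic_add=0.0,  ic_mix=47.0, matrix="sediment", category="synergism"),
    "Micrarchaeota": dict(ic_add=30.0, ic_mix=255.0, matrix="water",   category="synergism"),
}

#: Spiked initial concentration, uM (identical for all three compounds).
SPIKE_C0_UM = 17.6

#: Sacrificial sampling days of the microcosm design.
SAMPLING_DAYS = (0.0, 15.0, 30.0, 50.0, 70.0)
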