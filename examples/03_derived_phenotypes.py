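"""Derive blood-count ratios, eGFR variants, and renal disease groups.

Shows the systemic-inflammation ratios (NLR, PLR, LMR, SII), the three
CKD-EPI-style eGFR formulas at their kernel boundaries (where they return the
sex-specific scale coefficient exactly), and date-based renal case/control
grouping with the special-meaning sentinel date treated as missing.
"""

import pandas as pd

from ribocn.derived_phenotypes import blood_ratios, egfr, renal_disease_groups

counts = pd.DataFrame(
    {"neutrophils": [4.0, 3.0], "lymphocytes": [2.0, 0.0],
     "platelets": [250.0, 300.0], "monocytes": [0.5, 0.6]},
    index=["participant_a", "participant_b"],
)
print(blood_ratios(counts))
# participant_b has zero lymphocytes, so the lymphocyte-denominated ratios are
# left missing rather than infinite.

print("\neGFR at kernel boundaries (age 0, all power terms = 1):")
print(f"  cr,    female, Scr 0.7  -> {egfr('female', 0, scr_mgdl=0.7, variant='cr'):.3f}")
print(f"  cr,    male,   Scr 0.9  -> {egfr('male', 0, scr_mgdl=0.9, variant='cr'):.3f}")
print(f"  cc,    male,   Scc 0.8  -> {egfr('male', 0, scr_mgdl=0.72, scc=0.8, variant='cc'):.3f}")
print(f"  cr+cc, female           -> {egfr('female', 0, scr_mgdl=0.7, scc=0.8, variant='cr_cc'):.3f}")
print(f"  cr,    male, Scr 1.4, age 60 -> {egfr('male', 60, scr_mgdl=1.4, variant='cr'):.1f}")

dates = pd.DataFrame(
    {"N17": ["2005-01-01", "", "1903-03-03"], "N18": ["", "", ""], "N20": ["", "2010-06-15", ""]},
    index=["p1", "p2", "p3"],
)
print("\nrenal disease groups (True = case):")
print(renal_disease_groups(dates))
# p3's only entry is the sentinel date, so it remains a control everywhere.
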