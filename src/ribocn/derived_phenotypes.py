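"""Derived cohort phenotypes: blood-count ratios, blood-composition PCs, eGFR, renal groups.

Blood-count ratios (NLR, PLR, LMR, SII) are standard systemic-inflammation
markers derived from absolute cell counts; a zero denominator leaves the ratio
missing rather than infinite. Blood-composition principal components summarize
the five nucleated white-cell percentages (which are compositional, so four
components capture essentially all variance). eGFR follows the CKD-EPI-style
sex-specific piecewise power formulas for creatinine, cystatin C, and the
combined variant. Renal-disease case/control groups are built from first-report
dates of ICD-10-style code blocks, and the cohort filters reproduce standard
blood-trait exclusion rules (aberrant counts, pregnancy, processing delay,
medication use, overt disease).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ribocn.errors import ConfigurationError, InsufficientDataError, ValidationError

#: special-meaning first-report date treated as missing
SENTINEL_DATE = "1903-03-03"

#: medication codes for the six statins used in biochemistry-analysis exclusions
STATIN_CODES = {
    "1140861958",  # Simvastatin
    "1140888594",  # Fluvastatin
    "1140888648",  # Pravastatin
    "1141146138",  # Lipitor 10mg tablet
    "1141146234",  # Atorvastatin
    "1141192410",  # Rosuvastatin
}

#: default renal-disease groupings: ICD-10 code blocks per group
RENAL_DISEASE_GROUPS = {
    "glomerular_disease": [f"N0{i}" for i in range(0, 9)],  # N00-N08
    "kidney_failure": ["N17", "N18"],
    "urolithiasis": ["N20", "N21", "N22", "N23"],
}

BLOOD_PCT_COLUMNS = ["lymphocyte_pct", "monocyte_pct", "neutrophil_pct",
                     "eosinophil_pct", "basophil_pct"]


def blood_ratios(counts: pd.DataFrame) -> pd.DataFrame:
    """Derive NLR, PLR, LMR and SII from absolute blood-cell counts.

    Expects columns ``neutrophils``, ``lymphocytes``, ``platelets``,
    ``monocytes`` (units 10^9 cells/L). Ratios with a zero denominator are
    returned missing; missing inputs propagate.
    """
    n = counts["neutrophils"]
    l = counts["lymphocytes"].replace(0, np.nan)
    p = counts["platelets"]
    m = counts["monocytes"].replace(0, np.nan)
    out = pd.DataFrame(index=counts.index)
    out["NLR"] = n / l
    out["PLR"] = p / l
    out["LMR"] = counts["lymphocytes"] / m
    out["SII"] = n * p / l
    return out


def blood_composition_pcs(
    percentages: pd.DataFrame,
    nrbc_pct: pd.Series | None = None,
    n_components: int = 4,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Unit-variance PCA of the five nucleated white-cell percentages.

    Participants with any nucleated red blood cells (nrbc_pct > 0) are excluded
    before fitting — their composition reflects pathology, not the white-cell
    mixture of interest. Columns are z-scored (correlation-matrix PCA) before
    the decomposition. Returns (scores for retained participants, explained
    variance fractions for all components).
    """
    cols = [c for c in BLOOD_PCT_COLUMNS if c in percentages.columns]
    if len(cols) != 5:
        missing = set(BLOOD_PCT_COLUMNS) - set(percentages.columns)
        raise ValidationError(f"missing percentage column(s): {sorted(missing)}")
    data = percentages[cols]
    if nrbc_pct is not None:
        keep = ~(nrbc_pct.reindex(data.index).fillna(0) > 0)
        data = data[keep]
    data = data.dropna()
    if len(data) < 6:
        raise InsufficientDataError(
            f"need >= 6 complete participants for blood-composition PCA, got {len(data)}"
        )
    x = data.to_numpy(dtype=float)
    x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    var = s**2
    explained = var / var.sum()
    scores = u[:, :n_components] * s[:n_components]
    score_df = pd.DataFrame(
        scores,
        index=data.index,
        columns=[f"blood_pc{i + 1}" for i in range(n_components)],
    )
    return score_df, explained


@dataclass(frozen=True)
class EGFRCoefficients:
    """Sex-specific coefficients and fixed exponents of the eGFR formulas.

    Defaults follow the published sex-specific scale factors; alpha_cr here
    doubles as the min-kernel exponent for both the creatinine-only and the
    combined variant. All values are configurable.
    """

    gamma_cr_male: float = 142.0
    gamma_cr_female: float = 143.704
    gamma_cc_male: float = 135.0
    gamma_cc_female: float = 130.035
    gamma_crcc_male: float = 133.0
    gamma_crcc_female: float = 123.956
    alpha_cr_male: float = 0.9
    alpha_cr_female: float = 0.7
    kappa_male: float = 0.9
    kappa_female: float = 0.7
    cc_knot: float = 0.8
    exp_cr_max: float = -1.2
    exp_cc_min: float = -0.499
    exp_cc_max: float = -1.328
    exp_crcc_cr_max: float = -0.544
    exp_crcc_cc_min: float = -0.323
    exp_crcc_cc_max: float = -0.778
    age_base_cr: float = 0.9938
    age_base_cc: float = 0.996
    age_base_crcc: float = 0.9961
    creatinine_umol_to_mgdl: float = 0.0133


def convert_creatinine(
    scr_umol_per_l: float, factor: float = EGFRCoefficients.creatinine_umol_to_mgdl
) -> float:
    """Serum creatinine umol/L -> mg/dL via the configurable conversion factor."""
    return scr_umol_per_l * factor


def egfr(
    sex: str,
    age: float,
    scr_mgdl: float | None = None,
    scc: float | None = None,
    variant: str = "cr_cc",
    coefficients: EGFRCoefficients = EGFRCoefficients(),
    strict_as_printed: bool = False,
) -> float:
    """Estimated glomerular filtration rate, mL/min/1.73m2.

    ``variant`` is one of ``cr`` (creatinine), ``cc`` (cystatin C), ``cr_cc``
    (both). ``scr_mgdl`` must already be in mg/dL. Missing required biomarkers
    yield NaN; non-positive values raise. ``strict_as_printed`` switches the
    cystatin-only max kernel to take serum creatinine as its argument (a
    published-form quirk); the default uses cystatin C for internal consistency
    of a cystatin-only estimate.
    """
    c = coefficients
    if sex not in ("male", "female"):
        raise ValidationError(f"sex must be 'male' or 'female', got {sex!r}")
    male = sex == "male"
    kappa = c.kappa_male if male else c.kappa_female
    alpha = c.alpha_cr_male if male else c.alpha_cr_female

    def _check(name, v):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        if v <= 0:
            raise ValidationError(f"non-positive {name}: {v}")
        return float(v)

    scr = _check("serum creatinine", scr_mgdl)
    cys = _check("cystatin C", scc)

    if variant == "cr":
        if scr is None:
            return math.nan
        gamma = c.gamma_cr_male if male else c.gamma_cr_female
        return (
            gamma
            * min(scr / kappa, 1.0) ** alpha
            * max(scr / kappa, 1.0) ** c.exp_cr_max
            * c.age_base_cr**age
        )
    if variant == "cc":
        if cys is None:
            return math.nan
        max_arg = scr if strict_as_printed else cys
        if max_arg is None:
            return math.nan
        gamma = c.gamma_cc_male if male else c.gamma_cc_female
        return (
            gamma
            * min(cys / c.cc_knot, 1.0) ** c.exp_cc_min
            * max(max_arg / c.cc_knot, 1.0) ** c.exp_cc_max
            * c.age_base_cc**age
        )
    if variant == "cr_cc":
        if scr is None or cys is None:
            return math.nan
        gamma = c.gamma_crcc_male if male else c.gamma_crcc_female
        return (
            gamma
            * min(scr / kappa, 1.0) ** alpha
            * max(scr / kappa, 1.0) ** c.exp_crcc_cr_max
            * min(cys / c.cc_knot, 1.0) ** c.exp_crcc_cc_min
            * max(cys / c.cc_knot, 1.0) ** c.exp_crcc_cc_max
            * c.age_base_crcc**age
        )
    raise ValidationError(f"unknown eGFR variant {variant!r}")


def egfr_table(
    table: pd.DataFrame,
    coefficients: EGFRCoefficients = EGFRCoefficients(),
    creatinine_in_umol: bool = True,
) -> pd.DataFrame:
    """Vectorized convenience: add egfr_cr / egfr_cc / egfr_cr_cc columns.

    Expects columns ``sex`` ('male'/'female'), ``age``, ``serum_creatinine``
    (umol/L unless ``creatinine_in_umol`` is False), ``cystatin_c``.
    """
    scr = table["serum_creatinine"].astype(float)
    if creatinine_in_umol:
        scr = scr * coefficients.creatinine_umol_to_mgdl
    out = table.copy()
    for variant in ("cr", "cc", "cr_cc"):
        out[f"egfr_{variant}"] = [
            egfr(s, a, scr_mgdl=r, scc=cc, variant=variant, coefficients=coefficients)
            if s in ("male", "female") and not (isinstance(a, float) and math.isnan(a))
            else math.nan
            for s, a, r, cc in zip(
                table["sex"], table["age"], scr, table["cystatin_c"].astype(float)
            )
        ]
    return out


def renal_disease_groups(
    first_report_dates: pd.DataFrame,
    grouping: Mapping[str, Sequence[str]] | None = None,
    sentinel: str = SENTINEL_DATE,
) -> pd.DataFrame:
    """Case/control labels per renal-disease group from first-report dates.

    ``first_report_dates`` has one column per disease code holding date strings
    (empty/NaN = never reported). The sentinel date is a special-meaning entry
    and counts as missing. A participant is a case for a group if any member
    code carries a valid date, control otherwise. Unparseable non-sentinel
    dates raise.
    """
    grouping = grouping or RENAL_DISEASE_GROUPS
    out = pd.DataFrame(index=first_report_dates.index)
    for group, codes in grouping.items():
        present = [c for c in codes if c in first_report_dates.columns]
        case = pd.Series(False, index=first_report_dates.index)
        for code in present:
            col = first_report_dates[code]
            valid = col.notna() & (col.astype(str).str.strip() != "")
            is_sentinel = col.astype(str).str.strip() == sentinel
            to_parse = col[valid & ~is_sentinel]
            parsed = pd.to_datetime(to_parse, format="%Y-%m-%d", errors="coerce")
            bad = to_parse[parsed.isna()]
            if len(bad):
                raise ValidationError(
                    f"unparseable first-report date(s) for code {code}: "
                    f"{bad.head().to_dict()}"
                )
            case |= valid & ~is_sentinel
        out[group] = case
    return out


@dataclass
class CohortFilterRules:
    """Code lists and thresholds driving the cohort subset flags.

    The engine, not the lists, is the method: the default code lists are
    editable placeholders and should be replaced with the cohort's own
    curated lists.
    """

    blood_cancer_codes: set[str] = field(default_factory=lambda: {"1047", "1048", "1050",
                                                                  "1051", "1052", "1053",
                                                                  "1055", "1056", "1058"})
    blood_disorder_codes: set[str] = field(default_factory=lambda: {"1446", "1447", "1461",
                                                                    "1463"})
    congenital_codes: set[str] = field(default_factory=lambda: {"1652", "1653"})
    excluded_medication_codes: set[str] = field(default_factory=lambda: set(STATIN_CODES))
    max_leukocytes: float = 200.0       # 10^9 cells/L
    max_hemoglobin: float = 20.0        # g/dL
    max_hematocrit: float = 60.0        # %
    max_platelets: float = 1000.0       # 10^9 cells/L
    max_processing_delay_h: float = 36.0
    max_bmi: float = 30.0               # kg/m^2, HEALTHY only
    nonsmoker_statuses: set[int] = field(default_factory=lambda: {0, 1})


def _codes(cell) -> set[str]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return set()
    if isinstance(cell, str):
        return {c for c in cell.replace(",", "|").split("|") if c.strip()}
    if isinstance(cell, Iterable):
        return {str(c) for c in cell}
    return {str(cell)}


def apply_cohort_filters(
    table: pd.DataFrame,
    rules: CohortFilterRules | None = None,
    unrelated_ids: set[str] | None = None,
) -> pd.DataFrame:
    """Add nested subset membership flags to a cohort table.

    FILTERED drops blood cancers/disorders, pregnancy (status 1 or 2), aberrant
    blood measurements and long processing delays. FILTERED_UNRELATED further
    intersects with an unrelated-id set (if given). FILTERED_UNMEDICATED drops
    listed medications and anyone flagged as taking other prescription
    medication. HEALTHY additionally drops any recorded illness, congenital
    codes, current smokers and BMI above the cap. Subsets are nested by
    construction. Missing values never exclude a participant (only recorded
    violations do).
    """
    if rules is None:
        raise ConfigurationError("cohort filter rules must be supplied (defaults are placeholders)")
    t = table
    idx = t.index

    def col(name, default=np.nan):
        return t[name] if name in t.columns else pd.Series(default, index=idx)

    cancer = col("cancer_codes", None).map(_codes)
    noncancer = col("noncancer_codes", None).map(_codes)
    meds = col("medication_codes", None).map(_codes)
    congenital = col("congenital_codes", None).map(_codes)

    excluded = (
        cancer.map(lambda s: bool(s & rules.blood_cancer_codes))
        | noncancer.map(lambda s: bool(s & rules.blood_disorder_codes))
        | col("pregnancy").isin([1, 2])
        | (col("leukocytes") > rules.max_leukocytes)
        | (col("hemoglobin") > rules.max_hemoglobin)
        | (col("hematocrit") > rules.max_hematocrit)
        | (col("platelets") > rules.max_platelets)
        | (col("processing_delay_h") > rules.max_processing_delay_h)
    )
    out = t.copy()
    out["FILTERED"] = ~excluded

    if unrelated_ids is not None:
        out["FILTERED_UNRELATED"] = out["FILTERED"] & idx.astype(str).isin(
            {str(i) for i in unrelated_ids}
        )

    other_rx = col("other_prescription").map(lambda v: bool(v) and v == v)
    medicated = meds.map(lambda s: bool(s & rules.excluded_medication_codes)) | other_rx
    out["FILTERED_UNMEDICATED"] = out["FILTERED"] & ~medicated

    smoking = col("smoking_status")
    unhealthy = (
        cancer.map(bool)
        | noncancer.map(bool)
        | congenital.map(bool)
        | (smoking.notna() & ~smoking.isin(list(rules.nonsmoker_statuses)))
        | (col("bmi") > rules.max_bmi)
    )
    out["HEALTHY"] = out["FILTERED_UNMEDICATED"] & ~unhealthy
    return out
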