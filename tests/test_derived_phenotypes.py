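"""Blood ratios, compositional PCA, eGFR formulas, renal grouping, cohort filters."""

import math

import numpy as np
import pandas as pd
import pytest

from ribocn.derived_phenotypes import (
    CohortFilterRules,
    EGFRCoefficients,
    apply_cohort_filters,
    blood_composition_pcs,
    blood_ratios,
    egfr,
    renal_disease_groups,
)
from ribocn.errors import InsufficientDataError, ValidationError


class TestBloodRatios:
    def test_known_values(self):
        counts = pd.DataFrame(
            {"neutrophils": [4.0], "lymphocytes": [2.0], "platelets": [250.0],
             "monocytes": [0.5]}
        )
        out = blood_ratios(counts)
        assert out.loc[0, "NLR"] == 2.0
        assert out.loc[0, "PLR"] == 125.0
        assert out.loc[0, "LMR"] == 4.0
        assert out.loc[0, "SII"] == 500.0

    def test_zero_lymphocytes_leaves_ratios_missing(self):
        counts = pd.DataFrame(
            {"neutrophils": [4.0], "lymphocytes": [0.0], "platelets": [250.0],
             "monocytes": [0.5]}
        )
        out = blood_ratios(counts)
        assert out.loc[0, ["NLR", "PLR", "SII"]].isna().all()
        assert not math.isnan(out.loc[0, "LMR"])

    def test_missing_inputs_propagate(self):
        counts = pd.DataFrame(
            {"neutrophils": [np.nan], "lymphocytes": [np.nan], "platelets": [np.nan],
             "monocytes": [np.nan]}
        )
        assert blood_ratios(counts).iloc[0].isna().all()


class TestBloodCompositionPCA:
    def _compositional(self, rng, n=200):
        raw = rng.dirichlet(np.ones(5) * 3, size=n) * 100
        cols = ["lymphocyte_pct", "monocyte_pct", "neutrophil_pct",
                "eosinophil_pct", "basophil_pct"]
        return pd.DataFrame(raw, columns=cols)

    def test_compositional_rank_deficiency(self, rng):
        """Percentages summing to 100 leave the 5th component with ~no variance."""
        df = self._compositional(rng)
        scores, explained = blood_composition_pcs(df)
        assert explained[:4].sum() > 0.9999
        assert scores.shape == (200, 4)

    def test_nrbc_positive_participants_excluded(self, rng):
        df = self._compositional(rng, 50)
        nrbc = pd.Series(0.0, index=df.index)
        nrbc.iloc[7] = 0.1
        scores, _ = blood_composition_pcs(df, nrbc_pct=nrbc)
        assert 7 not in scores.index
        assert len(scores) == 49

    def test_duplicating_rows_leaves_explained_variance_unchanged(self, rng):
        df = self._compositional(rng, 80)
        _, e1 = blood_composition_pcs(df)
        _, e2 = blood_composition_pcs(pd.concat([df, df], ignore_index=True))
        assert np.allclose(e1, e2, atol=1e-10)

    def test_too_few_participants_raise(self, rng):
        with pytest.raises(InsufficientDataError):
            blood_composition_pcs(self._compositional(rng, 5))


class TestEGFR:
    def test_printed_gamma_at_kernel_boundaries(self):
        # every min/max kernel and the age factor equal 1 at these inputs
        assert egfr("female", 0, scr_mgdl=0.7, variant="cr") == pytest.approx(143.704)
        assert egfr("male", 0, scr_mgdl=0.9, variant="cr") == pytest.approx(142.0)
        assert egfr("male", 0, scr_mgdl=0.72, scc=0.8, variant="cc") == pytest.approx(135.0)
        assert egfr("female", 0, scr_mgdl=0.7, scc=0.8, variant="cr_cc") == pytest.approx(123.956)

    @pytest.mark.parametrize("variant", ["cr", "cc", "cr_cc"])
    def test_continuity_at_kernel_breakpoints(self, variant):
        """Left and right limits agree where min/max kernels switch."""
        knot = {"cr": 0.9, "cc": 0.8, "cr_cc": 0.9}[variant]
        eps = 1e-9
        lo = egfr("male", 50, scr_mgdl=knot - eps, scc=0.8, variant=variant)
        hi = egfr("male", 50, scr_mgdl=knot + eps, scc=0.8, variant=variant)
        assert lo == pytest.approx(hi, rel=1e-6)

    def test_monotone_decreasing_above_kappa(self):
        values = [egfr("female", 50, scr_mgdl=s, scc=1.0, variant="cr_cc")
                  for s in (0.8, 1.0, 1.5, 2.5)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_monotone_decreasing_in_age(self):
        values = [egfr("male", age, scr_mgdl=1.1, variant="cr") for age in (30, 50, 70)]
        assert values[0] > values[1] > values[2]

    def test_globally_monotone_with_canonical_negative_exponent(self):
        coeff = EGFRCoefficients(alpha_cr_male=-0.302, alpha_cr_female=-0.241)
        values = [egfr("female", 50, scr_mgdl=s, variant="cr", coefficients=coeff)
                  for s in (0.3, 0.5, 0.7, 1.0, 2.0)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_strict_as_printed_uses_creatinine_in_cc_max_term(self):
        default = egfr("male", 40, scr_mgdl=2.0, scc=0.5, variant="cc")
        printed = egfr("male", 40, scr_mgdl=2.0, scc=0.5, variant="cc",
                       strict_as_printed=True)
        assert printed < default  # Scr=2.0 drives the max kernel below 1

    def test_missing_biomarker_yields_missing(self):
        assert math.isnan(egfr("male", 50, scr_mgdl=None, variant="cr"))
        assert math.isnan(egfr("male", 50, scr_mgdl=1.0, scc=None, variant="cr_cc"))

    def test_nonpositive_biomarker_raises(self):
        with pytest.raises(ValidationError):
            egfr("male", 50, scr_mgdl=-1.0, variant="cr")

    def test_unknown_sex_or_variant_rejected(self):
        with pytest.raises(ValidationError):
            egfr("other", 50, scr_mgdl=1.0, variant="cr")
        with pytest.raises(ValidationError):
            egfr("male", 50, scr_mgdl=1.0, variant="xx")


class TestRenalGroups:
    def _dates(self, **cols):
        return pd.DataFrame({k: [v] for k, v in cols.items()})

    def test_valid_date_makes_case(self):
        dates = self._dates(N17="2005-01-01", N18="", N00="")
        out = renal_disease_groups(dates)
        assert bool(out.loc[0, "kidney_failure"])
        assert not bool(out.loc[0, "glomerular_disease"])

    def test_sentinel_date_is_control(self):
        dates = self._dates(N17="1903-03-03", N18="")
        out = renal_disease_groups(dates)
        assert not bool(out.loc[0, "kidney_failure"])

    def test_no_dates_control_everywhere(self):
        dates = pd.DataFrame({"N17": [None], "N20": [None]})
        out = renal_disease_groups(dates)
        assert not out.loc[0].any()

    def test_unparseable_date_raises(self):
        with pytest.raises(ValidationError):
            renal_disease_groups(self._dates(N17="not-a-date"))


class TestCohortFilters:
    def _table(self, n=10, **overrides):
        base = pd.DataFrame(
            {
                "pregnancy": [0] * n,
                "leukocytes": [7.0] * n,
                "hemoglobin": [14.0] * n,
                "hematocrit": [42.0] * n,
                "platelets": [250.0] * n,
                "processing_delay_h": [10.0] * n,
                "smoking_status": [0] * n,
                "bmi": [24.0] * n,
            },
            index=[f"p{i}" for i in range(n)],
        )
        for col, (idx, value) in overrides.items():
            base.loc[f"p{idx}", col] = value
        return base

    def test_hand_applied_rules(self):
        table = self._table(
            10,
            platelets=(0, 1200.0),      # aberrant platelets
            pregnancy=(1, 1),           # pregnant
            processing_delay_h=(2, 48.0),  # late processing
        )
        out = apply_cohort_filters(table, CohortFilterRules())
        assert out["FILTERED"].sum() == 7
        assert not out.loc["p0", "FILTERED"]
        assert not out.loc["p1", "FILTERED"]
        assert not out.loc["p2", "FILTERED"]

    def test_bmi_exclusion_only_affects_healthy(self):
        table = self._table(3, bmi=(0, 32.0))
        out = apply_cohort_filters(table, CohortFilterRules())
        assert out.loc["p0", "FILTERED"]
        assert not out.loc["p0", "HEALTHY"]

    def test_statin_user_dropped_from_unmedicated(self):
        table = self._table(3)
        table["medication_codes"] = ["1140861958", "", ""]
        out = apply_cohort_filters(table, CohortFilterRules())
        assert out.loc["p0", "FILTERED"]
        assert not out.loc["p0", "FILTERED_UNMEDICATED"]

    def test_smoker_excluded_from_healthy(self):
        table = self._table(3, smoking_status=(1, 2))
        out = apply_cohort_filters(table, CohortFilterRules())
        assert out.loc["p1", "FILTERED_UNMEDICATED"]
        assert not out.loc["p1", "HEALTHY"]

    def test_subset_nesting(self, rng):
        n = 200
        table = pd.DataFrame(
            {
                "pregnancy": rng.choice([0, 1, 2], n),
                "leukocytes": rng.uniform(1, 300, n),
                "hemoglobin": rng.uniform(8, 25, n),
                "hematocrit": rng.uniform(30, 70, n),
                "platelets": rng.uniform(100, 1500, n),
                "processing_delay_h": rng.uniform(0, 72, n),
                "smoking_status": rng.choice([0, 1, 2], n),
                "bmi": rng.uniform(17, 45, n),
                "medication_codes": rng.choice(["", "1140861958", "999"], n),
            },
            index=[f"p{i}" for i in range(n)],
        )
        out = apply_cohort_filters(
            table, CohortFilterRules(), unrelated_ids={f"p{i}" for i in range(0, n, 2)}
        )
        assert (out["HEALTHY"] <= out["FILTERED_UNMEDICATED"]).all()
        assert (out["FILTERED_UNMEDICATED"] <= out["FILTERED"]).all()
        assert (out["FILTERED_UNRELATED"] <= out["FILTERED"]).all()

    def test_missing_rules_raise(self):
        from ribocn.errors import ConfigurationError

        with pytest.raises(ConfigurationError):
            apply_cohort_filters(self._table(2), rules=None)
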