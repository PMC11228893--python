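"""Association models and summary statistics for cohort screens.

Linear and logistic models are fit with every continuous variable standardized
(z-scored) so that effect sizes are comparable across traits; logistic effects
are reported as log-odds with odds ratios e^beta. The phenome screen applies
the eligibility filters used for cohort-wide scans (minimum case count,
minimum measured fraction) and controls the false discovery rate with
Benjamini-Hochberg across the eligible set. Also provided: the genomic
inflation factor (median chi-square statistic over its null median), standard
errors recovered from beta and p, the fixed-effect inverse-variance-weighted
Mendelian randomization estimator, effect-size-profile correlations, quantile
trend summaries with t-based confidence intervals, and rank-based group tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from ribocn.errors import (
    InsufficientDataError,
    ModelError,
    ValidationError,
)


@dataclass
class ModelSpec:
    """One response ~ exposure + covariates model.

    ``categorical`` names the covariates to expand into indicator columns
    (most frequent level as the reference). ``standardize`` z-scores all
    continuous variables, the linear response included.
    """

    response: str
    exposure: str
    covariates: list[str] = field(default_factory=list)
    categorical: list[str] = field(default_factory=list)
    family: str = "linear"
    standardize: bool = True

    def __post_init__(self):
        if self.exposure in self.covariates:
            raise ValidationError("exposure cannot also be a covariate")
        if self.response in self.covariates or self.response == self.exposure:
            raise ValidationError("response cannot appear on the right-hand side")
        if self.family not in ("linear", "logistic"):
            raise ValidationError(f"unknown family {self.family!r}")


@dataclass
class AssociationResult:
    """Effect estimate for the exposure term of one fitted model."""

    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    or_value: float | None = None
    fdr: float | None = None

    def as_dict(self) -> dict:
        return {
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "n": self.n,
            "or": self.or_value,
            "fdr": self.fdr,
        }


def _zscore(x: pd.Series) -> pd.Series:
    sd = x.std(ddof=1)
    if sd == 0 or not math.isfinite(sd):
        raise ModelError(f"column {x.name!r} has zero variance; cannot standardize")
    return (x - x.mean()) / sd


def _design(table: pd.DataFrame, spec: ModelSpec) -> tuple[pd.Series, pd.DataFrame]:
    cols = [spec.response, spec.exposure] + list(spec.covariates)
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValidationError(f"column(s) not in table: {missing}")
    data = table[cols].dropna()
    y = data[spec.response]
    if spec.family == "logistic":
        vals = set(pd.unique(y))
        if not vals <= {0, 1, True, False}:
            raise ValidationError(f"logistic response {spec.response!r} is not binary: {vals}")
        y = y.astype(float)
    parts = []
    exposure = data[spec.exposure].astype(float)
    if spec.standardize:
        exposure = _zscore(exposure)
    parts.append(exposure.rename(spec.exposure))
    for cov in spec.covariates:
        if cov in spec.categorical:
            series = data[cov].astype("category")
            ref = series.value_counts().idxmax()
            levels = [ref] + [l for l in series.cat.categories if l != ref]
            dummies = pd.get_dummies(
                series.cat.reorder_categories(levels), drop_first=True, prefix=cov
            ).astype(float)
            parts.append(dummies)
        else:
            c = data[cov].astype(float)
            if spec.standardize:
                c = _zscore(c)
            parts.append(c.rename(cov))
    x = pd.concat(parts, axis=1)
    if spec.family == "linear" and spec.standardize:
        y = _zscore(y.astype(float))
    n_params = x.shape[1] + 1
    if len(data) < n_params + 10:
        raise InsufficientDataError(
            f"{len(data)} complete cases for {n_params} parameters (need >= {n_params + 10})"
        )
    return y, sm.add_constant(x, has_constant="add")


def fit_association(table: pd.DataFrame, spec: ModelSpec) -> AssociationResult:
    """Fit one association model; return the exposure coefficient.

    Complete-case OLS (linear) or maximum-likelihood logit (logistic); with
    ``standardize``, continuous variables are z-scored first so the linear beta
    is in SD units. CIs are t-based for linear fits, Wald on the log-odds scale
    for logistic (exponentiated into the odds ratio separately).
    """
    y, x = _design(table, spec)
    rank = np.linalg.matrix_rank(x.to_numpy())
    if rank < x.shape[1]:
        corr = x.drop(columns="const").corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.max().idxmax() if len(corr) else "?"
        raise ModelError(f"rank-deficient design (suspect column {worst!r})")
    try:
        if spec.family == "linear":
            fit = sm.OLS(y, x).fit()
        else:
            fit = sm.Logit(y, x).fit(disp=0, maxiter=100)
            if not fit.mle_retvals.get("converged", True):
                raise ModelError(f"logistic fit did not converge for {spec.response!r}")
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise ModelError(f"model failed for response {spec.response!r}: {exc}") from exc
    beta = float(fit.params[spec.exposure])
    se = float(fit.bse[spec.exposure])
    ci_low, ci_high = (float(v) for v in fit.conf_int().loc[spec.exposure])
    return AssociationResult(
        beta=beta,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        p=float(fit.pvalues[spec.exposure]),
        n=int(fit.nobs),
        or_value=math.exp(beta) if spec.family == "logistic" else None,
    )


def phenome_screen(
    table: pd.DataFrame,
    exposure: str,
    phenotypes: Mapping[str, str],
    covariates: Sequence[str] = (),
    categorical: Sequence[str] = (),
    min_cases: int = 200,
    min_measured_fraction: float = 0.5,
    fdr_method: str = "fdr_bh",
) -> pd.DataFrame:
    """Screen many phenotypes against one exposure with eligibility filters and FDR.

    ``phenotypes`` maps column name -> type ('continuous' or 'binary').
    Binary phenotypes need >= ``min_cases`` cases; every phenotype needs a
    value for >= ``min_measured_fraction`` of the table. Ineligible phenotypes
    appear in the output with their exclusion reason and no estimate; BH-FDR is
    computed across the eligible set only. Rows are ordered by input order.
    """
    import warnings

    rows = []
    total = len(table)
    for pheno, kind in phenotypes.items():
        if kind not in ("continuous", "binary"):
            raise ValidationError(f"phenotype {pheno!r} has unknown type {kind!r}")
        measured = table[pheno].notna().sum() if pheno in table.columns else 0
        reason = None
        if pheno not in table.columns:
            reason = "missing_column"
        elif measured < min_measured_fraction * total:
            reason = "min_measured_fraction"
        elif kind == "binary":
            cases = int((table[pheno] == 1).sum())
            if cases < min_cases:
                reason = "min_cases"
        row = {"phenotype": pheno, "type": kind, "n_measured": int(measured),
               "excluded": reason}
        if reason is None:
            spec = ModelSpec(
                response=pheno,
                exposure=exposure,
                covariates=list(covariates),
                categorical=list(categorical),
                family="linear" if kind == "continuous" else "logistic",
            )
            try:
                res = fit_association(table, spec)
                row.update(res.as_dict())
            except (ModelError, InsufficientDataError) as exc:
                row["excluded"] = f"model_error: {exc}"
        rows.append(row)
    out = pd.DataFrame(rows)
    eligible = out["excluded"].isna() & out["p"].notna() if "p" in out.columns else []
    if "p" in out.columns and eligible.any():
        _, fdr, _, _ = multipletests(out.loc[eligible, "p"], method=fdr_method)
        out.loc[eligible, "fdr"] = fdr
    else:
        warnings.warn("no eligible phenotypes in screen", stacklevel=2)
    return out


def genomic_inflation(pvalues: Iterable[float]) -> float:
    """Genomic inflation factor: median observed chi-square over the null median.

    lambda = median(chi2_quantile(1 - p, df=1)) / chi2_quantile(0.5, df=1).
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    observed = stats.chi2.isf(p, df=1)  # == ppf(1 - p)
    return float(np.median(observed) / stats.chi2.ppf(0.5, df=1))


def se_from_beta_p(beta: float, p: float) -> float:
    """Recover the Wald standard error from an effect size and its p-value."""
    if not 0 < p < 1:
        raise ValidationError(f"p must lie strictly in (0, 1), got {p}")
    if not math.isfinite(beta):
        raise ValidationError("beta must be finite")
    z = stats.norm.isf(p / 2)
    return abs(beta) / z


def ivw_mr(
    beta_exposure: Sequence[float],
    beta_outcome: Sequence[float],
    se_outcome: Sequence[float],
) -> tuple[float, float, float]:
    """Fixed-effect inverse-variance-weighted Mendelian randomization.

    beta_hat = sum(bx * by / se_y^2) / sum(bx^2 / se_y^2), with
    se(beta_hat) = sqrt(1 / sum(bx^2 / se_y^2)) and a Wald p-value. Instruments
    must be pre-harmonized to the same effect allele. Returns (beta, se, p).
    """
    bx = np.asarray(beta_exposure, dtype=float)
    by = np.asarray(beta_outcome, dtype=float)
    sy = np.asarray(se_outcome, dtype=float)
    if bx.size == 0:
        raise ValidationError("no instruments")
    if not (bx.size == by.size == sy.size):
        raise ValidationError("instrument vectors differ in length")
    if np.any(sy <= 0):
        raise ValidationError("outcome SEs must be positive")
    if np.all(bx == 0):
        raise ValidationError("all exposure betas are zero")
    w = bx**2 / sy**2
    beta = float(np.sum(bx * by / sy**2) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    p = float(2 * stats.norm.sf(abs(beta) / se))
    return beta, se, p


def effect_profile_correlation(
    profile_a: pd.DataFrame,
    profile_b: pd.DataFrame,
    fdr_threshold: float = 0.01,
) -> tuple[float, float, int]:
    """Pearson correlation between two per-feature effect-size profiles.

    Restricts to features significant in ``profile_a`` (column ``fdr`` <
    threshold), matches ``profile_b`` on the shared feature index, and
    correlates the ``beta`` columns. Returns (r, p, n_features).
    """
    sig = profile_a[profile_a["fdr"] < fdr_threshold]
    shared = sig.index.intersection(profile_b.index)
    if len(shared) < 3:
        raise InsufficientDataError(
            f"only {len(shared)} shared significant features (need >= 3)"
        )
    r, p = stats.pearsonr(sig.loc[shared, "beta"], profile_b.loc[shared, "beta"])
    return float(r), float(p), int(len(shared))


QUANTILE_LABELS = ["Low", "Mid-Low", "Mid", "Mid-High", "High"]


def quantile_trend(
    table: pd.DataFrame,
    grouping_variable: str,
    outcome: str,
    n_groups: int = 5,
) -> pd.DataFrame:
    """Outcome mean and 95% t-CI per equal-count quantile group of a variable.

    Five groups are labeled Low .. High; other group counts get Q1..Qk labels.
    CI: mean +/- t(0.975, n-1) * s / sqrt(n).
    """
    data = table[[grouping_variable, outcome]].dropna()
    if len(data) < 2 * n_groups:
        raise InsufficientDataError(
            f"{len(data)} complete cases for {n_groups} quantile groups"
        )
    labels = QUANTILE_LABELS if n_groups == 5 else [f"Q{i + 1}" for i in range(n_groups)]
    try:
        groups = pd.qcut(data[grouping_variable], n_groups, labels=labels)
    except ValueError as exc:
        raise ValidationError(
            f"cannot form {n_groups} distinct quantile bins of {grouping_variable!r}: {exc}"
        ) from exc
    rows = []
    for label in labels:
        vals = data.loc[groups == label, outcome].to_numpy(dtype=float)
        n = len(vals)
        mean = float(vals.mean())
        half = float(stats.t.ppf(0.975, n - 1) * vals.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan
        rows.append({"group": label, "n": n, "mean": mean,
                     "ci_low": mean - half, "ci_high": mean + half})
    return pd.DataFrame(rows)


def group_difference_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    paired: bool = False,
) -> tuple[float, float]:
    """Rank-based two-group test: Wilcoxon signed-rank (paired) or Mann-Whitney U."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise InsufficientDataError("need >= 3 observations per group")
    if paired:
        if a.size != b.size:
            raise ValidationError("paired test requires equal-length samples")
        diffs = a - b
        if np.all(diffs == 0):
            raise ValidationError("all paired differences are zero (degenerate)")
        stat, p = stats.wilcoxon(a, b)
    else:
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            raise ValidationError("all observations tied (degenerate)")
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(stat), float(p)
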