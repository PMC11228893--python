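# Methods

## The proxy estimator

Let `R` be the number of alignment records overlapping any 18S-analogue region
by at least one base (each record counted once even if it spans several
regions) and `B` the number of records mapped to chromosomes 1–22 (either
`chr1` or `1` naming dialect; unmapped records never count). The 18S Ratio is
`R / B`, and the copy-number equivalent is

```
CN = (R / B) × G / L
```

with `G = 2,875,001,522` bases (the summed Hg38 chr1–22 lengths) and
`L = 1,871` bases (the 18S subunit size). Both constants are configurable
(`ConversionConstants`). Note a two-base tension in the inputs: the 18S query
spans unit positions 3,658–5,526 (1,869 bases) while the conversion constant
is 1,871; the package keeps 1,871 as the default conversion constant and
documents rather than resolves the discrepancy.

The estimator assumes reads sample the genome uniformly, so the expected
region fraction grows with rDNA copy number. The independent cross-validation
estimator — `2 × mean 18S depth / mean filtered-exome depth` from a
tailored-assembly alignment — shares no counting machinery with the proxy and
is used to check cross-method concordance on synthetic data.

### Counting policy

The default counts all mapped records, including secondary, supplementary and
duplicate records, matching an unfiltered flag-agnostic count; a
`primary_only` policy is available for stricter modern pipelines. Overlap is
≥ 1 aligned base; no minimum-overlap fraction is applied. A missing numbered
baseline flags the sample with a machine-readable reason instead of aborting a
batch run. CRAM inputs require the reference FASTA.

### Sequencing-center adjustment

Coverage-derived estimates shift systematically between sequencing centers.
The adjustment fits `ratio ~ center` (one categorical factor, chosen reference
level) on all provided samples and subtracts each non-reference center's
coefficient from its samples' ratios. For a single-factor model the
coefficient is exactly the difference of center means, so after adjustment all
center means coincide to floating tolerance and the transform is idempotent.
Single-center input is returned unchanged with a warning. The fit is global
across all supplied samples by design; re-fitting within subsets is possible
by calling the function on the subset.

## Reference preparation

- **18S query**: inclusive 1-based extraction from the rDNA unit (defaults
  3,658–5,526).
- **Looped reference**: a pure rotation of the unit placing the sequence ends
  2,120 bp upstream of the TSS (the midpoint of the repetitive element nearest
  the unit's 3' end), so alignment coverage is not lost at the promoter.
  Length and residue multiset are preserved for any input and breakpoint.
- **Analogue discovery**: a self-contained ungapped seed-and-extend search
  (exact 16-mer seeds, both strands, extension to the diagonal bounds with
  terminal mismatch trimming). Matches with identity ≥ `min_identity`
  (default 0.90) over ≥ `min_length` (default 100) aligned bases are merged
  into forward-coordinate intervals sorted by contig and start. Real rDNA
  analogues are high-identity pseudo-copies, so gapped alignment is not
  needed at this scale; a curated BED can always be supplied instead of
  running discovery. E-values and bit scores are out of scope.

Coordinates are 0-based half-open internally; 1-based inclusive values are
converted at the boundary (BED stays 0-based half-open).

## Relatedness

Kinship bands (configurable `KinshipThresholds`): MZ strictly above 0.4;
first degree 0.177–0.354 (both ends inclusive); second degree from
`boundary_23` (default 0.0884 = 2^-3.5, the canonical KING cutoff) up to but
excluding 0.177; third degree from 0.0442 up to but excluding `boundary_23`;
everything else unrelated, including the (0.354, 0.4] gap. Lower bounds are
inclusive and upper bounds exclusive so classification is total and disjoint.
The 0.0844 variant of the second/third boundary is supported via
configuration.

First-degree pairs with IBS0 below 0.0012 are parental — unless the birth gap
is under 10 years (biologically implausible for parent-offspring) or the
birth years are unknown, in which case the pair is discarded as unverifiable;
IBS0 at or above threshold is fraternal.

Families are connected components of the pair graph (networkx), labeled in
order of smallest member id for determinism. The unrelated subset keeps all
individuals without a pair record plus exactly one member per family: the
oldest (smallest birth year), ties and all-missing families resolved to the
lexicographically smallest id (the latter flagged by a warning).

## Derived phenotypes

- **Blood ratios**: NLR = N/L, PLR = P/L, LMR = L/M, SII = N × P / L (counts
  in 10⁹ cells/L). A zero denominator leaves the ratio missing; missing
  inputs propagate. (A variant form of SII with L and P exchanged circulates
  in some summaries; the N × P / L form is the standard definition and the one
  implemented.)
- **Blood-composition PCs**: correlation-matrix PCA (z-scored inputs, SVD) of
  the five nucleated white-cell percentages after excluding participants with
  any nucleated red blood cells (their composition reflects pathology).
  Because the percentages are compositional (rows sum to 100), the data have
  rank ≤ 4 and the first four components explain ≥ 99.99% of the variance;
  the default returns those four scores.
- **eGFR**: the three sex-specific piecewise power formulas (creatinine,
  cystatin C, combined), with creatinine converted from μmol/L via a
  configurable factor (default 0.0133 as printed in the source material;
  the conventional value is 1/88.42 ≈ 0.0113). All coefficients live in
  `EGFRCoefficients`. Two printed-form quirks are preserved as defaults with
  escape hatches: (i) the cystatin-only formula's max kernel takes cystatin C
  by default (internally consistent) with `strict_as_printed=True` switching
  to serum creatinine as printed; (ii) the min-kernel exponent `alpha_cr`
  defaults to the printed 0.9 (male) / 0.7 (female), which duplicates κ and
  makes the creatinine formulas non-monotone below κ — the canonical negative
  exponents (−0.302 / −0.241) can be supplied via configuration, restoring
  global monotonicity. Each formula is continuous at its kernel breakpoints.
  Missing biomarkers yield missing output; non-positive values raise.
- **Renal groups**: glomerular disease (N00–N08), kidney failure (N17–N18),
  urolithiasis (N20–N23) by default. A participant is a case for a group iff
  any member code carries a valid first-report date; the special-meaning date
  1903-03-03 counts as missing; other unparseable dates raise.
- **Cohort filters**: FILTERED removes blood-cancer and blood-disorder codes,
  pregnancy (status 1 or 2), leukocytes > 200×10⁹/L, hemoglobin > 20 g/dL,
  hematocrit > 60%, platelets > 1000×10⁹/L, and blood processed > 36 h after
  venepuncture. FILTERED_UNMEDICATED additionally removes listed medications
  (the six statin codes ship as defaults) and anyone flagged as taking other
  prescription medication; HEALTHY additionally removes any recorded
  cancer/non-cancer illness, congenital codes, current smokers (status not in
  {0, 1}) and BMI > 30 kg/m². Subsets are nested by construction. The engine
  is the method: the shipped code lists are editable placeholders and must be
  replaced with a cohort's curated lists; passing no rules is a configuration
  error.

## Association machinery

- **Model fits**: complete-case OLS / Logit (statsmodels). With
  standardization on (the default), every continuous variable — the linear
  response included — is z-scored, so the linear beta is in SD units and a
  covariate-free simple regression beta equals the Pearson correlation.
  Categorical covariates expand to indicators with the most frequent level as
  reference. CIs are t-based (linear) or Wald on the log-odds scale
  (logistic, exponentiated to an OR). Rank deficiency and non-convergence
  raise naming the offending column; at least `parameters + 10` complete
  cases are required.
- **Phenome screen**: one model per declared phenotype (types come from a
  manifest, not inferred), with eligibility filters of ≥ 200 cases for binary
  phenotypes and values recorded for ≥ 50% of the table; ineligible
  phenotypes are reported with their exclusion reason. Benjamini–Hochberg FDR
  is computed across the eligible set of each invocation.
- **Genomic inflation**: λ = median(χ²₁-quantile(1 − p)) / χ²₁-quantile(0.5).
- **SE recovery**: se = |β| / Φ⁻¹(1 − p/2), for summary statistics reporting
  only beta and p.
- **IVW MR**: fixed-effect inverse-variance weighting,
  β̂ = Σ(βx βy / se_y²) / Σ(βx² / se_y²), se = (Σ βx²/se_y²)^(−1/2), Wald p.
  Instruments must arrive harmonized; clumping, harmonization, random-effects
  IVW and MR-Egger are out of scope.
- **Quantile trends**: five equal-count groups labeled Low…High, per-group
  mean with mean ± t(0.975, n−1)·s/√n intervals.
- **Group tests**: Wilcoxon signed-rank (paired) / Mann–Whitney U (unpaired)
  via scipy.

## Synthetic data

The read simulator is placement-only: each read joins the rDNA compartment
with probability `cn·L / (cn·L + G)` and lands uniformly within an analogue
region, else uniformly (length-weighted) on the numbered background contigs.
Analogue regions sit on an unplaced scaffold-style contig — as most real 18S
analogues do — so the numbered baseline counts exactly the background
compartment and `E[region/background] = cn·L/G`, making the estimator
unbiased on its own sampling model. Defaults: two 1 Mb background contigs,
two 1 kb analogue regions (L_toy = 2 kb), read length 100. No sequencing
errors, base qualities, GC bias or mappability structure are simulated; the
estimator consumes placements, so passing tests validate counting and
normalization semantics, not robustness to real-data coverage biases.

Cohort simulation draws true CN per participant from N(315, 80²) truncated to
[50, 800] (the commonly quoted ~100–600 diploid range). Family blocks share a
latent component, `z = √ρ·family + √(1−ρ)·individual`, giving intra-family
correlation ρ in expectation. Observed ratio = (CN + center offset +
measurement noise) × L/G, with a default +8-copy Sanger-vs-deCODE offset to
exercise the adjustment path and 5 copies of measurement noise. Continuous
traits are `β·z(CN) + N(0, 1−β²)` so the standardized regression slope equals
β by construction; binary traits use a logistic link with a specified
log-odds per SD of CN and baseline rate. An optional seasonal trait varies
with month while CN does not, for reverse-causality controls. All generators
are bit-reproducible given a seed and return truth tables; tests assert
against truth, never re-derive it.

## Problem sizes and numerical choices

The validation suite runs at sizes chosen to make sampling error small
relative to the tested tolerances while staying desk-scale: estimator
recovery uses 150,000 reads per alignment at CN ∈ {100, 300, 600} (binomial
SE ≈ 1–3 copies); concordance uses 94 samples at 300,000 reads; screen
calibration uses 20,000 participants × ~100 phenotypes; effect-size recovery
uses 50 replicates at n = 150,000 with one replicate set per parameter
(standardized β = 0.0273 for the linear anchor, log-odds ln 1.04 at 8% base
rate for the logistic anchor), asserting ≥ 93% CI coverage. The genomic
inflation null check uses 10⁶ uniform p-values with tolerance 0.01.

Ties in quantile binning raise rather than silently merging bins; zero
baselines flag samples rather than dropping them; missing data propagate and
are never zero-imputed.

## Known limitations

- No GC or mappability correction; the proxy inherits any coverage bias of
  the input alignments (center adjustment and covariates mitigate, not
  remove, such effects).
- Per-copy variant genotyping within rDNA units is out of scope.
- The analogue search is ungapped and aimed at high-identity copies; diverged
  or heavily indel-containing analogues would need an external aligner, whose
  BED output the pipeline accepts directly.
- Exact record-class parity with any particular cohort's CRAM counting
  pipeline cannot be asserted in general; the counting policy is explicit and
  configurable instead.
- The synthetic cohort generates effects directly on the CN z-score;
  measurement noise on the observed ratio produces the usual (here
  negligible, ~0.5%) regression-dilution attenuation when associations are
  fit on observed rather than true values.
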