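# Methods

## Model and procedure

The pipeline tests whether genome-wide heterozygosity is associated with
case status in a case-control cohort. Its stages and the statistical
assumptions behind them:

**Genotype substrate.** Biallelic autosomal SNVs coded as alt-allele counts
0/1/2 with a dedicated missing sentinel (−1). Phase is irrelevant to
heterozygosity and is discarded on input; half calls and `./.` are missing;
multiallelic and non-SNV records are skipped rather than split, because the
per-individual statistics below are defined for biallelic sites and
splitting would count one individual twice at one locus. X/Y/MT variants
are carried through I/O and QC (the X is what powers the sex check) but are
excluded from every heterozygosity statistic: male hemizygosity would
otherwise make sex a structural confounder of observed heterozygosity.

**QC.** Sample filters first, then variant filters on the surviving
samples, each variant attributed to exactly one filter in the report:

1. *Duplicates*: pairwise identity-by-state (share of identical codes over
   mutually non-missing variants) ≥ `ibs_min` (default 0.95). The pair
   member with fewer missing calls survives (ties: lexicographically
   smaller id). Pairs with < 50 overlapping variants are skipped as
   unreliable. No kinship estimation beyond exact duplicates.
2. *Sex discordance*: X-heterozygosity per sample; recorded females below
   0.05 or recorded males above 0.10 are removed. The wide gap between the
   two thresholds separates hemizygous males (rate ≈ genotyping error)
   from females (rate ≈ mean 2pq over X sites, typically ≳ 0.2).
3. *Missingness*: variants with missing fraction strictly above 5% removed.
4. *Hardy–Weinberg*: the exact conditional test (enumeration of all
   heterozygote counts compatible with the observed allele counts; p = sum
   of configurations no more probable than the observed one; no mid-p) at
   α = 1e-6 over all samples, autosomes only. Published cohort analyses of
   this kind rarely state the threshold or sample scope, so the
   conventional genome-wide default is used and both are exposed in
   `QCConfig` (`hwe_scope="controls"`
   restricts the test to controls). A chi-square alternative was
   considered and rejected: at desk scale the exact test costs little and
   its calibration at small minor-allele counts is exactly what the filter
   relies on.
5. *MAF*: keep minor allele frequency strictly **greater than** the
   threshold (default 0.01). Strict ">" for keeping reconciles the two
   conventions "MAF < 0.01 excluded" and "MAF > 0.01 kept".

Frequencies are recomputed after sample removal and on the merged
case+control set. Population-structure outlier removal is out of scope; a
user-supplied exclusion list (`QCConfig.exclude_samples`) is the hook.

**Heterozygosity metrics.** Per sample, over autosomal variants with MAF
strictly above the stratum threshold (default strata 0.01 and 0.1):

- `het_rate = n_het / n_hom_alt`. This literal definition (heterozygotes
  over homozygous-*alternative* genotypes) is unusual — most tooling
  divides by all homozygotes or all calls — so a `hom_all` denominator
  option is provided; the default follows the definition as stated.
  A sample with zero hom-alt genotypes has an undefined het_rate and is
  dropped from *both* metrics with a warning, keeping one shared analysis
  set.
- `h_obs = n_het / n_called`; `h_exp` = mean over the sample's own
  non-missing sites of `2p(1−p) · 2N/(2N−1)` (per-site called count N;
  the small-sample factor matches standard per-sample expected-homozygosity
  tooling and is toggleable). Computing both rates over the same per-sample
  site set makes their ratio invariant to whether counts or rates are used,
  even under per-sample missingness.
- `het_excess = (h_obs − h_exp)/h_exp = h_obs/h_exp − 1 = −F̂`, with
  F̂ the method-of-moments inbreeding estimate. This identity is asserted
  exactly in the tests.

Both metrics are z-scored (sample SD, n−1) across **all** retained samples,
cases and controls together, once per stratum. Subgroup regressions reuse
these full-set z-scores rather than re-standardising, so effect sizes are
on one scale across the grid; per-subgroup re-standardisation would change
the meaning of "per SD" between cells.

**Association.** Logistic regression of status (case = 1) on the z-scored
metric, fit by IRLS/Newton scoring: convergence when max |score| < 1e-8 or
relative log-likelihood change < 1e-10, at most 100 iterations, Wald SEs
from the observed information, and complete separation (diverging
coefficients, |β| > 30 with damped steps) flagged as `converged=False`
rather than raised. Covariates: age and BMI untransformed, sex coded
female = 0 / male = 1 (reference = the majority group; any fixed coding
leaves the heterozygosity β unchanged), diabetes yes = 1 optionally. Rows
with any missing covariate are dropped listwise, counts logged. The 95% CI
is exp(β ± 1.96·SE); the per-SD OR is exp(β). No multiple-testing
correction across the 12-cell grid — each cell is interpreted at α = 0.05,
matching the design the package reproduces. The unadjusted model
(`covariates=[]`) is the replication-cohort design, where age and BMI are
unavailable and all participants are female. Descriptives: pooled-variance
two-sided t-tests for age/BMI, chi-square without continuity correction for
sex proportions, Pearson correlation (t transform, n−2 df) for
covariate–heterozygosity relationships.

## The synthetic-data generator

Real genotype matrices for cohorts of this design are not publicly
deposited, so validation rests on a generator whose defaults encode the
discovery-cohort conditions: 677 samples (559 cases, 172/559 hip), 20,000
SNPs with MAF ~ Uniform(0.05, 0.5), per-sample F ~ truncated
Normal(0.01, 0.01²) (clamped to [−0.05, 0.5]), age ≈ 62 ± 9 y,
BMI ≈ 32 ± 6 kg/m², 56% female, 15% diabetes, age/BMI–(−F) correlations
−0.09/+0.09, a protective effect of OR 0.6 per SD of heterozygosity
propensity, and 0.5% missingness (imputed data are near-complete). The
cohort-scale covariate means sit between the observed case and control
groups since the generator draws covariates before assigning status.

Genotypes are independent draws per sample × variant from the inbreeding
multinomial P(het) = 2p(1−p)(1−F), P(hom_alt) = p² + F·p(1−p),
P(hom_ref) = (1−p)² + F·p(1−p), with negative F clamped per variant to the
largest value keeping all probabilities non-negative (allowing mildly
outbred individuals without rejecting configs). The heterozygosity
propensity is s = z(−F), so the configured `beta_het` is directly a per-SD
log-odds comparable to the reported ORs. The intercept is tuned by
bisection against a fixed uniform draw — the map from intercept to realised
case count is then a monotone step function — until the realised case
fraction is within ±0.01 of target (exact at the default sizes, which is
how the 559/118 and 2,019/2,029 presets hit their counts exactly).
Injectable QC violations (heterozygote-deficit variants redrawn at F = 0.8,
exact duplicate samples, recorded-sex swaps, a sex-aware X block with
hemizygous males) are registered in a ground-truth object for recall tests.
All draws flow from one seed through named substreams (frequencies, F,
genotypes, covariates, outcome, artifacts), so changing one count never
shifts unrelated draws.

What the generator does **not** emulate: linkage disequilibrium,
population stratification, imputation error, array batch effects, and
runs-of-homozygosity structure. Passing tests therefore show the estimator
is correct and calibrated under independent loci and a homogeneous
population; on real data, LD inflates the variance (not the expectation) of
the per-sample means, and stratification or batch structure can confound
heterozygosity with status in ways the model does not address.

## Numerical choices and test conditions

- HWE exact-test probabilities via log-gamma with max-subtraction, cached
  per (minor-allele count, sample count); ties in the "no more probable"
  comparison use a 1e-9 relative tolerance. Verified against exact
  rational-arithmetic enumeration for every genotype triple with total ≤ 50.
- z-scores must standardise to mean 0 / SD 1 within 1e-10; constant vectors
  are an error, not a silent zero.
- Logistic MLE verified two ways: a nested grid-search likelihood maximiser
  on small fixtures, and statsmodels' GLM on larger ones.
- Recovery-test scale follows the design constraint that z(−F) and
  z(het_excess) correlate > 0.95, which requires the F spread to dominate
  the binomial measurement noise of the per-sample mean
  (≈ √(h̄(1−h̄)/m)/h̄, about 0.008 at 20k SNPs): recovery and coverage
  simulations use F ~ Normal(0.05, 0.05²) at 10–20k SNPs, where the
  residual attenuation of the fitted per-SD log-odds is within the stated
  tolerances (±0.05 on the F slope, ±0.1 on an OR of 0.6, nominal CI
  coverage within Monte-Carlo error at 300 replicates). The type-I-error
  calibration uses 500 replicates of 300 samples × 2,000 SNPs with
  F ~ Normal(0.01, 0.01²) and no effect; problem sizes were fixed from
  these power calculations before measuring.
- Pipeline outputs are byte-deterministic for a fixed seed; floats are
  written at 6 significant digits.

## Known limitations

- HetRate's default denominator (hom-alt only) makes it allele-frequency
  sensitive by construction; het_excess is the frequency-robust metric, and
  the association direction — not the metrics' numerical equality to any
  external tool — is the tested contract.
- Duplicate detection is O(n²) in samples via three matrix products; fine
  to ~10⁴ samples, not intended for biobank scale.
- No LD pruning, relatedness beyond duplicates, imputation, dosage input,
  or population-structure correction (see the QC hook).
- The exact HWE filter assumes diploid autosomal genotypes; X variants are
  never HWE-filtered.
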