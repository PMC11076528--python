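# Methods

## Model and procedure

### The passenger clock

Hematopoietic stem cells accumulate clock-like C>T and T>C substitutions at
an approximately constant rate. When a driver lesion (here, an mCA) is
acquired at age t_d, every passenger already present in the founding cell
("ancestral" passengers) rides along as the clone expands, while later
passengers remain private to sub-lineages and mostly sit below the
detection limit of ~38x whole-genome sequencing. The detectable passenger
count therefore scales with t_d. Conditional on age and clone size, a
*larger* count implies a *later* driver, hence a faster-expanding — fitter
— clone. The score pipeline operationalizes this:

1. NB2 negative-binomial regression (log link, variance mu + alpha·mu²) of
   total passenger count on age, sex(female=1), clonal fraction, and study
   indicators when more than one study is present.
2. Raw (response-scale) residuals y − mu_hat.
3. Yeo-Johnson power transform with lambda chosen by maximum likelihood,
   then standardization to mean 0, variance 1.

The residual type is a free choice the source analyses leave open; because
the Yeo-Johnson map is strictly monotone per vector, Pearson or deviance
residuals change only the spacing, never the ranks. Both are available via
`residual_type=`, and a rank-based inverse-normal transform (Blom offsets,
(r − 3/8)/(n + 1/4)) via `transform="rank"`. The germline association scan
intentionally uses the rank-based transform of the counts themselves, the
convention of quantitative-trait GWAS, rather than the scoring module's
Yeo-Johnson-of-residuals path.

### Filtering semantics

All published thresholds are implemented as strict inequalities exactly as
printed, so boundary values pass: a call with lod_baf_phase = 20
(autosomal) or 5 (sex chromosome) is retained, depth 25 and 100 pass,
VAF 0.35 passes, a 2.0 Mb call passes the minimum-size rule. The
constitutional-duplication screens apply on the inclusive size windows
[2, 10] Mb (relative coverage > 2.25) and [50, 250] Mb (> 2.5); sizes in
the unnamed 10-50 Mb gap face no duplication rule, mirroring the two
explicit windows. Coordinates are 1-based inclusive and
size_mb = (end − start + 1)/1e6. "Clock-like" is evaluated after
normalizing each substitution to its pyrimidine-reference representation
(the convention of signatures SBS1/SBS5), so G>A and A>G qualify; a
`literal_strand=True` switch restricts to literal C>T/T>C for sensitivity
analysis. Calls with copy type `undetermined` pass quality filters but are
excluded from copy-type-specific aggregation.

Arm assignment uses a bundled table of approximate GRCh38 centromere
midpoints; a call entirely below the midpoint is `p`, entirely above is
`q`, anything spanning it is `whole`. In the curated malignancy classes, a
chromosome-level entry ("gain of chromosome 12") matches any arm, and an
arm-level entry is also matched by a whole-chromosome call. The lymphoid
and myeloid sets genuinely overlap at CN-LOH of 9q; the single-label
classifier applies precedence pv > lymphoid > myeloid (the order the sets
are defined in), and `class_membership` exposes the full set.

## The synthetic cohort generator

The generator emulates the data-generating story the method assumes, not a
particular dataset.

- **Clone growth**: deterministic logistic,
  cf(t) = e^{s·dt} / (N_HSC + e^{s·dt} − 1), a single founder expanding
  with per-year fitness s inside an effective stem-cell pool of fixed size
  N_HSC (default 2×10⁴, within the order-of-magnitude range of estimates
  of actively contributing HSCs). A stochastic branching process would add
  realism but not change the passenger-fitness relationship the method
  exploits; the deterministic law is seed-stable and analytically
  transparent.
- **Driver timing**: t_d uniform over (0, age) — a neutral prior,
  configurable.
- **Detection window**: clones are retained when cf at blood draw lies in
  [0.05, 0.95]. The lower bound is the mosaic-call detection limit
  (configurable; ~0.08-0.10 matches SNV detectability at 38x and is the
  natural "high" setting). The upper bound reflects that a clone at cf ≈ 1
  produces complete LOH indistinguishable from a constitutional event —
  exactly what the constitutional filters strip in real pipelines.
- **Passengers**: latent ancestral count Gamma-Poisson with mean
  mu·t_d and shape k (defaults mu = 4/yr, k = 3). HSCs accrue ~10-12
  clock-like substitutions per year genome-wide of which roughly a third
  are detectable at 38x, and the resulting cohort count scale (median a
  few tens) matches real passenger burdens. The Gamma-Poisson choice makes
  the NB2 scoring model correctly specified by default; a lognormal
  frailty switch (`frailty="lognormal"`) provides a misspecification
  stress test. Counts are allocated across autosomes + X proportionally to
  GRCh38 lengths; an adversarial switch concentrates a chosen fraction on
  the mCA chromosome to give the exclusion diagnostics something to catch.
- **Sequencing**: depth ~ Poisson(38); a passenger's VAF is
  Binomial(depth, cf/2)/depth, i.e. a heterozygous site in a diploid
  clone. CN-LOH duplication of passenger alleles (which can push VAF
  toward cf) is not modeled; the cf/2 rule is kept uniformly.
- **Contaminants**: non-clock-like somatic substitutions (rate 0.5·mu),
  germline heterozygous variants at VAF ≈ 0.5 (mean 8/sample), CHIP-gene
  annotated variants, plus sample-level nuisances (second mCAs, CHIP
  carriers, BAF-autocorrelation failures, sex discordance) so every filter
  has true rejections to perform. The generator records its own intended
  detectable-passenger count per subject with an independent inline copy
  of the filter predicates; an end-to-end test checks the counting stage
  reproduces it exactly.
- **Fitness heterogeneity**: s is the lesion's base fitness times
  (1 + modifier_effect)^g for the germline modifier genotype g ~
  Binomial(2, MAF = 0.21), times a lognormal factor with log-SD 0.3.
  Without the lognormal term, within-lesion expansion rates would vary
  only through the modifier, contradicting the observed high variability
  among carriers of the same mCA and leaving the blood-count coupling
  nothing to detect. A tag SNP in LD with the modifier (haplotype flip
  probability 0.05, r² ≈ 0.8) supports the conditional-analysis
  demonstration.
- **Blood counts**: baseline normal draws at typical adult values;
  carriers of chr9p CN-LOH/loss (and JAK2-CHIP flagged samples) get an
  erythrocyte shift of `ery_coupling_9p` (default 0.3×10¹²/L) per SD of
  log fitness. The "strong" preset (1.3) represents the JAK2/polycythemia
  regime where the clone dominates erythrocyte variation.

What the generator does **not** emulate: read-level data, haplotype
phasing and BAF tracks, LD structure beyond the single tag SNP,
relatedness/population structure, age-dependent mutation-rate changes, and
clonal interference between multiple clones. Passing tests therefore show
that the pipeline recovers expansion rates *when the passenger-clock
assumptions hold*, not that those assumptions hold in any particular real
cohort.

## Numerical choices

- NB2 fitting: maximum likelihood via statsmodels with a Poisson warm
  start and moment-based initial alpha, BFGS (gtol 1e-10) with a
  Nelder-Mead fallback, then a damped Newton polish on the analytic
  score/Hessian to gradient norm < 1e-9. Covariate columns are
  standardized internally and coefficients (and delta-method standard
  errors) mapped back, which makes fitted means — and scores — exactly
  invariant to affine rescaling of any covariate. Constant covariate
  columns are absorbed by the intercept, so an all-constant design reduces
  to the intercept-only model whose fitted mean equals the sample mean.
  All-zero counts, rank-deficient designs, and n < 10 per covariate raise
  errors rather than fitting.
- Yeo-Johnson lambda is solved with Brent's method at tolerance 1e-12 so
  repeated runs agree to ~1e-8; the transform requires ≥ 20 finite,
  non-constant residuals.
- The chromosome-density diagnostic treats each subject's on-chromosome
  count as Binomial(total, length share) under uniform accrual and pools
  a z-statistic across subjects; it is exactly calibrated under the
  generator's null because allocation is multinomial given the total.
- The single-variant scan residualizes the outcome and each genotype on
  the covariates (QR-based Frisch-Waugh), which reproduces joint-OLS
  betas, SEs and p-values exactly with dof = n − p − 1, at a fraction of
  the cost. Missing genotypes (< 10% per variant) are mean-imputed;
  MAF ≤ 0.01 and constant or covariate-collinear variants are skipped and
  logged. Significance is flagged at 5×10⁻⁸.
- Fold changes divide median scores, which live on a standard-normal scale
  and can be negative; when the reference (X-loss) median is ≤ 0 every
  row carries a machine-readable `sign_warning` and a difference-of-
  medians column is provided as the stable alternative. "> 25
  individuals" for the external-fitness comparison is strictly greater.

## Problem sizes

Tests and the acceptance script simulate ~10⁴ subjects per cohort,
yielding scored cohorts of ~2,000 (the scale at which the recovery and
calibration properties are stated); smaller cohorts back the unit tests.
These sizes were chosen so that every stochastic claim is comfortably
powered while a full run stays in the minutes range on a single core.

## Known limitations

- Scores are relative within a fitted cohort (mean 0, SD 1); they are not
  comparable across separately fitted cohorts without harmonization.
- The cf/2 VAF rule plus the 35% VAF filter censors passengers of very
  large clones; the clonal-fraction covariate absorbs the mean effect but
  scores for near-fixed clones are noisier.
- Ratio-of-medians fold changes are unstable when the reference median is
  near zero (flagged, see above).
- Fixed-effects OLS stands in for kinship-adjusted mixed models; with
  related samples or population structure the scan's calibration claims
  do not transfer.
- The external-fitness comparison consumes a provided table; no
  population-genetic re-derivation of clonal-fraction-based fitness is
  attempted.
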