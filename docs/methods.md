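# Methods

`metaboqtl` implements, end to end, the statistical machinery of a
family-based metabolite-QTL study: quantification of metabolites from 1D
NMR spectra, variance-components heritability in an extended pedigree,
kinship-aware score-test GWAS with mode-of-inheritance scanning and a
metabolome-wide significance threshold, and conditional fine-mapping of
candidate variants against lead GWAS SNPs.  Because individual-level data
of such cohorts are not publicly deposited, the package ships a
synthetic-data layer that reproduces the statistical structure every
stage assumes; all verification studies run on that layer.

## Synthetic cohort

**Pedigree.** The generator emulates a genetic isolate: a small number of
founder couples (default 22), four generations, and zero-truncated
Poisson child counts (default mean parameter 2.55) so that every couple
in a breeding generation has at least one child and the pedigree stays
connected.  Children of non-final generations marry unrelated, married-in
spouses recorded as founders of their generation.  These defaults give
roughly 2,000 phenotyped descendants — the scale of the cohort design the
package emulates.  Households are full sibships; founders and spouses get
singleton households.  The phenotyped analysis cohort is the set of
descendants (both parents known), so every analyzed sample belongs to a
sibship household.

**Kinship.** Computed from the pedigree by the recursive tabular method
(phi(i,j) = ½[phi(f_i,j) + phi(m_i,j)], phi(i,i) = ½[1 + phi(f_i,m_i)])
in generation order.  The additive genetic covariance uses 2Φ.  Kinship is
treated as known nuisance input: marker-based kinship estimation is out
of scope because the simulated pedigree is known exactly.

**Genotypes.** Bi-allelic variants are organized in LD blocks.  Founder
haplotypes come from a per-block Gaussian copula: one latent normal per
block per haplotype plus an independent per-variant component; a
haplotype carries the effect allele when the resulting uniform falls
below the target frequency.  This yields the exact requested MAF in
expectation (a finite equally-weighted haplotype pool would quantize
frequencies to multiples of 1/pool-size), while the copula correlation
`block_ld` tunes within-block r² continuously; `block_ld = 1` makes a
block comonotone (r² ≈ 1 for equal MAFs, and for unequal MAFs
r² = p₁(1−p₂)/[p₂(1−p₁)], which is how tag SNPs with a chosen r² are
constructed).  Transmission is gene dropping: one whole parental
haplotype per block, chosen independently per block (free recombination
between blocks, none within).  Realistic recombination maps, genotyping
error and imputation are deliberately not modeled.

**Phenotypes.** y = Σ βⱼ(gⱼ − 2pⱼ) + a + c + e with a ~ MVN(0, σ²g·2Φ),
a household effect c shared within sibships, and iid residuals, scaled
so the trait has unit variance in expectation
(σ²e = 1 − h² − c² − Σ 2p(1−p)β²).  Age and BMI-like covariates and a
medication flag (rate 0.123, matching the 298/2,416 exclusion
bookkeeping of the emulated design) are generated independently of the
trait; the medication exclusion is therefore tested as plumbing, not as
confounding.

**Spectra.** Each metabolite is a signature of 1–3 pseudo-Voigt lines
with relative amplitudes summing to one.  The JRES projection uses the
narrow signature widths (0.005–0.009 ppm) with relatively high noise;
the CPMG spectrum re-broadens every line by a common factor (default
2.5, height-preserving), adds a linear baseline, and carries less noise
— the resolution/SNR trade-off the two experiments are combined for.
Acquisition physics (phasing, water suppression, true 2D processing) is
not modeled; the pipeline starts at the 1D projection because that is
where the computational method starts.

What passing tests on this generator do *not* show: robustness to
chemical-shift drift between samples, to peak-shape deviations from the
pseudo-Voigt family, to non-sibship household structure, or to
ascertainment; the generator draws all of these from the model the
analysis assumes.

## NMR quantification

Peaks are detected on the (batch-mean) JRES projection as local maxima
with a prominence floor of max(user fraction of max, 5 robust noise SDs),
seeded with half-maximum widths and Lorentzian fraction 0.5.  The
pseudo-Voigt is A·[η·L + (1−η)·G] with unit-height components sharing
the FWHM.  Fitting minimizes the residual sum of squares with
Nelder–Mead (standard coefficients; scipy implementation), windowed:
the axis is split at signal-free gaps (below max(0.5 % of max, 4 noise
SDs) for a run of about one linewidth) and over-full windows are split
again at the shallowest inter-peak dip, capping each simplex at 5 peaks
(20 parameters).  Parameters are transformed (log width/amplitude,
logistic η) so constraints can never be violated; each window restarts
the simplex from its optimum until no further improvement, and the
result is never worse than the starting point.  Non-convergence is
reported in the diagnostics, not raised.

CPMG quantification solves c ≈ Σ aₖ·shapeₖ + polynomial baseline, with
the JRES-fitted shapes re-broadened by a single per-batch width factor
estimated by bounded 1-D minimization of the pooled residual (default
search range 0.8–8).  Coefficients are non-negative by default
(concentrations are), via bounded least squares; plain least squares is
available by flag.  Peaks are grouped into metabolite candidates by
single-linkage on across-sample Pearson correlation (threshold 0.8); a
group's intensity is the sum of its member amplitudes, which equals the
concentration when the signature's relative amplitudes sum to one.

The QC step (robust-noise SNR from second differences, linear baseline
slope fitted to the lowest-quintile points) is an explicit stand-in: the
upstream protocols leave their QC criteria unspecified, so these
concrete checks are this package's own choices and are documented as
such.

## Trait preparation

Fixed order: sample exclusion → outlier removal → rank transform.
Outliers are values beyond k = 4 sample SDs from the mean, computed
once (single-shot; iterating the rule would be a different procedure,
and the single pass is idempotent).  A constant trait has SD 0 and loses
nothing.  Ranks are 1..m with average ties; inverse-normal scores are
available behind a flag for sensitivity analysis only.  Outliers are
removed before any covariate adjustment (the alternative ordering is
defensible; this one is fixed and logged).  Risk-factor association uses
Pearson correlation of covariate-adjusted residuals with a t-test on
n − #covariates − 2 degrees of freedom.

## Variance components (REML)

Model: y ~ N(Xβ, σ²g·2Φ + σ²c·H + σ²e·I), H the 0/1 household-sharing
matrix.  2Φ is eigendecomposed once per cohort (reused across traits);
H = ZZᵀ over household indicators admits a Woodbury identity, so each
restricted-likelihood evaluation costs O(n·q²) for q households rather
than O(n³).  The total variance is profiled out analytically; the two
variance fractions are optimized by Nelder–Mead over a softmax
parameterization (variances cannot go negative), starting from the best
of three admissible starting points, with an explicit boundary refit
when a fraction collapses below 10⁻⁶.  Standard errors come from a
central-difference Hessian in the absolute variances with delta-method
propagation to h² and c².  Degenerate designs (kinship proportional to
the identity, all-singleton households) are detected and flagged rather
than silently fitted.  Non-PSD covariance inputs raise; non-convergence
is flagged.

## Association (score test)

The GWAS null model is the two-component polygenic fit (household
excluded by default, matching two-stage mmscore practice; an
`include_household` path exists).  The fitted covariance is whitened
once (V̂⁻¹ = WᵀW); each variant's statistic is

    U = g̃ᵀV̂⁻¹r,   χ²₁ = U²/(g̃ᵀV̂⁻¹g̃),   β̂ = U/(g̃ᵀV̂⁻¹g̃),

where r are the GLS residuals and g̃ is the coded genotype projected on
the orthogonal complement of the covariates in the V̂⁻¹ inner product.
The full projection (not just centering) is what makes the test reduce
exactly to the classical OLS Rao score test when kinship is the
identity, and keeps conditional tests exact when a conditioning genotype
joins the fixed effects.  Missing dosages are mean-imputed with the
observed-call count reported.  Monomorphic codings return a non-testable
result with a reason, never an exception.

Mode-of-inheritance scanning codes hard calls (dosages rounded; calls
more than 0.1 from an integer set missing) as additive {0,1,2}, dominant
{0,1,1}, recessive {0,0,1} and over-dominant {0,1,0}; the best model is
the smallest p.  Explained variance is 100·β̂²·Var(g)/Var(y residualized
on covariates).  The metabolome-wide threshold is the genome-wide level
divided by the number of unique metabolites; 5×10⁻⁸/42 = 1.19×10⁻⁹,
conventionally printed as 1.2×10⁻⁹ (the division is authoritative over
any rounded rendering).  Genomic inflation is the median χ²-equivalent
over 0.4549.  Analytic power uses the 1-df noncentral chi-square with
NCP = n·2p(1−p)β² (β in trait-SD units per allele; the cohort n is an
explicit argument because the measured and analyzed cohort sizes
differ).  Two-sided tests throughout; λ is reported, never applied as a
correction.

**Calibration behavior worth knowing.** Each variant's test is exactly
calibrated (type-I error at the nominal level; verified to 10⁻¹³ against
the OLS oracle at K = I).  But a λ estimated from one trait scanned at
many null variants is itself a random quantity with SD ≈ 0.05 at
n ≈ 2,000 under deep relatedness, because all statistics share the one
realized residual vector and whitened genotypes are anisotropic.  Across
seeds the mean λ is 0.99; a single run can land a few thousandths outside
a ±0.05 band without indicating miscalibration.

## Fine-mapping

Sequence variants with fewer than 5 non-missing carriers are removed
(exactly 5 is retained).  LD is the squared Pearson correlation of
dosages over complete pairs (composite LD; phase is unavailable for
dosages).  For each (variant, lead) pair the marginal test and both
mutually adjusted tests are computed by adding the conditioning genotype
to the null-model fixed effects — the variance components are not
re-estimated, keeping the score test exact under the original null.
Classification (defaults alpha_keep = 10⁻³, alpha_drop = 0.05, both
configurable and logged):

- `explains_lead`: variant survives adjustment, lead collapses;
- `independent`: both survive;
- `tagged_by_lead`: variant adds nothing over the lead;
- `indistinguishable`: r² > 0.999 (adjusted p-values suppressed);
- anything between the two alphas is reported `indeterminate` verbatim.

For the architecture-recovery study, loci are simulated as causal+tag
(tag r² = 0.9, lead = tag) or two independent causal variants (lead =
first).  The causal effect in the causal+tag arm defaults to 0.7 SD per
allele: the conditional noncentrality is n(1−r²)·2p(1−p)β², and at
n ≈ 2,000, r² = 0.9, MAF 0.2 an effect of 0.5 SD leaves only ~83 % power
at the 10⁻³ keep-threshold, while 0.7 SD gives > 99 % — the larger
default makes the study a test of the classifier rather than of marginal
power.  Two-causal loci use 0.5 SD (conditioning costs no power there).

## Problem sizes and numerical choices

Verification studies run at: 10 pedigrees of ~2,000 descendants for
heritability recovery (REML ~ 10 s per trait with the household
component); 10,000 null variants for calibration; 100 loci for
fine-mapping; 100 replicates for the mode-of-inheritance scan; 40
samples × 6 metabolites at SNR 50 for end-to-end quantification — sizes
chosen to match the emulated study's scale while remaining single-CPU
friendly.  Simplex tolerances: xatol 10⁻⁹, fatol 10⁻¹², iteration cap
200·dim per restart.  REML optimizer tolerance 10⁻⁵ in the transformed
parameters; kinship eigenvalues clipped at 0; a 10⁻¹⁰ jitter stabilizes
the Cholesky of 2Φ in the simulator.  Ties in the best-model scan cannot
occur except for exactly equal p-values (then the first-listed model
wins).  Seeds: every generator takes an explicit seed and fixed seeds
give byte-identical outputs.

## Known limitations

- The CPMG linear model assumes the JRES-fitted peak centers are valid
  for the CPMG spectrum up to a single width rescaling; per-peak shift
  or width refinement is not implemented.
- Households are sibships by construction; residence-based household
  structures would need a user-supplied H.
- The REML SE is a curvature estimate; near variance boundaries it is
  reported as NaN rather than truncated.
- X-chromosome models, dominance variance, imputation, and annotation
  pipelines are out of scope.
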