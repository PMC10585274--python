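# Methods

## The estimand and the data

Two-sample MR estimates the causal effect of an exposure X on an outcome Y
from two independent GWAS. For instrument j, the exposure GWAS reports
(β̂ⱼˣ, seⱼˣ) and the outcome GWAS (β̂ⱼʸ, seⱼʸ); under the instrumental-variable
assumptions each Wald ratio β̂ⱼʸ/β̂ⱼˣ estimates the same causal effect. The
two-step extension runs this twice along a chain X → M → Y and multiplies
the step estimates.

All inputs are tab-separated summary-statistics tables with columns
`snp_id, chrom, pos, effect_allele, other_allele, eaf, beta, se, pval, n`.
Effects on binary traits are log odds ratios; coordinates are 1-based;
the strand is assumed forward.

## Instrument selection

1. **Association gate.** Keep variants with p < `p_threshold`
   (default 5×10⁻⁵, the threshold used by the study whose result tables are
   bundled; a permissive choice that trades some instrument strength for
   instrument count).
2. **LD clumping.** Greedy, p-value ordered: repeatedly take the remaining
   variant with the smallest p as an index SNP and remove every remaining
   variant on the same chromosome within `clump_window_bp` (default 10 Mb)
   with pairwise r² ≥ `clump_r2` (default 0.001). Ties on p are broken by
   (chrom, pos, snp_id), making the result deterministic and independent of
   row order. On instances small enough to enumerate, this equals the
   unique subset that is pairwise independent and p-value dominant, which
   is how the test suite verifies it. LD is consumed as a pairwise r²
   lookup (TSV of `snp_a, snp_b, r2`); absent pairs count as r² = 0.
3. **Strength filter.** Per-SNP variance explained is available in two
   modes: the textbook shorthand 2·EAF·(1−EAF)·(β/se)² ("printed" mode,
   which approximates N·r² and can exceed 1) and z²/(N+z²) ("normalized"
   mode, bounded by 1), the pipeline default. The set-level F statistic is
   (R²/K)/((1−R²)/(N−K−1)) with K instruments and N the smallest per-SNP
   sample size. F < 10 conventionally flags weak-instrument bias; because F
   is a set-level quantity while exclusion is described per-IV in the
   literature, the filter iteratively drops the smallest-R² SNP and
   recomputes until F ≥ `f_min` (default 10) or one SNP remains, logging
   each drop.

## Harmonization

For each SNP shared between exposure and outcome tables the outcome effect
is rewritten to the exposure's effect allele: direct match kept; swapped
roles negate β and complement EAF; single-base strand complements (A↔T,
C↔G) are resolved first; irreconcilable allele pairs are dropped and
counted. Palindromic pairs (A/T, G/C) cannot be strand-resolved from
alleles alone: they are dropped when either study's EAF is within
`palindromic_eaf_window` (default 0.08) of 0.5, otherwise oriented by EAF
agreement (same side of 0.5 ⇒ same coding). The 0.08 window follows the
dominant two-sample-MR convention; the source study is silent on its
palindromic handling, so the window is configurable and logged. Output
vectors are ordered by `snp_id`, which (together with exact negation being
a bit-exact float operation) makes every downstream estimate bit-identical
under any allele-coding permutation of the inputs — a property the
acceptance suite checks over 50 seeded recodings.

## Estimators

With ratios β̂ⱼ = β̂ⱼʸ/β̂ⱼˣ and first-order SEs seⱼ = seⱼʸ/|β̂ⱼˣ|
(the exposure-side noise term is deliberately omitted, as is standard):

* **IVW.** β̂ = Σwⱼβ̂ⱼ/Σwⱼ with wⱼ = 1/seⱼ²; fixed-effects SE = (Σwⱼ)^−½;
  Cochran's Q = Σwⱼ(β̂ⱼ−β̂)² on J−1 df. The default multiplicative
  random-effects model inflates the SE by √(Q/df) with a floor at 1 — the
  estimate can never be reported as more precise than fixed effects, and
  under-dispersion is not rewarded.
* **MR-Egger.** WLS of β̂ʸ on β̂ˣ with a free intercept, weights 1/(seʸ)²,
  after orienting all exposure effects non-negative (flipping the paired
  outcome effects) — the orientation Egger's identifying convention
  requires. The slope is the causal estimate, the intercept the mean
  directional pleiotropy. SEs use the unscaled WLS covariance inflated by
  max(1, √(Q_res/(J−2))). Requires J ≥ 3 and variance in the exposure
  effects.
* **Weighted median.** Ratios sorted ascending; with normalized
  inverse-variance weights, the estimate is the ratio at centred cumulative
  weight 0.5, linearly interpolated between bracketing SNPs. The SE is a
  seeded parametric bootstrap: each ratio resampled from N(β̂ⱼ, seⱼ²),
  the weighted median recomputed, SD taken over `n_boot` (default 1000)
  replicates. Bootstrap rather than jackknife because it respects the
  per-SNP precision structure; seeding makes it reproducible.
* **Leave-one-out.** J random-effects IVW fits each omitting one SNP, in
  `snp_id` order; an entry is flagged influential when its omission flips
  the sign of the estimate or moves p across 0.05.

Confidence intervals are β̂ ± 1.96·se and p-values two-sided normal
throughout (not t): this convention exactly reproduces the CI bounds and
p-values of the published tables the package bundles, so it is adopted as
the implied convention of that analysis.

## Two-step mediation

From three arms — total effect β₀ (exposure→outcome), step one β₁
(exposure→mediator), step two β₂ (mediator→outcome) — the indirect effect
is β₁β₂ with delta-method SE √(β₁²se₂² + β₂²se₁²); the covariance term is
zero because the two steps come from non-overlapping samples. On a binary
outcome exp(β₁β₂) is the indirect odds ratio. The classifier returns
`partial_mediation` when p₀, p₁, p₂ < α; `indirect_only` when p₀ ≥ α and
p₁, p₂ and the indirect p are all < α; `no_mediation` otherwise
(α = 0.05, configurable, no multiplicity correction — matching the source
analysis). Applying the delta-method z-test to the bundled reference
estimates reproduces the published indirect p-values to three decimals,
which is the evidence that this was the method implied by that analysis.

In the pipeline, the total-effect arm excludes any exposure instrument
that itself passes the instrument threshold for the mediator, so the
total-effect instruments are independent of the mediator; the exclusion is
applied only to that arm, matching the design it emulates.

## The synthetic-data generator

Per SNP j: γⱼ ~ N(0, σ_γ²) is the true exposure effect; the mediator gets
β_xm·γⱼ + αⱼᴹ and the outcome
(β_direct + β_my·β_xm)·γⱼ + β_my·αⱼᴹ + αⱼʸ, where the pleiotropy terms
αⱼ are N(μ_p, σ_p²) for a `prop_invalid` fraction of SNPs and 0 otherwise.
Pleiotropy is drawn **in the exposure-increasing orientation** (it enters
as sign(γⱼ)·αⱼ): directional pleiotropy means a push on the outcome that is
consistent relative to the exposure-raising allele, which is the convention
under which the Egger intercept estimates μ_p·prop_invalid; drawn in a
random allele frame it would average to zero by construction and be
undetectable by design. Observed effects add N(0, seⱼ²) noise with
seⱼ = (2·EAFⱼ·(1−EAFⱼ)·N)^−½ per trait; EAFs are uniform on `eaf_range`;
p-values are two-sided normal (floored at 10⁻³⁰⁰ to stay in (0,1]). LD is
block-diagonal with within-block r² = ρ^|i−k|; blocks sit 20 Mb apart so
only within-block structure is ever inside a clumping window. Alleles are
random nucleotide pairs with a `prop_palindromic` fraction forced
palindromic, and each trait table independently relabels effect/other
alleles (negating β, complementing EAF), so harmonization is load-bearing
in every end-to-end test.

Defaults (chosen once, as the emulated study conditions): J = 200 causal
SNPs, σ_γ = 0.05 (≈ 0.5 SNP-heritability for the exposure at J = 200 —
biobank-trait scale), N = 100,000 for the continuous exposure and mediator,
N = 20,000 for the outcome (the effective size 4p(1−p)N of a case-control
GWAS is far below its nominal count), β_xm = 0.3, β_my = 0.2, no direct
path, no pleiotropy, EAF ∈ (0.05, 0.95), 20% palindromic variants.

What the generator does **not** emulate: individual-level genotypes,
case-control liability-scale effects, genome-wide realistic LD, sample
overlap between cohorts, population stratification, or EAF estimation
error. Passing recovery tests therefore demonstrates correctness of the
estimators under the stated model, not robustness to those real-data
complications.

## Numerical and edge-case choices

* p-values floored at 10⁻³⁰⁰; a zero SE yields p = 1 for a zero estimate.
* Single-SNP IVW reduces exactly to the Wald ratio; Q requires J ≥ 2,
  Egger/weighted-median/leave-one-out require J ≥ 3, and violations raise
  typed data errors rather than returning degenerate numbers.
* Clumping tie-breaks and `snp_id`-ordered harmonized vectors make every
  pipeline output deterministic under a fixed seed; report files from
  repeated runs are byte-identical.
* Invalid input rows (se ≤ 0, EAF outside (0,1), identical alleles,
  p ∉ (0,1]) are dropped at read time with a logged count, not silently
  repaired.
* Reference-table SEs are recovered from the printed p-values
  (se = |β|/z_p) for significance work, and from the printed CI widths
  (width/3.92) for CI reproduction; the p-route preserves more significant
  figures than the two-figure printed CI bounds.

## Problem sizes used in checks

The test suite's calibration experiments use J = 100 SNPs with cohorts of
50,000 (1,000 replicates without pleiotropy; 200 with 30% directional
pleiotropy, μ_p = 0.01, σ_p = 0.005) and, for delta-method CI coverage,
biobank-scale cohorts of 500,000 (300 replicates) where instrument strength
makes the first-order approximations accurate. The acceptance script uses
400/150/200 replicates for the same three experiments. These sizes were
chosen so each experiment's Monte-Carlo error is small relative to the
quantity it measures.

## Known limitations

* At N = 50,000 with σ_γ = 0.05, instrument noise leaves a measurable
  weak-instrument attenuation in IVW (about −2% relative, ≈ −0.006 on a
  true effect of 0.3; replacing the noisy exposure betas by their true
  values removes it entirely and yields exactly 95.0% CI coverage). This is
  the well-known finite-sample behaviour of ratio-based MR, not an
  implementation artifact; it halves when cohorts double.
* Winner's curse: selecting instruments and estimating their effects in
  the same GWAS inflates the selected exposure betas, further attenuating
  downstream ratios — visible in the mediator→outcome step at modest
  sample sizes.
* No MR-PRESSO, mode-based estimation, multivariable MR, Steiger
  filtering, proxy-SNP lookup, or proportion-mediated estimation; single
  mediator per triple; no covariance correction for overlapping samples.
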