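# Methods

## Design

`mrscreen` implements the standard two-sample Mendelian randomization (MR)
screen: genetic variants serve as instrumental variables for an exposure
(here, the relative abundance of a microbial taxon), and their effects in
an independent outcome GWAS identify the causal effect of the exposure on
the outcome, provided the instruments (i) are associated with the exposure,
(ii) are independent of confounders, and (iii) affect the outcome only
through the exposure (the exclusion restriction). The pipeline consumes
summary statistics only; no individual-level data are touched.

Stages per exposure: p-value filtering → greedy LD clumping →
harmonization → weak-instrument filtering → estimation → sensitivity
analysis → verdict. Each stage is an importable function with its own
contract, and the batch driver composes them.

## Instrument selection

Instruments are SNPs with exposure p < 1 × 10⁻⁵ (strict inequality). The
suggestive threshold, rather than genome-wide 5 × 10⁻⁸, is the common
choice for molecular and microbiome exposures where few signals reach
genome-wide significance; it trades some instrument strength for coverage,
which is why the per-SNP F filter exists downstream.

Clumping is greedy: candidates are ranked by ascending p (ties broken by
chromosome string, position, then SNP id, making the output invariant to
input row order); the best remaining SNP becomes an index SNP and removes
every remaining same-chromosome SNP within 10,000 kb (inclusive) whose r²
with it exceeds 0.001. LD comes from an explicit r² matrix supplied by the
caller — square, long (pairwise), or a bare SNP list declaring an
independent panel — rather than from a reference genotype panel, which
keeps the computation deterministic and offline. Instruments absent from
the LD matrix are dropped with a warning rather than assumed independent.

## Harmonization

Outcome effects are aligned to the exposure's effect allele: identical
pairs pass through, swapped pairs negate βY, anything else (including
strand complements, e.g. A/G vs T/C) is dropped as a mismatch. Palindromic
SNPs (A/T, C/G) are removed unconditionally — no allele-frequency rescue —
because their strand cannot be resolved from the alleles alone. Instruments
missing from the outcome GWAS are dropped, not proxied. These are the
conservative choices; both drop classes are logged per SNP and serialized
in the JSON report, so the cost in instruments is always visible.

## Estimators

With Wald ratios θⱼ = βYⱼ/βXⱼ and inverse-variance weights
wⱼ = βXⱼ²/σYⱼ²:

- **IVW** is the wⱼ-weighted mean of θⱼ, identical to zero-intercept
  weighted least squares of βY on βX with weights 1/σY². The fixed-effect
  SE is (Σwⱼ)^(−1/2); the *reported* SE multiplies it by
  max(1, √(Q/(k−1))) — the multiplicative random-effects model with a
  variance floor, the default of the mainstream MR tooling. The floor
  means heterogeneity can only widen the interval; under homogeneity the
  reported test is therefore mildly conservative (analytically, true level
  ≈ 0.039 at k = 10 for nominal 0.05) while the fixed-effect test is
  exactly nominal. Both are exposed (`ivw`, `ivw_fixed_effect`); the
  calibration tests check the fixed-effect level against the nominal band
  and the random-effects variant for conservativeness, never
  anti-conservativeness.
- **MR-Egger** fits the same weighted regression with a free intercept
  after orienting every instrument to βX ≥ 0 (Egger is not
  orientation-invariant; the convention makes it deterministic). The
  intercept estimates the mean direct effect under InSIDE; inference uses
  t with k − 2 df and the weighted residual variance floored at 1. The
  floor makes the intercept test conservative at small k — deliberate, as
  a k = 3 pleiotropy test has no power worth spending type-I error on.
- **Weighted median** sorts θⱼ, forms cumulative-weight midpoints
  sⱼ = Σᵢ≤ⱼwᵢ − wⱼ/2 (weights normalized), and linearly interpolates θ at
  s = 0.5, clamping to the extreme ratios outside [s₁, s_k]. The
  interpolated estimate lies within one inter-ratio interval of the exact
  weighted-absolute-deviation minimiser (the discrete weighted median);
  the oracle test asserts exactly that bound. Its SE is a parametric
  bootstrap (default 1,000 replicates) resampling both βX and βY from
  normal(β, σ); the seed is a mandatory argument so results are
  reproducible by construction.
- Instruments with βX = 0 are an error for the Wald ratio and IVW and are
  dropped with a warning by the weighted median.

ORs are exp(β) with 95% CI exp(β ± 1.96·SE) throughout.

## Sensitivity suite

Cochran's Q = Σwⱼ(θⱼ − β̂_fixed)² on χ²(k−1) tests heterogeneity; the
Egger intercept tests directional pleiotropy; leave-one-out recomputes IVW
k times, flagging a SNP as influential when its removal flips the sign of
β̂ or moves the p-value across α. Per-SNP strength uses
R² = 2·MAF·(1−MAF)·β² and F = R²/(1−R²)·(n−k−1)/k. F is computed with
k = 1 per SNP — the single-instrument convention consistent with published
per-SNP F values — and that value drives the F > 10 filter; the
joint-count variant is carried alongside for reference. A missing allele
frequency leaves F undefined; the default policy keeps such instruments
with a warning (strict mode drops them).

## Verdicts and headline rules

A taxon is **associated** when IVW p < α and both sensitivity tests are
clean (Q p > α and intercept p > α), **unreliable** when either
sensitivity test fires (or when k < 3 leaves the suite unrunnable),
**not associated** otherwise, **no_instruments** when nothing survives
QC; associated taxa are labelled protective (OR < 1) or risk (OR > 1).
α = 0.05 with no multiple-testing correction across taxa — the screening
convention this pipeline mirrors — but a Benjamini–Hochberg column over
the IVW p-values is emitted for information and never used in verdicts.

The ">50% heterogeneous SNPs → report the weighted median; >50%
pleiotropic → report MR-Egger" headline rules require a per-SNP
classification that screening practice leaves unspecified; here a SNP is
heterogeneous when its Q contribution wⱼ(θⱼ − β̂)² exceeds the χ²(1)
upper-α quantile, and pleiotropic when its studentized Egger residual
exceeds the two-sided normal α quantile. The headline switch is annotation
only; IVW is always reported.

## Synthetic-data generator

The generator emulates the *summary-statistic façade* of a
many-exposure/one-outcome screen. Per instrument: MAF ~ U(0.05, 0.5);
SE = 1/√(2·MAF·(1−MAF)·n) (standardized-trait approximation, which makes
the F/R² statistics internally consistent with the declared n); true βX is
|N(0, 0.1)| resampled above a z = 6 detection margin so the p < 10⁻⁵
filter keeps true instruments with probability ≈ 1; the reported effect
allele is the exposure-increasing one, which keeps "directional pleiotropy
with mean m" well defined under Egger's βX ≥ 0 convention. Outcome effects
are θ·βX_true plus a direct effect (zero, balanced, or directional
normal) plus optional extra-variance heterogeneity, observed with sampling
noise at their SEs. Each exposure carries 50 decoy null SNPs per true
instrument so selection does nontrivial work; default sample sizes
(n_exp = 18,340; n_out = 77,257) mirror the scale of a microbiota
consortium GWAS and a biobank case-control GWAS. Two-sided p-values that
underflow to zero at extreme z are clamped to the smallest positive float
so the p ∈ (0, 1] invariant holds.

What the generator does **not** model: real LD (blocks are synthetic and
supplied separately), winner's-curse selection from an external discovery
scan, case-control asymmetry beyond the normal approximation, sample
overlap between the two GWAS, population stratification, and any actual
microbiome biology. Passing tests therefore demonstrate the statistical
machinery is correct under its stated model — not that any particular
real-data finding is right.

## Numerical choices and degenerate inputs

Clump ties broken deterministically (p, chromosome, position, id);
different chromosomes never clump. Egger requires variance in |βX|
(otherwise the slope is unidentified) and k ≥ 3; IVW and the weighted
median require k ≥ 2 (k = 1 is directed to the Wald ratio); leave-one-out
requires k ≥ 3 so every subset still supports IVW. R² ≥ 1 is treated as
malformed input. File round-trips are exact: floats are written in
shortest round-trip representation and parsed with exact conversion
(pandas' default float parser is not round-trip-safe and is bypassed).
Duplicate SNP ids within one GWAS keep the first occurrence, logged.

## Study sizes

The calibration battery runs the full pipeline on 1,000 null taxa
(k = 10 true instruments, 500 decoys each) and 500-replicate recovery
studies at n = 200,000 per GWAS — sizes at which Monte-Carlo error is
small relative to the tested tolerances while the whole suite stays a
few minutes on one CPU. The demonstration screen uses 20 taxa with
planted truth at the same sample sizes.

## Known limitations

- No proxy-SNP lookup, no allele-frequency rescue of palindromes, no
  strand complementing: instrument counts can run lower than pipelines
  that rescue ambiguous variants.
- No MR-PRESSO/mode-based/multivariable estimators, no Steiger filtering,
  no reverse-direction MR.
- The random-effects IVW p-value is conservative under exact homogeneity
  (by the variance floor); users needing exact nominal behaviour under
  the fixed-effect model should read `ivw_fixed_effect`.
- LD must be supplied; the package never computes r² from genotypes.
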