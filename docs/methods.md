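# Methods

## Design

`medimr` analyses three GWAS summary-statistic sets — a quantitative
exposure, a quantitative mediator and a binary outcome — in two phases.
Phase 1 is a bidirectional screen of the exposure→outcome relationship: the
forward leg must show a causal effect (p < α) and the reverse leg
(outcome instrumented at its own, stricter threshold) must not. Phase 2
estimates the exposure→mediator (*a*) and mediator→outcome (*b*) legs and
combines them with the total effect (*c*) into a product-of-coefficients
mediation path. All estimation is two-sample: only per-SNP association
summaries (beta, SE, p, allele pair, allele frequency, sample size) are
used, never individual-level data.

Assumptions inherited from the MR framework: instruments are associated
with their exposure (enforced by the p-threshold and F > 10 screens),
independent of confounders (supported by LD clumping and an optional
user-supplied confounder-SNP blacklist), and affect the outcome only
through the exposure (checked, not guaranteed, by the Egger intercept and
MR-PRESSO). The mediation algebra additionally assumes effect homogeneity
and no exposure–mediator interaction, and is computed throughout on the
log / log-odds scale; odds ratios are presentation-layer transforms.

## Estimators

* **IVW**: weighted regression of outcome on exposure betas through the
  origin, weights 1/σᵧ². Default is the multiplicative random-effects
  variant (fixed-effect SE × max(1, √(Q/(J−1)))); `ivw_model="fixed"`
  switches to fixed-effect. Point estimates are identical; the MRE SE is
  never smaller. A single instrument degrades to the Wald ratio
  (first-order SE σᵧ/|βₓ|; a second-order option adds βᵧ²σₓ²/βₓ⁴).
* **MR-Egger**: the same regression with a free intercept after orienting
  all exposure effects non-negative. SEs come from the weighted fit with
  residual inflation max(1, √(RSS_w/(J−2))); the intercept's two-sided
  p ≥ 0.05 is read as no evidence of directional pleiotropy. Normal
  p-values by default, Student-t on J−2 df via flag.
* **Weighted median**: per-SNP ratios ordered by value, cumulative
  standardized weights sⱼ = (Σᵢ≤ⱼ wᵢ − wⱼ/2)/Σw with first-order ratio
  weights, linear interpolation at s = 0.5. SE by seeded parametric
  bootstrap (default 1,000 draws) from the summary sampling distributions.

## Diagnostics

Cochran's Q uses the fixed-effect fit; homogeneity is declared at
p ≥ 0.05 on the χ²(J−1) upper tail. Leave-one-out refits IVW J times;
"robust" means no single omission changes the estimate's sign or its
α = 0.05 verdict. MR-PRESSO computes each SNP's weighted squared residual
against the IVW fit excluding that SNP, simulates the no-pleiotropy null
parametrically (redrawing both betas around the leave-one-out fit,
n_sim = 5,000 by default, seeded), and reports a global upper-tail p, 
Bonferroni-adjusted per-SNP outlier p-values, and — when outliers are
removed — a distortion p locating the cleaned estimate within estimates
from 1,000 random same-size subsets. Monte-Carlo p-values use the
(r+1)/(n+1) convention so they are never zero. A leg "fails QC" (flagged,
not errored) when Q, the Egger intercept or the distortion test rejects
at α = 0.05.

## Instrument selection and harmonization

Selection: strict p < threshold (defaults 5×10⁻⁵ for molecular traits,
5×10⁻⁶ for the outcome-as-exposure leg), optional blacklist, then greedy
clumping — scan by ascending p (ties by position, then id), keep a SNP iff
r² < 0.001 with every kept SNP within 10,000 kb on the same chromosome.
Per-SNP variance explained is R² = 2p(1−p)β² (unit trait variance); a
β²/(β²+Nσ²) variant serves records without allele frequencies. The
strength filter applies F = (ΣR²/(1−ΣR²))·((N−K−1)/K) > 10 to the clumped
set (the formula's K-instrument form); a per-SNP screen is available via
`f_mode="snp"`, and single-instrument sets face the per-SNP form either
way.

Harmonization aligns the outcome record to the exposure's effect allele:
identical pairs pass, swapped pairs get a sign flip and frequency
complement, complementary-strand pairs are re-lettered first. For
palindromic SNPs (A/T, C/G) the allele letters cannot distinguish a strand
flip from a swap, so the allele frequency is the sole arbiter: both
frequencies must lie outside the ambiguity window (default [0.42, 0.58],
configurable) or the SNP is dropped; missing frequency on either side also
drops it. All drops are logged with machine-readable reasons, and counts
are conserved: intersection = kept + logged drops.

## The simulator

`simulate_mediation_gwas` emulates the three-cohort study design at the
summary level — the standard device in MR methods work, sufficient to
exercise every estimator without genotype simulation. Latent per-SNP truth
follows the causal triangle (see the module docstring); observed betas add
Gaussian noise with SE = 1/√(2p(1−p)n) (quantitative) or
1/√(2p(1−p)·n_case·n_control/n_total) (binary log-odds, the effective-
sample-size approximation). Cohort-size defaults (7,174 / 8,299 /
11,262+25,483) mirror the motivating lipidome–metabolome–longevity
setting.

Design choices worth knowing:

* **Mediator-specific instruments.** A mediator observed only through
  exposure-driven SNPs has no valid instruments of its own — SNPs shared
  with the exposure estimate *b* as θ_MO + θ_EO-direct/θ_EM, not θ_MO. The
  generator therefore plants mediator-specific effects (δ ~ N(0.12, 0.02))
  on a fraction of the exposure-null SNPs, as a real metabolite GWAS would
  provide. Exposure-valid SNPs keep the stated identities exactly.
* **Effect scales.** γ ~ N(0.12, 0.02) puts exposure instruments well past
  5×10⁻⁵ at n ≈ 7,000 while keeping their outcome associations below
  5×10⁻⁶, so the forward and reverse instrument sets separate the way the
  two thresholds intend. Under forward-only causation the outcome then
  usually has no instruments at all; the reverse leg is reported "not
  estimable" and treated as showing no reverse effect (with that reason
  recorded), rather than failing the pathway.
* **LD.** SNPs in a block share their latent effect and receive
  compound-symmetric noise (ρ = 0.8 within blocks of 3 by default), making
  clumping consequential; blocks are placed > 20 Mb apart so the clumping
  window binds only within a block. The LD reference returned to the
  pipeline is the generating correlation itself.
* **Representation scrambling.** A configurable fraction of mediator and
  outcome rows is stored allele-swapped (beta negated, frequency
  complemented) or strand-complemented — value-preserving re-encodings that
  force harmonization to do real work. Because the scrambling draws are
  consumed regardless of the fractions, the same seed with scrambling off
  yields the identical latent data, which the tests exploit to verify
  harmonization recovers every flip exactly.

The default scenario (`strong_mediation`) plants a = 0.2, b = 0.25,
c′ = 0.15, i.e. a mediated proportion of 0.25. What the simulator does
*not* emulate: genome-wide LD structure, allele-frequency estimation error
(frequencies are exact, so palindromic resolution in tests is cleaner than
in real data), winner's-curse-inducing discovery overlap, population
stratification, and uneven per-SNP sample sizes. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
generative model, not robustness to every pathology of real GWAS inputs.
Exposure betas also enter the IVW regressor with sampling noise
(≈ 15% of the effect scale at the default n), which mildly inflates
Cochran's Q on strongly powered legs — visible as occasional QC flags on
perfectly valid synthetic pathways, and the reason the MRE variant is the
default.

## Numerical conventions

Thresholds are strict as printed (p < 5×10⁻⁵, r² < 0.001, F > 10).
Clumping ties break deterministically (p, then position, then id).
Two-sided p-values are normal-based unless the t option is chosen; they
are floored at the smallest positive float rather than reported as 0.
Delta-method variance is first-order (Sobel) by default; `second_order=True`
adds σ_a²σ_b². The mediated proportion is reported as a bare percentage
without a CI; sign disagreement between a·b and c, or |proportion| > 1, is
flagged as inconsistent mediation instead of being masked. No
multiple-testing correction is applied across screened pathways — matching
the single-pathway reporting convention the pipeline mirrors — and this is
a deliberate, documented caveat for users screening many exposures.
Reported sizes in the statistical tests (e.g. 1,000 null replicates for
IVW calibration, 500 for PRESSO calibration, 200 pipeline seeds for
mediation recovery) were chosen as the package's own desk-scale defaults
giving Monte-Carlo error comfortably inside the asserted bands.

## Known limitations

No proxy-SNP lookup, Steiger filtering, multivariable MR or radial
variants; the LD reference is block-diagonal; the reverse screen can be
defeated by strong forward effects leaking instruments past the outcome
threshold (tail SNPs occasionally do, and then legitimately fail the
screen); and the delta-method CI undercovers when both legs are near zero.
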