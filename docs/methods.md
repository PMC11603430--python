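# Methods

## Scope and design

The package implements the summary-statistics workflow of a two-sample MR
study with two-step mediation: instrument selection, allele harmonization,
point estimation (Wald ratio, IVW fixed-effect and
multiplicative-random-effects, MR-Egger), sensitivity analyses (Cochran's
Q, leave-one-out, MR-PRESSO), and the product-of-coefficients mediation
decomposition. Weighted-median/mode estimators, multivariable MR and
directionality (Steiger) filtering are deliberately out of scope; the
univariable two-step design estimates β₂ without adjusting for the
exposure, which is unbiased when the mediator's instruments do not act on
the outcome through the exposure (true in the simulator by construction,
an assumption on real data).

## Estimators and numerical choices

* **IVW** is computed in ratio form (per-variant Wald ratios pooled with
  inverse-variance weights), which is algebraically identical to weighted
  regression through the origin with weights se_out⁻²; the test suite
  asserts that identity against an independent weighted least-squares fit.
  Variants with β̂ₓ = 0 are excluded with a warning (the ratio is
  undefined); an all-zero set is an error. The default reported model is
  multiplicative random effects — SE inflated by max(1, √(Q/(k−1))) — so
  the reported interval is never narrower than the fixed-effect one.
* **Confidence intervals** use the conventional 1.96 normal multiplier;
  the Egger slope and intercept use t(k−2) quantiles and p-values, with
  SEs carrying the multiplicative overdispersion factor
  √(max(1, RSS_w/(k−2))). Before the Egger fit every variant is oriented
  so β̂ₓⱼ > 0; the fit is invariant to joint sign flips.
* **Wald ratio SE** defaults to the first-order delta approximation
  se_out/|β̂ₓ|; a second-order option adds the exposure-side term. Because
  a ratio of normals has no finite moments, the Monte-Carlo check of the
  delta SE in the tests compares against the central-68%-interval
  half-width of the simulated ratio rather than its tail-dominated SD.
* **Mediation SEs**: the indirect-effect SE √(β₁²se₂² + β₂²se₁²) is the
  first-order delta method with zero covariances (the three estimates come
  from non-overlapping two-sample fits). It omits the se₁²se₂² cross term
  of the exact product variance (≈3% at the magnitudes typical here). The
  proportion's SE compounds the indirect and total relative variances,
  treating the two as independent although they share the outcome GWAS —
  an approximation, so a parametric-bootstrap percentile CI (10⁴ redraws
  of the three coefficients) is available via `bootstrap=True`.
  Proportions are reported as percentages at one decimal. |proportion| > 1
  is permitted but flagged (`inconsistent`): it arises when direct and
  indirect paths oppose or the total effect is near zero.
* **p-value conventions**: two-sided normal everywhere except the Egger
  t-tests; p = 0 in input files is clamped to the smallest positive double
  rather than dropped, since genome-wide hits in real exports underflow.
* **Rounding** of OR/CI strings is half-even at three decimals.

## Instrument selection and harmonization

Screening uses a strict inequality (p < threshold). Clumping is the
standard greedy procedure: repeatedly keep the most significant remaining
variant and discard remaining variants on the same chromosome that are
both within the window (10,000 kb default) and at r² ≥ 0.001 with it;
p-ties break by (chromosome, position). Variants absent from the LD
reference are treated as independent, with a warning — appropriate for the
simulator's complete panels, optimistic for real data. No weak-instrument
filter is applied; per-variant F = (β̂/se)² is available as a diagnostic.

Harmonization resolves identical, swapped and strand-complemented allele
pairs exactly. Palindromic variants are resolved by effect-allele
frequency when both frequencies lie outside a ±0.08 band around 0.5
(dropped otherwise, or when either frequency is missing); the band is a
conservative conventional choice, configurable. Variants missing from the
outcome table are excluded — no proxy-variant search. An audit table
counts every shared variant by status and always conserves the
intersection size.

## MR-PRESSO implementation

The observed statistic is RSS = Σⱼ wⱼ(β̂ᵧⱼ − θ̂₍₋ⱼ₎β̂ₓⱼ)² with
wⱼ = se_outⱼ⁻² and θ̂₍₋ⱼ₎ the leave-one-out IVW slope. Its null
distribution comes from parametric resampling of both sides
(β̂ₓⱼ* ~ N(β̂ₓⱼ, seₓⱼ²), β̂ᵧⱼ* ~ N(θ̂₍₋ⱼ₎β̂ₓⱼ, se_outⱼ²)), with empirical
p-values floored by the (1 + exceedances)/(n_sim + 1) rule. Defaults:
n_sim = 5000, per-variant outlier α = 0.05 after Bonferroni over k, and a
distortion test comparing the outlier-corrected IVW shift against 1000
random same-size removals. All resampling is seeded; identical seeds give
bit-identical results. k ≥ 4 and n_sim ≥ 1000 are enforced.

## The simulator

`simulate_tri_trait` realizes the mediation diagram X → M → Y with direct
path τ: variant j carries γⱼ on X, b₁γⱼ + δⱼ on M and
(τ + b₁b₂)γⱼ + b₂δⱼ + α_pl,ⱼ on Y (log-odds scale for the binary
outcome). Two variant blocks are generated: exposure instruments
(γⱼ ~ N(0, γ_sd), m_snps of them) and mediator instruments (γ = 0,
δⱼ ~ N(0, δ_sd)). The mediator block exists because two-step mediation is
only identified when the mediator has genetic architecture of its own —
without it, "mediator instruments" all act through the exposure and step
2 estimates (τ + b₁b₂)/b₁ instead of b₂. Horizontal pleiotropy
(`pleio_mode` balanced/directional) perturbs the exposure block's δ and
every variant's α_pl; under `none` all pleiotropic effects are exactly 0.

Estimated effects are truth plus Gaussian noise with the large-sample SEs
for a standardized genotype, 1/√(n·2f(1−f)) for quantitative traits and
1/√(n·φ(1−φ)·2f(1−f)) for a binary outcome with case fraction φ. Under LD
(`ld_block_size` > 1) the noise is exchangeably correlated (r = ld_rho)
within consecutive blocks and the LD reference records exactly those
correlations; true marginal effects are *not* inflated by neighbours, so
truth stays analytically known and LD affects only noise correlation and
clumping. Effect-allele frequencies are identical across the three tables
(one super-population); positions are synthetic (variant j at
j·1000 kb on chromosome 1 by default) so the clump window is exercised.

Defaults are the study conditions the package targets: n = 300,000 for
the exposure GWAS, 18,340 for the mediator, 314,017 with case fraction
0.004 for the outcome; m_snps = 50, γ_sd = 0.02 (mean instrument
F ≈ 45–50, within the 30–60 range typical of well-instrumented complex
traits); m_snps_med = 30, δ_sd = 0.15 (mediator F ≈ 160 at the small
mediator sample size, so the relaxed p < 10⁻⁵ screen retains most and
winner's curse is negligible); b₁ = −0.89, b₂ = 0.577,
τ = −1.661465, giving a total effect of −2.175 and a true proportion
mediated of 0.2361 — the worked-example decomposition.

What the simulator does **not** emulate: realistic human LD panels,
allele-frequency differences between cohorts, strand errors (the
harmonization tests inject those separately), sample overlap between the
three GWAS, winner's-curse inflation of selected instrument effects at
the significance boundary, and logistic non-collapsibility (binary-trait
effects are generated directly on the log-odds scale because the pipeline
operates purely on summary coefficients). Passing recovery tests
therefore demonstrate correctness of the estimators under clean
two-sample assumptions, not robustness to those real-data pathologies.

## Problem sizes in the test suite

Replicate suites use fixed a-priori seed ranges: 300 replicates for IVW
coverage of the true total effect, 200 for mediation-proportion recovery,
200 for Egger intercept coverage, 100 seeds each for the MR-PRESSO size
and power checks (k = 30, n_sim = 2000), and 500 replicates for per-SNP
noise calibration. The analytic-limit check runs at n = 10¹⁰, where the
10⁻³ tolerance sits ≈30 SDs out. The whole suite completes in well under
two minutes on one CPU.

## Known limitations

* The distortion test's two-sided empirical p uses |shift| exceedances
  against random same-size removals; with a single outlier among few
  variants the subset space is small and the p-value coarse.
* Proportion-mediated SEs ignore the shared outcome GWAS between α and
  β₂; the bootstrap option mitigates but does not remove this.
* The palindrome frequency rule can mis-orient variants whose frequency
  straddles 0.5 between cohorts; the conservative band trades instruments
  for safety.
* Reverse-direction ("bidirectional") analyses are run by swapping trait
  roles in the manifest; there is no bespoke reverse mode.
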