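# Methods

This note records the statistical model behind `mrchain`, the numerical and
design choices that were genuinely open, and what the synthetic-data
validation does and does not establish.

## Estimators

All estimators operate on a harmonized instrument set: aligned per-SNP
effects (β̂ₓⱼ, seₓⱼ) on the exposure and (β̂ᵧⱼ, seᵧⱼ) on the outcome, with the
outcome effect re-signed to the exposure's effect allele.

**Wald ratio** (single SNP): β̂ = β̂ᵧ/β̂ₓ with se = seᵧ/|β̂ₓ|, the first-order
delta rule under the no-measurement-error (NOME) convention for the exposure
side.

**IVW with multiplicative random effects** (primary): weighted regression of
β̂ᵧ on β̂ₓ through the origin, weights wⱼ = 1/seᵧⱼ². Heterogeneity is absorbed
by inflating the fixed-effect SE by max(1, √(Q/(J−1))) where Q is Cochran's
Q; the floor at 1 means homogeneous sets keep the fixed-effect SE. Inference
is normal. A single instrument delegates to the Wald ratio.

**MR-Egger**: the same weighted regression with an unconstrained intercept,
after orienting every instrument so β̂ₓⱼ > 0 (the estimand is invariant to
joint sign flips). The intercept estimates average directional pleiotropy;
the slope is the causal estimate under InSIDE. SEs use the multiplicative
inflation max(1, √(RSS_w/(J−2))) and t inference on J−2 degrees of freedom —
conventions vary between t and normal here; the more conservative t was
chosen and the choice is recorded in the result's `extras`.

**Weighted median**: per-SNP ratios rⱼ with weights wⱼ = β̂ₓⱼ²/seᵧⱼ², sorted;
the standardized cumulative weight at rank j is pⱼ = (Sⱼ − wⱼ/2)/S_total and
the estimate linearly interpolates the inverse of p at ½. SE from a seeded
parametric bootstrap (β̂ₓ*, β̂ᵧ* resampled from their reported sampling
normals; default 1,000 draws).

**Simple / weighted mode**: the argmax of a Gaussian-kernel density over the
ratios, bandwidth h = φ·0.9·min(sd, IQR/1.349)·J^(−1/5) with φ = 1 by
default, evaluated on a 512-point grid spanning the ratios ± 3h; the
weighted variant weights each kernel by wⱼ. Degenerate case: identical
ratios (h = 0) return that ratio. SE by the same parametric bootstrap.

Method minima: Egger, median and modes require J ≥ 3; `run_all` skips them
with a logged reason below that, and MR-PRESSO requires J ≥ 4.

## Diagnostics

**Cochran's Q** uses ratio-scale weights β̂ₓⱼ²/seᵧⱼ² around the fixed-effect
IVW estimate, χ² with J−1 df.

**MR-PRESSO.** Observed statistic: RSS = Σⱼ wⱼ(β̂ᵧⱼ − β̂₍₋ⱼ₎·β̂ₓⱼ)² with
leave-one-out IVW slopes β̂₍₋ⱼ₎ and wⱼ = 1/seᵧⱼ². The null distribution is
simulated by drawing β̂ᵧ*ⱼ ~ N(β̂₍₋ⱼ₎·β̂ₓⱼ, seᵧⱼ) and β̂ₓ*ⱼ ~ N(β̂ₓⱼ, seₓⱼ) and
recomputing RSS* with leave-one-out slopes refitted on the starred data
(1,000 simulations by default, add-one Monte-Carlo p-values:
p = (1 + #{RSS* ≥ RSS})/(n_sim + 1)). Per-SNP outlier p-values compare each
observed residual to that SNP's simulated residual distribution, Bonferroni
adjusted by J. When outliers are flagged, the distortion test compares the
shift in the IVW estimate after their removal against the shift from removing
equally many randomly chosen SNPs. A known operating characteristic,
reproduced here: an outlier with an extremely small outcome SE acquires
extreme regression leverage, distorts the leave-one-out expected values that
define the simulated null, and can thereby mask itself; detection is reliable
when instruments have passed the strength screen and the outlier's SE is not
orders of magnitude below its peers'. Outlier-corrected estimates are
reported as an annex, not substituted downstream.

## Instrument quality control

* Selection is strict (`p < threshold`); layer defaults follow the emulated
  design — genome-wide 5×10⁻⁸ with lenient clumping r² < 0.1 for the
  cis-eQTL exposure layer, suggestive 5×10⁻⁶ with strict r² < 0.001 for the
  abundance mediator layer, both in a 10,000 kb window. A run using
  r² ≥ 0.1 is flagged in the drop log because the estimators assume
  independent instruments; no LD-aware (generalized) IVW is implemented.
* Clumping is greedy: keep the smallest-p remaining SNP, drop same-chromosome
  neighbours within the window (center-to-center, 1-based positions) at
  r² ≥ the threshold. SNPs absent from the LD matrix count as unlinked and
  are logged.
* Instrument strength uses the per-SNP approximation F = (β̂/se)²; SNPs with
  F < 10 are dropped (strict inequality — at exactly F = 10 the SNP is
  retained; the threshold is configurable).
* Harmonization resolves swapped alleles (sign and frequency flip) and strand
  complements; palindromic (A/T, G/C) SNPs are oriented by comparing allele
  frequencies to ½ in both studies and dropped as ambiguous when either
  frequency is missing or within ±0.08 of ½ (band configurable). Duplicate
  SNP ids keep the smallest p.
* Steiger filtering computes variance explained per SNP as r² = Z²/(Z²+n),
  Z = β̂/se, for both traits and drops SNPs with r²_outcome > r²_exposure.
  This form is monotone in |Z| and needs no trait-specific inputs; for binary
  outcomes it is an observed-scale approximation (no liability-scale
  correction), which the per-SNP report flags. The report's p-value is a
  Fisher-z two-correlation comparison.

## Mediation

Two-step decomposition from three MR estimates: indirect = β₁β₂, direct =
βall − β₁β₂, proportion = β₁β₂/βall. The indirect-effect variance is the
first-order propagation form β₁²se₂² + β₂²se₁², matching the two-step MR
convention; the exact second-order term se₁²se₂² is available behind a flag
(`second_order=True`). The direct-effect SE assumes independence of the total
and indirect estimates, which is conservative when instrument sets overlap.
The proportion's CI uses the delta method on the ratio; proportions outside
[0, 1] are reported as computed with an `inconsistent_mediation` flag, never
truncated. Triples enter mediation only when all three links are significant
at the screening alpha on the primary (IVW) p-value.

## Synthetic data

The generator emulates the statistical shape of its target data sources: a
quantitative
expression exposure (n ≈ 30,000) instrumented by ~5–30 cis SNPs, a
quantitative microbial-abundance mediator (n = 5,959) whose instruments clear
a suggestive threshold, and a binary disease outcome at biobank scale
(8,434 cases / 770,180 controls). Traits are standardized; per-SNP effects
are drawn normal and rescaled so the instruments jointly explain a configured
variance (defaults 3% for the exposure over 10 SNPs, 5% for the mediator over
15 — instrument strengths in the F ≈ 20–100 range typical of cis-QTL and
microbiome GWAS instruments).

The **analytic engine** computes each SNP's expected marginal effect
(exposure SNPs act on the mediator via β₁ and on the outcome via
β_direct + β₁β₂ plus any per-SNP pleiotropy; mediator SNPs act on the outcome
via β₂), sets nominal SEs from sample size and allele frequency
(1/√(2p(1−p)n) for quantitative traits, 1/√(2p(1−p)n·K(1−K)) on the log-odds
scale for the binary outcome at prevalence K), and samples observed effects
from their sampling normals. The **individual engine** simulates genotypes
and phenotypes explicitly, with the binary outcome generated by a liability
threshold at the configured prevalence and analysed by per-SNP logistic
regression; configured log-odds effects are converted to liability units by
the first-order constant c = φ(z_K)/(K(1−K)). It is restricted to cohorts of
at most 50,000 and exists to cross-validate the analytic engine — the test
suite verifies that analytic nominal SEs match the individual engine's
empirical sampling spread within 10% at n = 20,000.

Features of real data the generator deliberately omits: LD is block-diagonal
exchangeable and affects only the clumping logic (observed sampling noise is
drawn independently across SNPs); microbial abundances are treated as a
latent quantitative trait, with no compositional count modelling; there is no
sample overlap between the three studies, no population stratification, and
no winner's-curse in instrument effect sizes. Passing tests therefore
establish the correctness and calibration of the estimators and filters under
clean two-sample assumptions, not robustness to those real-data
complications.

`plant_violations` injects named defects for validating the QC and
diagnostics: directional pleiotropy shifts, one gross outlier (Wald ratio 10×
the true effect with its SE shrunk 0.3×), weak instruments (SE inflated so
F < 10 while the source-reported p-value column is left untouched, so the
strength screen — not re-selection — must catch them), reverse-causal SNPs
(outcome Z ≈ 50, exposure Z ≈ 6), and ambiguous palindromic recodings
(A/T alleles at frequency ≈ ½ in both studies).

## Pipeline

The study design runs in four steps: (1) each exposure against the outcome at
the exposure-layer thresholds; (2) each mediator against the outcome at the
mediator-layer thresholds, plus reverse MR (outcome → mediator, default
5×10⁻⁸ instruments — the reverse threshold is an assumption, stated here, as
the design leaves it open) for mediators passing screening; (3) screened
exposures against screened mediators; (4) mediation on qualifying triples.
Reverse-significant mediators are annotated, never excluded. Screening uses
nominal α = 0.05 on IVW by default; Bonferroni and Benjamini–Hochberg modes
are available, and every step table carries the expected-false-positive count
(tests × α) and, in Bonferroni mode, the implied threshold α/tests.

Per-pair sub-seeds are derived from the master seed and the pair label via
SHA-256, so adding a pair never perturbs another pair's results; two runs
with the same config and master seed produce byte-identical report bundles.

Problem sizes in the validation battery (test suite and
`scripts/acceptance.py`) were chosen so the full set completes in a few
minutes on one core: 1,000–2,000 replicates for calibration checks, 200–500
for operating-characteristic and coverage checks, 10⁶ draws for the
Monte-Carlo propagation oracle.

## Known limitations

* No correlated-instrument (LD-aware) IVW; the lenient r² < 0.1 exposure
  layer therefore mildly understates SEs, as flagged in the drop log.
* The Steiger r² is an observed-scale approximation for binary traits.
* Mediation assumes one mediator per triple (no multivariable MR for the
  direct effect, no joint multiple-mediator models).
* The weighted-median/mode bootstrap resamples from reported SEs and ignores
  exposure-outcome sampling correlation (two-sample setting assumed).
* The Egger intercept under planted directional pleiotropy shows a modest
  finite-sample attenuation (≈ 10–15% at J = 50 with strong instruments) due
  to the anti-correlated slope/intercept errors under exposure measurement
  error; the regression itself matches an independent WLS oracle to 10⁻¹⁰.
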