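# Methods

## Setting and data model

`mrkit` performs two-sample Mendelian randomization from per-SNP summary
statistics. The exposure study reports, for each instrument SNP *j*, the
additive effect β̂_Xj of the effect allele on the exposure (a
standardized quantitative trait, so β_X is in SD units) with standard
error σ_Xj; the outcome study reports β̂_Yj, the log odds ratio of the
outcome per effect allele, with σ_Yj. The working model is

- β̂_Xj ~ N(γ_j, σ²_Xj), β̂_Yj ~ N(Γ_j, σ²_Yj), independent errors
  (two-sample design: no overlapping participants);
- Γ_j = θ·γ_j + α_j, where θ is the causal log OR per SD of exposure and
  α_j the SNP's direct (pleiotropic) effect on the outcome.

All estimators are functions of the per-SNP Wald ratios
r_j = β̂_Yj/β̂_Xj. The default ratio SE is the first-order delta method,
σ_Yj/|β̂_Xj|, under which the IVW weights reduce to β̂²_Xj/σ²_Yj; the
second-order form |r_j|·sqrt(σ²_Yj/β̂²_Yj + σ²_Xj/β̂²_Xj) is available
everywhere by flag.

## Harmonization

The outcome association is re-oriented onto the exposure study's effect
allele: identical alleles pass through; swapped alleles negate β_Y and
reflect the EAF; complementary alleles are strand-flipped first.
Palindromic SNPs (A/T, C/G) cannot be strand-resolved from labels; they
are aligned by allele frequency when the minor-allele frequency is below
0.42 and excluded as "palindromic-ambiguous" otherwise. The 0.42 cutoff
is the conventional conservative choice: within ±0.08 of 0.5 the
frequency signal is too weak to distinguish strands reliably. The
threshold is configurable; the bundled instrument set contains no
palindromic SNPs, so its harmonization is a pass-through.

## Instrument selection

The vetting pipeline applies, in order: (1) genome-wide significance
(p < 5×10⁻⁸, strict); (2) LD pruning against a user-supplied r² matrix
with threshold 0.001 — while any pair violates the threshold, remove the
SNP with the most violating partners, breaking ties by larger p-value
and then by later input order (the third key makes the published
degree-then-p rule fully deterministic); (3) exclusion of SNPs with a
genome-wide-significant association with any secondary trait in a local
lookup table. LD and phenome lookups are deliberately file-based: the
upstream services are lookups, not computations, and local tables keep
the pipeline hermetic and testable.

Instrument strength: R² = 2·EAF·(1−EAF)·β²_X (variance explained on a
unit-variance trait) and F = R²(n−2)/(1−R²); F ≤ 10 flags a weak
instrument. Per-SNP sample sizes are used when present, else the
study-level default n = 44,147.

The bundled table stores EAF to two decimals; these are reconstructions
(the published table typesets EAF and F run together) and are the unique
parse consistent with the F formula for seven of the nine SNPs. The two
remaining printed F values are not consistent with any EAF parse at the
study-level n and are carried as printed metadata only.

## Estimators

All methods report θ̂, SE, normal 95% CI (θ̂ ± 1.96·SE), two-sided p,
and the exponentiated OR scale.

- **IVW, fixed effects**: θ̂ = Σw_j r_j/Σw_j with w_j = β̂²_Xj/σ²_Yj;
  SE = (Σw_j)^(−1/2). Identical (to machine precision; property-tested)
  to the zero-intercept WLS slope of β̂_Y on β̂_X with weights 1/σ²_Yj.
- **IVW, random effects**: multiplicative over-dispersion — the fixed SE
  is scaled by max(1, sqrt(Q/(J−1))) with Q Cochran's statistic. The
  floor at 1 means the two IVW rows coincide whenever Q ≤ J−1 (the
  bundled set has Q = 7.20 on 8 df). The additive DerSimonian–Laird
  model is deliberately not used: the multiplicative form is the one
  whose fixed/random rows collapse under under-dispersion.
- **Penalized robust IVW**: each weight is multiplied by
  min(1, 20·p_j), where p_j is the upper χ²₁ tail of SNP j's Q
  contribution — only SNPs individually inconsistent with the IVW fit
  (p_j < 0.05) are down-weighted; the regression is then fit by IRLS
  with the Tukey biweight (c = 4.685, 95% efficiency), via statsmodels
  RLM, and the SE carries an over-dispersion factor floored at 1. The
  penalty is one-step (computed about the plain IVW estimate); under
  gross contamination the contaminated centre can smear penalties onto
  valid SNPs, so the estimator is intended for the moderate-outlier
  regime (~10 SE), which the tests exercise.
- **Maximum likelihood**: the joint normal likelihood over
  (γ_1..γ_J, θ) is profiled — for fixed θ the nuisance effects have the
  closed form γ_j(θ) = (β̂_Xj/σ²_Xj + θβ̂_Yj/σ²_Yj)/(1/σ²_Xj + θ²/σ²_Yj)
  — and θ is found by 1-D minimization; SE from the (θ,θ) block of the
  inverse observed information of the full parameter vector. Unlike IVW
  it propagates exposure-side uncertainty; as σ_X → 0 it reduces to IVW
  (tested at σ_X scaled by 10⁻⁶).
- **Median estimators**: sorted ratios are assigned cumulative weight
  midpoints s_j = Σ_{k≤j}u_k − u_j/2 (u equal, or ∝ β̂²_X/σ²_Y for the
  weighted form) and the estimate interpolates r against s at 0.5. With
  nine equal weights the midpoint falls exactly on the 5th sorted ratio.
  Consistent when ≥ 50% of the weight comes from valid instruments.
- **Mode-based estimators**: the estimate is the argmax of a Gaussian
  kernel density over the ratios, on a 10,000-point grid spanning the
  ratio mean ± 5 SD (grid error ≪ reporting precision); bandwidth
  h = φ·0.9·min(SD, 1.4826·MAD)·J^(−1/5) with φ = 1 by default,
  following the original mode-based-estimate rule (unweighted spread).
  Kernel weights are equal (simple) or inverse squared ratio SEs
  (weighted); the weighted form uses second-order delta SEs by default,
  again following the original formulation (first-order available by
  flag). Consistent under ZEMPA: the largest homogeneous ratio cluster
  is valid. If all ratios coincide the bandwidth degenerates and the
  common ratio is returned with SE 0, flagged in the method label.
- **Bootstrap SEs** (median and mode): parametric — each replicate
  redraws β̂*_Xj ~ N(β̂_Xj, σ_Xj) and β̂*_Yj ~ N(β̂_Yj, σ_Yj) and
  recomputes the estimate; SE is the SD over 1000 replicates (default).
  The generator is an explicit seeded `numpy` Generator passed down,
  never global state; results are bit-reproducible under a fixed seed.
- **MR-Egger**: instruments are first oriented so every β̂_X ≥ 0
  (negating both betas, to which the model is invariant), then WLS of
  β̂_Y on β̂_X *with* intercept, weights 1/σ²_Y. The slope is the causal
  estimate under InSiDE (pleiotropy independent of instrument strength);
  the intercept estimates the average directional pleiotropic effect.
  Both SEs carry a multiplicative over-dispersion factor floored at 1;
  CIs use normal quantiles, which reproduce the reference analysis
  (t quantiles would not).

## MR-PRESSO

For each SNP the leave-one-out IVW slope θ̂₍₋ⱼ₎ defines its residual
d_j = β̂_Yj − θ̂₍₋ⱼ₎β̂_Xj (so a pleiotropic SNP cannot mask itself);
the observed statistic is RSS = Σ d²_j/σ²_Yj. Its null distribution is
simulated: β̂*_Xj ~ N(β̂_Xj, σ_Xj), β̂*_Yj ~ N(θ̂₍₋ⱼ₎β̂_Xj, σ_Yj), with
the RSS of each replicate computed by the same leave-one-out recipe.
Monte-Carlo p-values use (1 + exceedances)/(n_sim + 1). Per-SNP outlier
p-values compare each observed weighted squared residual with its
simulated distribution, Bonferroni-adjusted; the corrected estimate is
IVW on the non-outliers, and the distortion test compares the raw-minus-
corrected difference with the distribution obtained by removing random
subsets of the same size (skipped, reported as None, when no outliers
are found). Internal slope reporting follows the original MR-PRESSO
convention — WLS SE without the floor at 1 and a t(J−1) p-value — which
is why its CI is slightly narrower than the fixed-effects IVW row when
Q/df < 1. The global test's type-I error is verified at 0.05 ± 3
binomial SEs over 500 null datasets in the test suite.

## Synthetic data

The simulator draws, per SNP: allele frequency p_j ~ U(maf_range); true
exposure effect γ_j ~ N(gamma_mean, gamma_sd) or a fixed list; direct
effect α_j = 0 (none), N(0, alpha_sd) (balanced) or
N(alpha_mean, alpha_sd) (directional) — always independent of γ_j, so
InSiDE holds by construction; sampling SEs from the standard GWAS
asymptotics σ_Xj = (2n_X p_j(1−p_j))^(−1/2) for a standardized
quantitative exposure and σ_Yj = (2n_Y p_j(1−p_j)·cf(1−cf))^(−1/2) for a
binary outcome with case fraction cf (normal approximation to the
logistic score); observed betas normal about the truth. True values are
returned in a separate sidecar so analysis code cannot read them by
accident. `scenario_from_fixture` mirrors the bundled study's shape:
J = 9, n_X = 44,147, n_Y = 15,664 with cf = 3968/15664 ≈ 0.253, and γ
matched to the fixture's exposure-beta spread.

What the simulator does *not* emulate: LD between instruments (it
mirrors the post-pruning state), InSiDE-violating (correlated)
pleiotropy, winner's-curse selection of instruments, sample overlap
between the two studies, and non-collapsibility of the odds ratio.
Passing calibration tests therefore demonstrate correctness of the
estimators under the stated model, not robustness to those real-data
complications.

## Problem sizes and numerical choices

Default analysis sizes — 1000 bootstrap replicates, 1000 MR-PRESSO
simulations — complete in seconds for nine instruments. The test-suite
calibration runs use 200–500 replicate datasets (with 999 MR-PRESSO
simulations each for the type-I check) and instrument counts of 10–100;
these sizes put Monte-Carlo error well inside the asserted bands (e.g.
coverage SE ≈ 0.01 at 500 replicates) while keeping the whole suite
under a minute. Parameter-recovery runs use strong instruments
(mean F > 100) so that the first-order weak-instrument bias of IVW
(≈ 1/F̄) is negligible against the 1%-of-θ bias band.

Ties and degeneracies: LD pruning breaks ties degree → p-value → later
input order; identical Wald ratios give Q = 0, I² = 0, random = fixed
IVW, and degenerate (SE 0) median/mode estimates; p-values are clamped
into (0, 1] (Monte-Carlo p-values cannot be 0 by construction).
Full printed precision is kept on ingest and through JSON serialization
(`repr` round-trip; readers use exact float parsing) so the published
table is reproduced without rounding drift.

## Known limitations

- Single-exposure only: no multivariable MR, no Steiger directionality
  filtering, no LD-aware (correlated-instrument) IVW.
- The exposure is assumed standardized; R²/F are wrong if β_X is on an
  unstandardized scale.
- MR-Egger's intercept test has low power with few instruments and a
  narrow spread of instrument strengths; a null intercept is not proof
  of no pleiotropy.
- The penalized robust IVW's one-step penalty can be distorted by gross
  (≫ 10 SE) contamination, as noted above.
- Binary-outcome effects are treated as log ORs from logistic-score
  asymptotics; rare-disease approximations and non-collapsibility are
  not modelled.
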