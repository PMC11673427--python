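# Methods

## Model

Two-sample summary-data MR treats the per-variant associations
(β̂_Xj, se_Xj) from an exposure GWAS and (β̂_Yj, se_Yj) from an
independent outcome GWAS as noisy observations of underlying effects
γ_j and θγ_j + α_j, where θ is the causal effect of a 1-SD change in
the exposure (on the log-odds scale for a binary outcome) and α_j is a
direct (horizontally pleiotropic) effect. The package estimates θ by

- **IVW**: weighted zero-intercept regression of β̂_Y on β̂_X with
  weights w_j = 1/se_Yj². With multiplicative random effects the SE is
  inflated by √φ̂, φ̂ = max(1, Q/(J−1)), so fixed- and random-effects
  answers coincide whenever heterogeneity is at or below its expectation.
  Valid when all α_j = 0 (or average out with weights).
- **Weighted median**: the ratio β̂_Yj/β̂_Xj at the point where the
  cumulative inverse-variance weight crosses ½ (piecewise-linear
  interpolation between order statistics). Consistent when instruments
  carrying at least half the weight are valid — but only in the limit of
  precise per-SNP ratios; with noisy ratios the median of the mixture
  distribution retains some contamination bias (see Limitations).
- **MR-Egger**: the same regression with a free intercept after
  orienting every SNP so β̂_Xj ≥ 0. Under InSIDE (instrument strength
  independent of direct effects) the intercept estimates the average
  pleiotropic effect and the slope remains consistent for θ. Both SEs
  are inflated by √max(1, Q′/(J−2)).
- **MR-Egger + SIMEX**: measurement error in β̂_X attenuates the Egger
  slope when the spread of true effects is not large relative to se_X,
  quantified by I²_GX (the signal fraction of the weighted variance of
  |β̂_X|). SIMEX adds noise of variance λ·se_Xj² for λ in
  {0, 0.5, 1, 1.5, 2} (B replicates per λ, default 1000), fits a
  quadratic in λ to the per-λ mean slope and intercept, and extrapolates
  to λ = −1. Orientation is applied once, before the noise: re-orienting
  inside replicates folds the noise distribution and biases the trend
  (verified empirically during development). The SE uses the naive SIMEX
  variance — quadratic extrapolation of (mean model variance − between-
  replicate variance) per λ, falling back to the plain Egger variance if
  the extrapolated variance is non-positive. The pipeline runs SIMEX
  when I²_GX < 90%, the conventional trigger, or always with
  `simex_always`.
- **MR-PRESSO**: the observed residual sum of squares about
  leave-one-out IVW fits is compared with its parametric-bootstrap null
  (β̂*_Xj ~ N(β̂_Xj, se_Xj), β̂*_Yj ~ N(θ̂₍₋ⱼ₎β̂_Xj, se_Yj)); empirical
  p-values carry a +1 continuity correction so they are never zero.
  Per-SNP outlier p-values are the tails of each SNP's own simulated
  residual term, Bonferroni-corrected across J at α = 0.05; the
  corrected estimate is IVW without the flagged SNPs. The distortion
  test exists behind a flag but is not part of the default report.

Heterogeneity: Cochran's Q (about the IVW fit, χ²_{J−1}) and Rücker's
Q′ (about the Egger fit, χ²_{J−2}); Q ≥ Q′ always, since the free
intercept cannot increase the weighted RSS.

Multivariable MR regresses β̂_Y on the J×K matrix of exposure effects
(no intercept for IVW; intercept plus whole-row sign orientation on a
chosen exposure for Egger) with weights 1/se_Y², SEs inflated by
√max(1, RSS_w/(J−K)). Instruments are the union of each exposure's
genome-wide-significant hits, jointly clumped on each variant's minimum
p across exposures; every retained SNP's effect on every exposure is
taken from the full summary tables regardless of significance.
Exposure measurement error is ignored (standard MVMR-IVW weighting).

Power for a binary outcome uses the normal-approximation non-centrality
ν = ln(OR)·√(N·R²·K(1−K)); the test suite checks it against a
Monte-Carlo oracle of the IVW Wald test to ±0.03.

## Key parameters

| parameter | default | notes |
|---|---|---|
| GWAS significance threshold | 5×10⁻⁸ | strict inequality |
| clumping r² / window | 0.001 / 10,000 kb | greedy, min-p first, ties by (chrom, pos) |
| palindromic frequency window | 0.08 | keep only if both EAFs outside 0.42–0.58 and concordant |
| weighted-median bootstrap | 1000 draws | parametric, seeded |
| SIMEX grid / B | (0, 0.5, 1, 1.5, 2) / 1000 | quadratic extrapolant |
| MR-PRESSO n_sim / outlier α | 1000 / 0.05 | Bonferroni across J |
| p-value reference | normal | t(J−2) available for Egger |

Per-SNP F uses the squared-Z form (β/se)², which needs no allele
frequency; the exact regression form r²(n−2)/(1−r²) sits behind a flag.
Per-SNP r² uses the t-statistic transform F/(F+n−2). Variant identity
is by identifier alone (summary files disagree on genome builds); a
strict chromosome/position cross-check is deliberately not default.

## The synthetic generator

`simulate_two_sample` draws summary statistics directly at the summary
level: MAF p_j uniform in (0.05, 0.5); true effects γ_j as half-normal
magnitudes scaled so Σ2p_j(1−p_j)γ_j² equals a target R² (effects are
reported for the exposure-increasing allele, so positive orientation is
the identity on truth and planted directional pleiotropy is not
attenuated by sign flips); se_Xj = 1/√(2n_X p_j(1−p_j)) for the
continuous exposure and se_Yj = 1/√(2n_Y K(1−K) p_j(1−p_j)) for the
binary outcome. Defaults are the ApoA→AMD configuration: J = 308,
n_exposure = 364,987, n_outcome = 357,849, K = 8913/357,849,
R² = 0.11, θ = ln(1.14). Pleiotropy regimes: none, balanced,
directional (mean μ_α on a random invalid fraction), and
InSIDE-violating (α proportional to γ plus noise). `simulate_ld_panel`
builds block-diagonal r² references with within-block-correlated Z
scores so clumping is non-trivial; `simulate_mvmr` draws correlated
per-SNP exposure effects. Identical seeds give byte-identical tables.

What the generator does **not** model: sample overlap between the two
GWAS, winner's curse beyond what explicit selection induces, LD between
instruments in the association tables themselves, population
stratification, and non-collapsibility of the odds ratio. Passing tests
therefore demonstrate correctness of the estimators under their own
assumptions, not robustness to those artefacts of real data.

## Problem sizes used in tests

Calibration experiments use J = 100 instruments and 1000 replicates
(IVW unbiasedness, coverage, type-I error), 400 replicates for the
pleiotropy-separation experiment, 100/200 seeds for MR-PRESSO outlier
recovery and null uniformity (J = 20, n_sim = 500–1000), and 500
replicates for the SIMEX comparison (J = 50, B = 100). These sizes give
Monte-Carlo errors comfortably below the tolerances asserted while
keeping the default suite around ten seconds.

## Design decisions and numerical choices

- The pleiotropy-separation experiment applies genome-wide-significance
  selection before estimating, as the pipeline itself does. This
  matters: without selection, the weakest half-normal instruments carry
  large relative measurement error and the Egger intercept systematically
  under-recovers the planted mean pleiotropy by ~10% even at
  I²_GX ≈ 98% (an errors-in-variables artefact that vanishes as
  n_exposure → ∞); after selection the intercept is unbiased to within
  Monte-Carlo error. The planted directional effect (μ_α = 0.05) is
  chosen to exceed the per-SNP outcome noise (se_Y ≈ 0.0175 at the AMD
  scale), the regime in which median-type robustness is meaningful.
- The SIMEX acceptance experiment engineers I²_GX ≈ 70% with normal
  (not half-normal) effects bounded away from zero
  (γ ~ N(0.1, 0.01²), se_X = 0.0065). When low I²_GX instead arises
  from significance selection of many weak effects, the selected
  errors are not mean-zero (winner's curse) and SIMEX — whose error
  model assumes symmetric noise — over-corrects; that regime is a
  documented limitation, not a target of the correction.
- Empirical p-values use (1 + #exceedances)/(1 + n_sim).
- The MVMR solver uses the pseudoinverse so a degenerate column yields
  a zero coefficient rather than an exception in solver-level tests;
  user-facing entry points still reject near-collinear designs
  (smallest singular value ≤ 10⁻⁶ × largest).
- Simulated p-values are floored at 10⁻³⁰⁰ so extreme associations
  survive the round trip through text tables; the reader's
  p-consistency validation skips the underflow region.
- The power target's OR = 1.14 is the observed IVW estimate for
  ApoA→AMD, adopted as the hypothesised effect because no separate
  design OR is available; this is an assumption, not data.

## Limitations

- No genome-build liftover, GWAS-VCF input, or proxy-SNP lookup.
- No mode-based estimators, MR-RAPS, Steiger filtering, or conditional
  F-statistics for MVMR.
- The weighted median's 50%-invalid breakdown guarantee is asymptotic
  in per-ratio precision; at case-control outcome scales with a few
  thousand cases its bias under contamination is reduced relative to
  IVW but not eliminated.
- LD references are consumed, never estimated from genotype panels.
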