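# Methods

## The causal model and its assumptions

For exposure X (a variance-standardized serum metabolite) and binary
outcome Y (a stroke phenotype on the log-odds scale), each instrument
SNP j supplies summary associations (β̂_Xj, σ_Xj) and (β̂_Yj, σ_Yj)
estimated in non-overlapping samples. Under the three instrumental
conditions — relevance (the SNP affects X), exchangeability
(independence of confounders of X–Y) and exclusion restriction (no
effect on Y except through X) — every per-SNP Wald ratio
θ̂_j = β̂_Yj/β̂_Xj estimates the same causal log-odds effect θ, and the
estimators below pool them with different robustness/efficiency
trade-offs. Horizontal pleiotropy (a direct SNP→Y path α_j) violates
exclusion; the sensitivity suite exists to detect and absorb it.

## Instrument processing

1. **Selection**: keep SNPs with exposure p < `iv_p_threshold`
   (default 1e-5, the locus-wide "suggestive" convention appropriate for
   metabolite GWAS, where genome-wide-significant hits are often too few
   to instrument a trait). Ties in p are broken by variant id so runs are
   deterministic.
2. **LD clumping**: greedy by ascending p; a retained index variant
   removes every remaining variant on the same chromosome within
   ±`clump_window_kb` (default 5000 kb, inclusive) whose pairwise
   r² > `clump_r2` (default 0.01). LD is an explicit input (long-format
   TSV); unknown pairs default to r² = 0 (independent), configurable,
   because no particular reference panel is assumed.
3. **Strength**: per-SNP variance explained R²_j = 2·eaf(1−eaf)·β̂²_Xj
   under the standardized-exposure convention, falling back to
   R²_j = z²/(z² + N − 2) when eaf is missing (both choices logged per
   SNP); F_j = R²_j(N−2)/(1−R²_j), filter F > `f_min` (default 10).
   Filtering is per-SNP; the set-level ΣR² is reported for information
   and drives the power approximation.
4. **Harmonization**: palindromic (A/T, C/G) SNPs are dropped
   unconditionally — allele frequency cannot resolve strand reliably at
   intermediate frequencies, and the loss of a few instruments is the
   cheaper error. Outcome alleles are matched directly, by swap
   (negating β̂_Y, reflecting eaf), or after complementing both alleles
   (strand flip), in that order; irreconcilable variants are dropped.
   Every removal at every stage carries exactly one reason code in the
   exclusion log, so removals partition the input.
5. **Confounder screen**: an optional one-id-per-line exclusion list
   (e.g. assembled from a phenome-wide lookup) removes instruments
   associated with known confounders. No web queries are performed.

## Estimators

* **IVW**: with first-order ratio SEs σ_j = σ_Yj/|β̂_Xj| and weights
  w_j = 1/σ_j², θ̂ = Σw_jθ̂_j/Σw_j (algebraically the 1/σ²_Y-weighted
  regression of β̂_Y on β̂_X through the origin). Fixed-effects
  SE = (Σw_j)^(−1/2); Cochran's Q = Σw_j(θ̂_j−θ̂)² on J−1 df;
  I² = max(0, (Q−(J−1))/Q). The random-effects model is multiplicative:
  SE inflated by max(1, √(Q/(J−1))), selected when the Q-test p < α
  (default 0.05); the floor at 1 keeps fixed = random when Q ≤ J−1.
  Inference is normal.
* **MR-Egger** (J ≥ 3): orient all β̂_Xj ≥ 0 (recode alleles by flipping
  both betas), then weighted linear regression of β̂_Y on β̂_X with
  weights 1/σ²_Yj and a free intercept. The slope estimates θ under
  InSIDE (pleiotropy independent of instrument strength); the intercept
  estimates the mean directional pleiotropic effect across instruments.
  Inference is t on J−2 df with the same multiplicative overdispersion
  floor. The I² reported with it is heterogeneity I² from the weighted
  residual sum; the I²_GX regression-dilution statistic is a different
  quantity and is not computed.
* **Weighted median** (J ≥ 3): sort ratios, form breakpoints
  s_j = Σ_{k≤j} w̃_k − w̃_j/2 from normalized weights, interpolate at
  s = 0.5. Consistent when valid instruments carry >50% of weight. SE =
  SD of the estimate over `n_boot` (default 1000) parametric-bootstrap
  replicates drawing β̂*_X, β̂*_Y around the observed values; seeded.
* **MR-PRESSO style residual test** (J ≥ 4): RSS_obs =
  Σ_j w_j(β̂_Yj − θ̂_{−j}β̂_Xj)² with leave-one-out IVW expectations and
  w_j = 1/σ²_Yj; K simulations (default 1000) of β̂*_Y under those
  expectations give the global p = (1+#{RSS* ≥ RSS_obs})/(K+1), so its
  resolution is 1/(K+1). Per-SNP observed residuals are referred to their
  own simulated distributions, Bonferroni-multiplied by J, flagged below
  `outlier_alpha` (0.05). The corrected estimate is IVW on the unflagged
  set; the distortion coefficient (percent change raw→corrected) is
  referred to random same-size removals, two-sided. J ≥ 4 guarantees ≥3
  SNPs after a single-outlier removal. The implementation follows the
  published algorithm, not any package's internal constants, and is
  validated by its operating characteristics (below).
* **Leave-one-out** (J ≥ 2): IVW re-estimates dropping each SNP, same
  model-selection rule.
* **Power**: two-sided power for a binary outcome from the
  non-centrality λ = |θ|·√(N·ΣR²·K(1−K)); returns α at θ = 0.

## Discovery control

p-values < 0.05 are "nominal"; Benjamini–Hochberg adjustment
(q_(i) = min_{j≥i} p_(j)·m/j, capped at 1) is applied within each
outcome's family of exposures — the grouping whose arithmetic matches a
452-metabolite-per-outcome screen (a rank-1 p multiplies by m, a rank-3
p by m/3). The reverse direction uses the symmetric grouping (family =
all outcomes for one exposure); instrument selection for binary
exposures reuses the same thresholds. Tiers, applied only to
FDR-significant records: `passed_all` when Egger, weighted-median and
the PRESSO-corrected estimates are all individually significant;
`robust` when weighted-median and PRESSO both are; `potential` when
PRESSO is but the weighted median is not; `non_robust` otherwise.
"PRESSO significant" means the corrected estimate's p when outliers were
flagged, else a significant IVW together with a non-significant global
test — i.e. passing requires both no distortion and a surviving signal.
Per-pair seeds derive from the master seed by stable hashing of
(exposure, outcome, direction), so any single pair reproduces in
isolation.

## Pathway over-representation

Per outcome, metabolites with nominal IVW p < 0.05 form the significant
set; each (source, pathway) annotation is tested with the exact
hypergeometric upper tail P(X ≥ k), X ~ HG(N, K, n), background = all
metabolites in the annotation table (the conservative choice), BH across
pathways within the outcome. No continuity approximation; identifier
translation across annotation namespaces is out of scope.

## The synthetic generator

`SimulationScenario` emulates the screen's data shape: a 7,824-sample
standardized-metabolite exposure GWAS and a stroke-scale binary outcome
GWAS (default 446,696 samples, 34,217 cases — the any-ischemic-stroke
shape; other cohort shapes from the screen's Table of outcomes are in
`synthetic.COHORTS`). Per SNP: maf ~ U(maf_range), true effect
b_j = ±√(ve_j/2p(1−p)) hits the requested variance explained,
σ_X = 1/√(2p(1−p)N_X), and the binary-outcome SE uses the
effective-sample calibration σ_Y = 1/√(2p(1−p)·N_Y·K(1−K)) — the
standard log-odds approximation, adequate for operating-characteristic
work though not an individual-level logistic simulation. Pleiotropy α_j
applies to a random invalid fraction: balanced (mean 0), directional
(mean μ), or InSIDE-violating (α correlated with |b| at `inside_corr`,
default 0.6, giving MR-Egger a documented failure regime). Default
per-SNP ve is 0.003 (F ≈ 23), matching a metabolite GWAS whose weakest
retained instruments sit comfortably above F = 10. `effect_sign`
controls allele orientation: "random" (default) mirrors arbitrary
effect-allele coding; "positive" orients effects as trait-increasing,
the regime where directional pleiotropy actually biases IVW (with random
signs, E[α/β_X] cancels by symmetry). What the generator does **not**
model: LD beyond simple within-block r², realistic frequency spectra,
winner's curse at selection, sample overlap, population stratification.
Passing tests therefore demonstrate estimator and pipeline correctness
under the stated generative model, not robustness to those real-data
complications.

## Calibration experiments (`mrscreen.validation`)

Problem sizes were chosen so the full suite runs in well under a minute
on one CPU at 500–1000 replicates per experiment.

* **Recovery/coverage** (1000 pairs, J=50, true OR 1.5): uses the
  subarachnoid-hemorrhage cohort shape (3,289 cases / 339,922 controls)
  and strong instruments (ve = 0.018/SNP, F ≈ 141). Two structural
  facts shape this design. First, the first-order Wald variance ignores
  exposure noise; its validity requires θ²·N_eff,Y ≪ N_X. At the largest
  cohort shapes with OR 1.5 that ratio is ≈ 0.66 and nominal 95%
  intervals genuinely cover ≈ 93% — a known limitation of first-order
  two-sample MR, not an implementation artifact — whereas at the
  hemorrhagic-stroke scale the ratio is ≈ 0.07 and coverage is nominal.
  Second, regression dilution attenuates the mean estimate by ≈ 1/(F+1);
  the recovery check therefore asserts 2% relative accuracy rather than
  pure Monte-Carlo error, which no finite-F two-sample design can meet.
* **Type-I error** (1000 pairs, θ=0, default scenario): IVW rejection at
  α = 0.05 must sit in 5% ± 1.5%.
* **Egger regime** (1000 pairs): directional pleiotropy μ = 0.08
  (sd 0.02) on a random half of instruments, InSIDE holding. The
  intercept estimates the mean pleiotropic effect across all
  instruments, i.e. invalid_fraction·μ = 0.04. The scenario uses a
  two-point instrument-strength design (ve ∈ {0.0008, 0.037}, maf
  0.25–0.35) so the weighted strength reliability (I²_GX in the Egger
  literature) is ≈ 0.98 — the no-measurement-error regime the recovery
  property assumes; at lower reliability the slope dilutes and the
  intercept absorbs the remainder, which is Egger's documented weakness,
  not a target of this check.
* **Weighted-median regime** (1000 pairs, J=20): 40% invalid instruments
  sharing α = 0.073 at θ = ln 2 with high per-SNP precision
  (ve = 0.045/SNP, maf 0.2–0.4). The WM finite-sample bias under a
  shared shift saturates near Φ⁻¹(0.5/0.6)·σ_ratio, so the contrast
  "WM median bias < 10% of θ while IVW exceeds it" is demonstrable only
  where per-SNP ratio noise is small relative to θ; this scenario
  predicts ≈ 6% vs ≈ 12–14% and the simulations confirm it.
* **PRESSO operating characteristics**: global-p decile occupancy within
  10% ± 4 points under the no-pleiotropy null (500 replicates, K=1000,
  θ=0 — at θ=0 the simulation null matches the generative null exactly);
  detection of a single 8-outcome-SE displaced SNP in ≥90% of 200 sets
  (J=20); removing flagged outliers never increases Q.
* **Null screen**: 100 null exposures against one outcome yield 0–1
  FDR-significant records.

## Numerical and degenerate-input choices

z_{0.975} is fixed at 1.959964 (the printed-report convention). Wald
ratios raise a named error on β̂_X = 0. Egger returns nothing on a
degenerate design (all β̂_X equal after orientation) or J < 3; the
weighted median clamps bootstrap β̂*_X away from exactly 0. Empirical
p-values use the (1+#)/(K+1) form so they are never 0. Hypergeometric
p-values are clamped to ≥1e-300. Tie-breaks (selection order, weighted
median sorting) are stable sorts. Floats serialize at 17 significant
digits so write∘read is the identity to better than 1e-12 relative.

## Known limitations

First-order Wald variances are anti-conservative when the exposure GWAS
is much smaller than the effective outcome sample and θ is large (see
the coverage discussion above). No Steiger filtering, proxy-SNP
substitution, second-order ratio variances, mode-based or multivariable
estimators. The LD model is a user-supplied pairwise table, not a
haplotype reference. Reverse screens at strong forward transmission can
pick up forward-causal SNPs through winner's curse (no directionality
filter is applied); the bundled fixtures demonstrate divergence in the
regime where per-SNP outcome associations stay below the selection
threshold.
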