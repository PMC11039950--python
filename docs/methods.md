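# Methods

## Model

For one exposure–outcome pair, each instrument j carries a per-SD exposure
effect estimate γ̂ⱼ (SE σ_Xⱼ) and a log-odds outcome effect estimate Γ̂ⱼ
(SE σ_Yⱼ), aligned to one effect allele. Under the instrumental-variable
assumptions (relevance, no confounding of the instrument, exclusion
restriction), Γⱼ = β₀γⱼ, and each Wald ratio β̂ⱼ = Γ̂ⱼ/γ̂ⱼ estimates the
causal log-OR per SD of abundance, β₀. Horizontal pleiotropy adds a direct
effect αⱼ so Γⱼ = β₀γⱼ + αⱼ; the five estimators trade off efficiency against
robustness to different pleiotropy configurations, and the diagnostics test
for it.

Per-SNP ratio SEs are first-order, σ_Yⱼ/|γ̂ⱼ|, matching the convention of the
standard summary-data MR toolchains; exposure-side noise is ignored in the
per-SNP SE (a second-order option exists behind `wald_se_order=2`) but is
fully exercised by the parametric bootstrap and the PRESSO simulations. All
two-sided p-values use the normal distribution, again the summary-data MR
convention, even at small J.

## Estimators and numerical choices

* **IVW**: weighted mean of ratios, w = γ̂²/σ_Y². Fixed-effect SE (Σw)^(−1/2);
  the multiplicative random-effects SE multiplies it by max(1, √(Q/(J−1))), so
  it never shrinks below the fixed SE. `auto` selects random-effects exactly
  when Cochran's Q has p < 0.05, mirroring the choose-by-heterogeneity rule.
* **MR-Egger**: records are first oriented so γ̂ ≥ 0 (the estimate is
  orientation-dependent; this is the toolchain convention), then Γ̂ is
  regressed on γ̂ with intercept, weights 1/σ_Y². Coefficient SEs are the
  unscaled WLS SEs times max(1, residual sd) — multiplicative random effects
  with a floor at the fixed-effect covariance.
* **Weighted median**: ratios sorted ascending; with normalized weights uⱼ the
  breakpoints are (Σ_{k≤j} u_k) − uⱼ/2; the estimate interpolates linearly in
  cumulative weight to the 0.5 point. Below the first breakpoint the smallest
  ratio is returned (cannot occur for J ≥ 2 with positive weights at both
  ends).
* **Weighted mode**: weighted Gaussian KDE over the ratios, bandwidth
  h = φ·0.9·min(sd, mad/0.6745)·J^(−1/5) (φ defaults to 1; mad is scaled to
  sd-consistency). The estimate is the density argmax over a 512-point grid
  spanning [min−3h, max+3h]; the grid resolution is the argmax-stability
  constant of the implementation. If all ratios coincide (h = 0) the common
  ratio is returned. The kernel is evaluated in single precision in-place;
  the argmax over the grid is insensitive to that rounding.
* **Bootstrap SEs** (median and mode): parametric — n_boot (default 1000)
  draws of (γ̂*, Γ̂*) from normals centred at the observed effects with the
  observed SEs, re-estimating each time; SE = sd of the re-estimates. Fully
  seeded and vectorized across bootstrap replicates.
* **MR-PRESSO**: observed residuals use the leave-one-out IVW prediction,
  rⱼ = Γ̂ⱼ − β̂₍₋ⱼ₎γ̂ⱼ, and RSS = Σ rⱼ²/σ_Yⱼ². K (default 1000) parametric
  simulations of both sides give the null RSS distribution; p-values use the
  add-one rule (1+#)/(K+1) so they are never zero. Per-SNP outlier tests are
  Bonferroni-adjusted over J and flagged at 0.05; the corrected estimate is
  fixed-effect IVW on the non-outliers; the distortion test compares the
  observed relative shift against K random outlier-sized exclusions.
* **Cochran's Q** is always centred on the fixed-effect IVW estimate
  (definitional: the random-effects scale is derived from this Q).
* Ties in clumping are broken by (p, chromosome, position, rsID) so the result
  is invariant to input order; a pair absent from the LD table counts as
  r² = 0 and is tallied as a diagnostic.
* BH-FDR is computed via `statsmodels.stats.multitest.multipletests`
  (method `fdr_bh`) behind the package's `bh_fdr` surface; the test suite
  checks it against an explicit step-up oracle. The q = 0.1 boundary is
  assigned to "suggestive" (significance requires q strictly below 0.1).
  The FDR family is all exposures tested against one outcome.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical layer of the two-sample design the
pipeline targets. Defaults are the study conditions: n_x = 14,306 (European
microbiome-GWAS cohort size), n_y = 12,677 (effective size of an abdominal
aortic aneurysm case–control GWAS, 3,201 cases / 317,899 controls,
4/(1/n₁+1/n₀)), J = 14 instruments per taxon, τ = 0.05 for the spread of true
per-SD effects — together giving per-instrument F statistics around 20–40,
matching what survives an F ≥ 10 filter in practice. Per-SNP SEs follow
1/√(2p(1−p)n) with allele frequency p ~ U(0.05, 0.95).

True exposure effects are drawn as |N(0, τ²)|: the effect allele is coded as
the abundance-increasing allele. This coding makes "directional" pleiotropy
(μ_α ≠ 0) directional with respect to the γ ≥ 0 orientation that MR-Egger
uses; with sign-symmetric γ the orientation flip would exactly cancel a
directional mean. The estimate γ̂ is resampled until it clears the locus-wide
threshold, so each replicate has exactly J instruments (selection is
conditioned on, not filtered post hoc, keeping fixture sizes fixed). Invalid
instruments receive αⱼ = κγⱼ + N(μ_α, σ_α²) with σ_α defaulting to 0.02;
κ ≠ 0 violates InSIDE. Harmonization stressors (palindromic pairs, strand
flips, swapped alleles) are injected in stated fractions and logged in the
returned truth, so the drop log can be checked exactly.

Not emulated: real LD (blocks are synthetic with constant within-block r²),
allele-frequency spectra, sample overlap between the two GWAS, population
stratification, winner's-curse from discovery in the same data, and the
abundance-measurement layer (only the GWAS summary level is simulated).
Passing tests therefore demonstrate correctness of the statistical pipeline
under its own model, not robustness to those real-data features.

## Monte-Carlo study sizes

The calibration and power experiments in the test suite and
`scripts/acceptance.py` use: 500 replicates for type-I error, CI coverage and
Egger intercept power (J = 50); 200 replicates for PRESSO outlier power
(J = 20). The recovery experiments use a strong-instrument base scenario,
τ = 0.1 and n_x = 200,000 (per-instrument F ≈ 10³): at that strength the
first-order weak-instrument attenuation of IVW (≈ β₀/F̄) is far below the
Monte-Carlo error of the mean at 500 replicates, so bias checks measure the
estimators rather than instrument strength. The analysis script
`05_recovery_study.py` runs a reduced 200-replicate grid with n_boot and K at
200 for quick turnaround.

## Known limitations

* The parametric bootstrap SEs of the weighted median and mode run
  conservative: at the strong-instrument recovery scenario their 95% CIs
  cover the truth in ~97–98% of replicates (IVW, Egger and PRESSO sit at
  ~95%). The direction is safe but interval widths for those two estimators
  should be read as upper bounds.
* MR-Egger's intercept test has intrinsically limited power when the
  pleiotropy mixture itself (a fraction ρ of SNPs shifted by μ_α) inflates
  the residual heterogeneity that scales its SE; at μ_α = 0.05, ρ = 0.3,
  J = 50 the power sits near one half.
* Proxy-SNP substitution and confounder lookup against external catalogs are
  out of scope: unmatched instruments are dropped with a logged reason and
  the blacklist is user-supplied, keeping runs reproducible offline.
* Indels and palindromic-SNP rescue by allele frequency are not supported;
  palindromes are always dropped.
* Positions are treated as opaque within one analysis; no liftover between
  genome builds.
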