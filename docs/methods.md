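# Methods

## Model and assumptions

All estimators operate on per-variant two-sample summary statistics
(γ̂ⱼ, σ_Xj, Γ̂ⱼ, σ_Yj), j = 1…L, assumed to come from the generative model

    γ̂ⱼ ~ N(γⱼ, σ²_Xj),    Γ̂ⱼ ~ N(αⱼ + β γⱼ, σ²_Yj),

with mutually independent errors across variants (uncorrelated variants; any
LD pruning happens upstream) and non-overlapping exposure and outcome
samples. γⱼ ≠ 0 for every variant (each instrument is genuinely associated
with the exposure), and the coding convention is γⱼ > 0. MR-Egger is
consistent for β under InSIDE (instrument strengths independent of direct
effects αⱼ) *and* NOME (σ_Xj ≈ 0); this package is about what happens when
NOME fails while InSIDE holds.

Out of scope by design: allele-letter/strand harmonization, palindromic
variants, LD clumping, correlated variants, single-sample MR,
binary-outcome non-collapsibility and case-control ascertainment, additive
(DerSimonian–Laird) random effects, and median/mode estimators.

## Estimators and inference

**Ratio and IVW.** β̂ⱼ = Γ̂ⱼ/γ̂ⱼ with first-order (NOME) SE σ_Yj/|γ̂ⱼ|. The
IVW estimate is the wⱼ = γ̂ⱼ²/σ²_Yj weighted mean of the β̂ⱼ, identical to the
zero-intercept WLS slope of Γ̂ on γ̂ with weights 1/σ²_Yj (an equivalence the
test suite asserts to 1e−10 against statsmodels). A variant with γ̂ⱼ = 0
raises a degenerate-instrument error rather than silently producing an
infinite ratio.

**MR-Egger.** Straight-line fit of Γ̂ on γ̂ with a free intercept. The
weighted form (default for observed data) uses WLS weights 1/σ²_Yj — the
inverse-variance reading of "weighting by the precision of the outcome
association", consistent with the IVW weights. Because MR-Egger is not
invariant to allele recoding, `egger()` first orients all exposure
associations positive and records how many variants were flipped.

**Multiplicative random effects.** For inverse-variance-weighted fits
(IVW and weighted Egger) the fixed-effect covariance is inflated by
φ = max(1, √(RSS_w/df)), df = L−1 (IVW) or L−2 (Egger): pleiotropy-driven
over-dispersion widens intervals, under-dispersion never narrows them
(φ is floored at 1, since on the weighted scale the fixed-effect residual
variance is 1). The *unweighted* Egger fit uses the ordinary OLS residual
variance without a floor — the raw outcome scale has no unit baseline to
floor against, and flooring there would destroy all power whenever σ_Y ≪ 1.
Consequently `MRResult.overdispersion` is ≥ 1 for weighted fits and is the
raw residual SD for unweighted fits (a perfect unweighted fit has SE 0).
Tests are two-sided Student-t at α = 0.05 by default.

## Instrument strength: F and I²GX

Per-variant Fⱼ = γ̂ⱼ²/σ²_Xj; the reported mean F̄ is their unweighted
arithmetic mean. Cochran's Q on the exposure associations,
Q_GX = Σ (γ̂ⱼ − γ̄)²/σ²_Xj with γ̄ the precision-weighted mean, gives
I²GX = (Q_GX − (L−1))/Q_GX, truncated at 0 (standard I² convention; Q = 0
also returns 0). Truncated values are used everywhere, including when
averaging across simulation replicates. The weighted variant — appropriate
alongside a 1/σ²_Y-weighted Egger fit — applies the identical formula to the
transformed pairs (γ̂ⱼ/σ_Yj, σ_Xj/σ_Yj); when σ_Yj is constant the two
variants coincide exactly. I²GX is reported to 3 decimals.

The crude dilution correction β̂₁ᴱ/I²GX is provided but warns below
I²GX = 0.9: the I²GX estimate is noisy and can be at or near zero under weak
instruments (its sampling distribution at low F̄ has genuine mass at zero
for small L — `i2_sampling_experiment` quantifies this), making the ratio
unstable. SIMEX is the recommended adjustment in that regime.

## SIMEX

For each λ in the grid (default 0.5, 1, 1.5, 2) and b = 1…B (default 200;
100 inside the study harness for throughput), pseudo-exposure estimates
γ̂*ⱼᵇ = γ̂ⱼ + √λ · σ_Xj · Zⱼᵇ, Z iid N(0,1), raise the measurement-error
variance to (1+λ)σ²_Xj; outcome data and all SEs are unchanged. The Egger
fit is averaged over the B refits per λ, a polynomial (default quadratic;
linear available) is least-squares fitted to the averaged coefficients over
{0} ∪ grid — the λ = 0 anchor is the naive fit itself — and evaluated at
λ = −1, the no-measurement-error point. Intercept and slope are extrapolated
from the *same* pseudo-datasets so their negative correlation is preserved.

Standard errors use the Stefanski–Cook difference method: per λ, the mean
model-based coefficient variance v̄(λ) minus the empirical variance ê(λ) of
the B estimates is extrapolated to λ = −1 with the same family (anchored at
v̄(0) = naive variance, ê(0) = 0); a non-positive extrapolated variance
falls back to the naive model variance. Degenerate pseudo-designs (no spread
in γ̂*) are redrawn with bounded retries. If σ_X ≡ 0 the pseudo-data are
exact copies and the naive fit is returned unchanged — SIMEX is the identity
under exact NOME, which the tests assert bitwise. Identical (dataset,
config, seed) gives bit-identical output.

## Synthetic-data generator and calibration

`simulate_dataset` draws, independently per variant *and per dataset*,
σ_Xj ~ U(sx_low, sx_high), γⱼ ~ U(gamma_low, gamma_high),
αⱼ ~ U(alpha_low, alpha_high), sets σ_Yj = 2σ_Xj (same allele frequency,
different cohort sizes; the multiplier is configurable), and then samples
(γ̂ⱼ, Γ̂ⱼ) from the model above. Redrawing γ and α freshly each dataset makes
instrument strength independent of direct effects by construction (the
sample correlation between γ and α averages to zero — asserted by a property
test). The five pleiotropy scenarios fix (alpha_low, alpha_high, β):
balanced/negative/positive pleiotropy with β = 1, positive pleiotropy with
β = 0, and the fully null case. The latent (γⱼ, αⱼ, β) are returned as a
`SimTruth` record so tests can regress Γ̂ on the *true* γ and recover β and
mean(α) as an oracle.

`calibrate` chooses the uniform bounds to hit a target (F̄, I²GX) via the
moment equations

    I²GX  = σ²_γ / (σ²_γ + s²),        s² = 1/E[1/σ²_X] = sx_low · sx_high,
    F̄     = 1 + (σ²_γ + μ²_γ) · E[1/σ²_X],

with σ²_γ = (gamma_high − gamma_low)²/12 and μ_γ the midpoint. The effective
error variance is the precision-weighted (harmonic) uniform moment, not the
arithmetic E[σ²_X]: both the Q_GX statistic and the 1/σ²_X-weighted
regression weight each variant by its precision, so the dilution they
experience is governed by 1/E[1/σ²_X]. Two equations leave two free
conventions, fixed once:

* `sx_ratio` = sx_high/sx_low = 2 — a factor-2 spread of exposure SEs,
  representing realistic allele-frequency heterogeneity;
* the overall scale, pinned by the asymptotic IVW bias under directional
  pleiotropy: E[β̂IVW] ≈ β(F̄−1)/F̄ + ᾱ · μ_γ E[1/σ²_X]/F̄, and the multiplier
  μ_γ E[1/σ²_X]/F̄ is set to `ivw_bias_factor` = 2.1, i.e. mean pleiotropy
  ᾱ = 0.1 displaces IVW by ≈ 0.21.

Feasibility: positive bounds with gamma_low ≥ 0 require
F̄ ≥ 1 + 4·I²/(1−I²); e.g. I²GX = 0.95 is unattainable at F̄ = 5 and
`calibrate` raises a `CalibrationError`. The achieved mean F is within ~2%
of target (Monte-Carlo checked); the mean *estimated* I²GX equals the target
at strong instruments but is biased downward at low F̄ (≈ 0.56 at target
0.60 with F̄ = 20, L = 25) — that bias is a finding of the method, not a
calibration error, and `verify_calibration` reports it.

## Study harness conventions

`run_study` analyses every replicate with IVW, Egger, truncated unweighted
I²GX and optionally SIMEX, and reports means, rejection rates at α = 0.05
and Monte-Carlo SEs. Two defaults differ deliberately from the
observed-data `egger()` defaults:

* **No per-replicate re-orientation.** The generator enforces the positive
  coding convention at the *parameter* level (gamma_low ≥ 0), so the data
  are already correctly coded; flipping on the noisy sign of γ̂ⱼ would
  introduce a selection effect exactly in the weak-instrument regime under
  study.
* **Unweighted Egger.** With weights 1/σ²_Y ∝ 1/σ²_X, the weighted fit's
  dilution factor is the harmonic-moment ratio, which sits systematically
  above the truncated I²GX estimate in finite samples; the unweighted fit's
  dilution (arithmetic-moment ratio) tracks the mean I²GX estimate, which is
  the attenuation identity (mean slope ≈ β × mean Î²GX) the harness is built
  to exhibit, and matches the reference performance grid.

Both are exposed (`weighted=`, `orient=`) for sensitivity analysis. Each
(scenario, target) cell gets an independent seed substream and each
replicate an independent child stream, so results are reproducible and
order-independent given the seed.

## Numerical choices and problem sizes

* Straight-line WLS/OLS fits are closed-form on sufficient statistics
  (vectorised over SIMEX pseudo-replicates); statsmodels is the independent
  oracle in tests, agreement ≤ 1e−10 relative.
* Degenerate inputs: zero exposure effect → degenerate-instrument error for
  ratio/IVW; zero spread in γ̂ → singular-design error for Egger; Q_GX = 0 →
  I²GX = 0; I²GX ≤ 0 → crude correction refuses.
* se_exposure = 0 is allowed in memory (exact NOME, the SIMEX identity
  case) but rejected in input files.
* Default study sizes follow the reference conditions: L = 25 variants,
  5000 replicates per cell (SIMEX cells use B = 100). The acceptance script
  runs 5000 replicates per cell throughout, including the SIMEX cell, where
  the adjusted slope's replicate SD (≈ 0.5 at I²GX = 0.75 — quadratic
  extrapolation amplifies noise) makes smaller runs too imprecise for a
  ±0.03 comparison.

## What the generator does and does not emulate

It emulates the idealised two-sample setting: normal summary estimates with
known SEs, uncorrelated variants, InSIDE satisfied, continuous-trait scale
on both axes. It does not emulate LD between variants, InSIDE violations
(pleiotropy through confounders), allele-frequency-driven correlation
between σ_X and γ, sample overlap between the two GWAS, binary-outcome
effects, or winner's-curse selection of instruments. Passing simulation
tests therefore demonstrate the estimators' behaviour under the stated
model, not robustness to those real-data complications; on real data the
I²GX diagnostic conflates NOME and InSIDE problems and should be read as a
necessary, not sufficient, check.

## Known limitations

* The calibration's two free conventions are a reconstruction; with them,
  one corner of the reference grid (the weak-instrument, lowest-I²GX slope
  cell) is reproduced only to ~0.02 rather than ~0.01.
* The weighted-I²GX transform assumes the same 1/σ²_Y weights as the Egger
  fit; other weighting schemes would need a matching transform.
* SIMEX variance estimation is asymptotic; with very small L or B the
  fallback to the naive variance can under-cover.
* No plotting beyond what users build from the returned DataFrames.
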