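# mrnome

Two-sample summary-data Mendelian randomization (MR) with instrument-strength
diagnostics for MR-Egger regression and SIMEX correction of regression
dilution.

## The problem

Two-sample MR estimates the causal effect β of an exposure on an outcome from
per-variant GWAS summary statistics: SNP-exposure associations γ̂ⱼ (SE σ_Xj)
from one study and SNP-outcome associations Γ̂ⱼ (SE σ_Yj) from another, for L
uncorrelated variants, under the model

    γ̂ⱼ ~ N(γⱼ, σ²_Xj),    Γ̂ⱼ ~ N(αⱼ + β γⱼ, σ²_Yj),

where αⱼ is the pleiotropic (direct) effect of variant j.

* **IVW** combines the ratio estimates Γ̂ⱼ/γ̂ⱼ with weights wⱼ = γ̂ⱼ²/σ²_Yj
  (equivalently the zero-intercept weighted regression of Γ̂ on γ̂); it is
  unbiased only when pleiotropy is absent or balanced.
* **MR-Egger** regresses Γ̂ⱼ = β₀ᴱ + β₁ᴱ γ̂ⱼ with a free intercept: β₀ᴱ
  estimates the average directional pleiotropy and β₁ᴱ the causal effect
  under the InSIDE assumption.

Both treat γ̂ⱼ as exact (the NO-Measurement-Error, NOME, assumption). When
NOME fails, the MR-Egger slope suffers classical regression dilution:
E[β̂₁ᴱ] ≈ β · σ²_γ / (σ²_γ + s²), with s² the average error variance of the
exposure associations. The retention fraction is estimated by

    I²GX = (Q_GX − (L − 1)) / Q_GX,   Q_GX = Σⱼ (γ̂ⱼ − γ̄)² / σ²_Xj,

truncated at 0 (γ̄ is the 1/σ²_Xj-weighted mean). I²GX = 0.9 means ~10%
expected attenuation — the MR-Egger analogue of the per-variant F = γ̂ⱼ²/σ²_Xj
rule of thumb. The package provides I²GX (unweighted and weighted variants),
the crude correction β̂₁ᴱ/I²GX, and **SIMEX**: re-estimate under successively
inflated measurement error (variance multiplier 1+λ), model the coefficient
trend in λ, and extrapolate to λ = −1. A calibrated simulation engine
generates synthetic two-sample datasets whose mean F statistic and true I²GX
hit requested targets, plus a Monte-Carlo harness for bias/size/power grids.

Intended users: statistical geneticists and epidemiologists running two-sample
MR sensitivity analyses, and methodologists studying weak-instrument
behaviour of summary-data estimators.

## Worked example

Generate a synthetic dataset with strong instruments (mean F ≈ 125, true
I²GX = 0.95) and analyse it:

```
$ mrnome simulate --scenario 1 --fbar 125 --i2 0.95 --seed 7 --out example.tsv
$ mrnome analyze example.tsv --simex --simex-b 200 --seed 7

mrnome analyze: example.tsv (25 variants)

Model                       Parameter        Est        SE   t-value     p-value
IVW                         beta          0.9027    0.0663     13.61     8.9e-13
MR-Egger (weighted)         beta_0E       0.1279    0.0692      1.85      0.0775
MR-Egger (weighted)         beta_1E       0.6168    0.1672      3.69     0.00121
MR-Egger (unweighted)       beta_0E       0.1227    0.0746      1.65       0.113
MR-Egger (unweighted)       beta_1E       0.6031    0.1745      3.46     0.00215
MR-Egger + SIMEX            beta_0E       0.1145    0.0726      1.58       0.128
MR-Egger + SIMEX            beta_1E       0.6524    0.1760      3.71     0.00116

mean F statistic: 113.3
I2GX (unweighted): 0.941   (Q_GX = 405.60)
I2GX (weighted):   0.945   (Q_GX = 434.90)
```

Reading the output: the true causal effect in this scenario is β = 1 with
balanced pleiotropy. IVW (0.90 ± 0.07) is close to the truth; the MR-Egger
slope for this particular draw is lower (0.62) with a much wider interval —
the usual power cost of freeing the intercept — and I²GX ≈ 0.94 says
regression dilution accounts for only ~6% attenuation on average, so SIMEX
moves the slope up modestly (0.62 → 0.65). The intercept test (p ≈ 0.08)
does not indicate directional pleiotropy, consistent with the balanced
generating model. With weak instruments the report adds a caution, e.g.

```
I2GX (unweighted): 0.461   (Q_GX = 44.55)
WARNING: I2GX = 0.461 < 0.90 - the MR-Egger causal estimate is attenuated by
regression dilution; interpret with caution and consider SIMEX adjustment.
```

The same analysis is available as a library:

```python
import mrnome

d = mrnome.read_summary_tsv("example.tsv")
d = mrnome.orient_exposure_positive(d)
print(mrnome.ivw(d).estimate, mrnome.egger(d).slope.estimate)
print(mrnome.i2_gx(d), mrnome.i2_gx(d, weighted=True))
```

Performance grids (mean estimates and rejection rates over thousands of
simulated datasets, per scenario and per (mean F, I²GX) target) come from
`mrnome.run_study` or `mrnome study --fbar 125 --i2 0.95,0.75 --reps 5000
--seed 1 --out grid.tsv`.

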