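# lgmsens

Sensitivity analysis for latent growth models under missing data.

Longitudinal studies in education and psychology almost always lose
participants — through permanent attrition, through skipped measurement
waves, and through item non-response. Whether the estimated change over time
survives those losses depends on the unverifiable mechanism behind them:
missing completely at random (MCAR), missing at random given observed data
(MAR), or missing not at random (MNAR, where the unobserved change itself
drives the dropout). `lgmsens` lets an applied researcher fit one linear
latent growth model under **eight missing-data techniques spanning all three
assumptions** and then tells them, parameter by parameter, how far the
techniques agree and how to report the result.

## The model

For subject *i* at wave *t* with slope loading λ_t (years; λ₁ = 0):

```
y_it = I_i + λ_t S_i + ε_it,   (I_i, S_i) ~ N((μ_I, μ_S), Ψ),   ε_it ~ N(0, θ_t)
```

The implied moments over waves are E[y_t] = μ_I + λ_t μ_S and
Cov(y_t, y_s) = ψ_II + λ_t λ_s ψ_SS + (λ_t + λ_s) ψ_IS + [t = s] θ_t. The
reported parameters are the mean intercept μ_I, mean slope μ_S, intercept
variance ψ_II, slope variance ψ_SS and intercept–slope covariance ψ_IS.

The eight techniques:

| assumption | techniques |
|---|---|
| MCAR | **LD** — listwise deletion (complete cases only) |
| MAR | **ML** — full-information maximum likelihood (FIML); **MI** — joint-normal multiple imputation with Rubin's-rules pooling (m = 100 by default); **MLaux** / **MIaux** — the same with auxiliary variables (saturated correlates / in the imputation model) |
| MNAR | pattern-mixture models with shared Ψ and Θ across dropout strata: **H&G** — two groups (completers vs non-completers); **Neighbouring** / **Available** (and opt-in **Complete**) — three dropout strata with the last stratum's slope fixed by an identifying restriction |

Around the fits: Little's MCAR chi-square test (via EM for the incomplete
multivariate normal), per-wave *t*-test screens, dropout-group ANOVA with
Tukey HSD, and an auxiliary-variable screen (Nagelkerke R² for predicting
missingness, OLS R² for the outcome, |r| ≥ .10 counts).

A synthetic-data module generates three-wave cohorts with known growth
parameters and controllable MCAR/MAR/MNAR dropout, including a preset that
emulates a 1072-student cohort measured at loadings (0, 1.17, 2.17) with
~21% complete trajectories, so every stage is testable against known truth.

## Worked example

```python
import lgmsens as L

params, scenario, n, times = L.study_emulation_preset()
ds, latent = L.simulate_growth(n, times, params, seed=1)
masked, _ = L.impose_missingness(ds, scenario, latent=latent, seed=2)
masked.aux = L.generate_auxiliaries(latent, ["aux1", "aux2"],
                                    rho_intercept=0.3, seed=3)

res = L.little_mcar_test(masked)
print(f"chi2={res.chi2:.3f} df={res.df} p={res.p:.3f}")
# chi2=7.374 df=9 p=0.598

spec = L.GrowthSpec(wave_times=tuple(times), cov_IS_free=False)
summary = L.run_sensitivity(
    masked, spec,
    config=L.SensitivityConfig(m=20, burn_in=200, thin=20, seed=4))
print(L.render_report(summary, "text"))
```

```
Sensitivity analysis: growth estimates by missing-data technique

parameter       mean_intercept       mean_slope intercept_variance  slope_variance
technique
LD            3.235 (0.055)***   -0.048 (0.025)   0.382 (0.050)***   0.023 (0.016)
ML            3.259 (0.026)***  -0.042 (0.020)*   0.409 (0.032)***   0.024 (0.013)
MI            3.263 (0.027)***   -0.045 (0.026)   0.407 (0.034)***   0.023 (0.014)
MLaux         3.258 (0.026)***  -0.042 (0.020)*   0.409 (0.032)***   0.023 (0.013)
MIaux         3.262 (0.027)***   -0.046 (0.023)   0.407 (0.030)***  0.027 (0.013)*
H&G           3.257 (0.026)***   -0.023 (0.029)   0.410 (0.032)***   0.024 (0.013)
Neighbouring  3.255 (0.026)***    0.021 (0.038)   0.410 (0.032)***   0.024 (0.013)
Available     3.255 (0.026)***   -0.010 (0.025)   0.410 (0.032)***   0.024 (0.013)

Agreement classification
  mean_intercept: =
    option 2: MAR models in detail; Add: Not contradicted by MNAR.
  ...
```

Each cell is "estimate (SE)" with `*** p < .001, ** p < .01, * p < .05`.
Here the data were generated MCAR, and Little's test (p = .60) and the
classification agree: the mean intercept is estimated around 3.26 by every
technique (the generating value was 3.28), LD pays for discarding 80% of
the sample with a doubled standard error, and the classifier labels the
parameters as concordant (option 2: report the MAR models, note that the
MNAR models do not contradict them). When the techniques disagree, the
classifier instead flags option 1 (MAR- and MNAR-class results diverge:
present both and choose cautiously) or option 3 (ML alone diverges from MI,
MLaux, MIaux and the MNAR class: prefer the latter).

The same pipeline runs from the shell:

```bash
lgmsens simulate --out cohort.csv --seed 1
lgmsens diagnose --data cohort.csv
lgmsens sensitivity --data cohort.csv --m 100 --seed 1 --out report.csv
```

Real datasets enter through `read_wide_csv` (one row per subject, one
outcome column per wave, optional auxiliary and dropout-group columns;
empty cells or a configurable token mark missing values).
`scripts/replicate.py` applies the whole workflow to the three deposited
learning-strategy scale files when placed under `data/`.

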