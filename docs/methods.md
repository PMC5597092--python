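# Methods

## Model and estimands

The analysis model throughout is the linear latent growth curve for T waves
of a bounded (1–5) subscale score:

y_it = I_i + λ_t S_i + ε_it, with (I_i, S_i) bivariate normal with mean
(μ_I, μ_S) and covariance Ψ = [[ψ_II, ψ_IS], [ψ_IS, ψ_SS]], and independent
normal residuals ε_it with variance θ_t. Loadings λ are fixed design
constants in years; the default three-wave design uses (0, 1.17, 2.17) —
a 14-month and then a 12-month gap expressed in units of 12 months
(14/12 rounded to 1.17). The implied moments are μ(λ) = μ_I + λ μ_S and
Σ(λ) = Λ Ψ Λᵀ + Θ with Λ = [1, λ].

The estimands reported by every technique are μ_I, μ_S, ψ_II, ψ_SS and
(when freed) ψ_IS. Residual variances are per-wave free by default, which
matches common SEM-software defaults; a homogeneous option exists. When a
fitted covariance row is not wanted (the common convention of fixing ψ_IS
to zero unless both variances are significant), `GrowthSpec(cov_IS_free=
False)` removes the parameter rather than leaving it silently at a bound.

## Likelihood machinery

All maximum-likelihood routes share one engine. Subjects are grouped by
missingness pattern; each pattern contributes its count, observed-variable
mean and scatter matrix, so one likelihood evaluation costs O(#patterns ×
T³) regardless of n:

ℓ = Σ_j −(n_j/2) [ p_j log 2π + log|Σ_Oj| + tr(Σ_Oj⁻¹ S_j) + (ȳ_j − μ_Oj)ᵀ Σ_Oj⁻¹ (ȳ_j − μ_Oj) ].

This is exactly the sum of per-subject normal log-densities on observed
sub-vectors (FIML); a non-positive-definite observed submatrix during the
search returns a large penalty instead of crashing. Optimization is
L-BFGS-B with variances bounded below at 1e-8, three deterministic restarts
from moment-based starts jittered by fixed factors (×1, ×0.85, ×1.2), best
log-likelihood winning with ties to the first. Standard errors come from
the observed information: a central finite-difference Hessian with step
1e-5·max(|θ|, 1), inverted (pseudo-inverse with a warning if singular).
Inference uses normal-theory z statistics, consistent with SEM convention.
Note that SEs for variance parameters estimated at or near the lower bound
are reported but not trustworthy — the usual boundary caveat.

Listwise deletion is the same fit restricted to complete cases
(equivalently FIML on the complete-case subset; the equality is asserted in
tests to 1e-6).

### Auxiliary variables (MLaux)

FIML with auxiliaries uses the saturated-correlates device: the joint
vector (y, aux) is modelled as one multivariate normal in which the outcome
block keeps the growth structure while the auxiliary means, the auxiliary
covariance block (parameterized by its Cholesky factor to keep it PD) and
all outcome–auxiliary cross-covariances are free. The growth parameters and
their SEs are read off the joint fit; the saturated block is nuisance.
Categorical auxiliaries are dummy-coded (first level dropped); a
zero-variance auxiliary is a configuration error, and more auxiliaries than
a third of the complete cases triggers a warning (a common rule of thumb
for stable auxiliary sets).

## EM and Little's MCAR test

The unstructured incomplete-data normal is estimated by EM on the same
pattern-grouped sufficient statistics. Start: complete-case moments,
falling back to available-case means/variances with zero covariances.
Convergence: relative observed-data log-likelihood change below 1e-10, cap
5000 iterations; the log-likelihood trace is retained and its monotonicity
asserted in tests. Non-convergence flags the result rather than failing
silently.

Little's statistic compares pattern means with the EM grand means on the EM
covariance: χ² = Σ_j n_j (ȳ_j − μ̂_Oj)ᵀ Σ̂_Oj⁻¹ (ȳ_j − μ̂_Oj), df = Σ_j p_j −
T, upper-tail chi-square p. Complete data give χ² = 0 with df = 0. A
singular pattern submatrix falls back to a pseudo-inverse with a warning.
The test's type-I error is verified by simulation (1000 MCAR replicates at
n = 300 must reject at .05 between 3% and 7% of the time). The per-variable
t-test screen (observed-vs-missing groups, Welch) is reported for
inspection only; Little's test is the gating diagnostic.

## Multiple imputation

Imputation is joint-normal data augmentation with a Jeffreys-style
noninformative prior. I-step: missing sub-vectors drawn from their
conditional normal given observed cells and current (μ, Σ), vectorized per
pattern. P-step: Σ ~ inverse-Wishart(n − 1, S) with S the completed-data
scatter, then μ ~ N(ȳ, Σ/n). Defaults m = 100, burn-in 500, thinning 100;
m follows the tutorial analysis this package generalizes, burn-in/thinning
are conservative choices for a 3–6 dimensional chain (the sampler mixes in
far fewer iterations; the defaults simply make the kept datasets
effectively independent). Observed cells are never altered (asserted
bitwise). Plain MI imputes from the outcome waves alone; MIaux adds the
(dummy-coded) auxiliaries to the imputation model only — the analysis model
never changes, and imputed auxiliary values are used unrounded.

Each completed dataset gets the complete-data ML growth fit; non-convergent
fits are excluded from pooling with a warning. Rubin's rules: Q̄ = mean
estimate, W = mean squared SE, B = between-imputation variance (ddof 1),
T = W + (1 + 1/m)B, ν = (m − 1)(1 + W/((1 + 1/m)B))², p from t(ν). The
classical ν is used (no small-sample correction) — with n ≈ 1000 and
m = 100 the difference is negligible; B = 0 degrades gracefully to the
normal reference.

## Pattern-mixture models

Subjects are stratified by dropout pattern: from an administrative
enrolment label when available (preferred, since wave non-response is not
attrition; the cross-tabulation of the two sources is logged), otherwise by
last observed wave. The growth model is fitted as a multigroup FIML problem
with group-specific latent means and a single shared Ψ/Θ block — the
under-identified strata borrow their variance structure from the strata
that can estimate it.

* Two-group model: completers vs non-completers, both latent means free per
  group.
* Three-group restriction models: the last stratum (observed essentially
  only at wave 1) has its mean slope substituted inside the likelihood —
  not penalized — by the restriction expression: group 1's slope
  (complete-case), group 2's (neighbouring-case), or the size-weighted
  average of groups 1–2 (available-case). Reparameterization makes the
  constraint exact at the solution (asserted to 1e-10). The complete-case
  restriction requires an explicit opt-in flag: borrowing completers'
  growth for the earliest dropouts is rarely defensible when dropout is
  suspected to be outcome-related.

Pooling: population parameters are the stratum-proportion-weighted averages
θ̄ = Σ_g π_g θ_g (machine-exact by construction). The delta-method variance
combines the full parameter covariance from the joint fit (so the
correlation induced by shared variances and by the restriction itself is
carried through the gradients) with the multinomial variance of the
estimated proportions, C_gg = π_g(1 − π_g)/N, C_gh = −π_g π_h/N. The
standalone `pool_pattern_mixture` helper also accepts fixed weights
(dropping the multinomial term) and a diagonal-variance mode for
independently fitted groups.

## Synthetic data and the study-emulation preset

The generator draws (I, S) from the bivariate normal, adds independent
residuals, and returns the latent record on a separate channel from the
dataset handed to estimators — estimators can never see it, oracle tests
always can. Missingness is layered on the complete data:

* monotone attrition — per-wave logistic hazard given survival, with the
  linear predictor logit(h_t) + β z, where z is the standardized mechanism
  predictor: nothing (MCAR, β = 0), the last observed earlier score (MAR),
  the latent slope or the value being deleted (MNAR), or an auxiliary
  column;
* intermittent wave non-response — an independent Bernoulli overlay;
* wave-1 non-response — applied only to subjects observed later, so every
  subject keeps ≥ 1 observed wave.

A deletion log records every removed cell with its cause and linear
predictor, and is asserted to agree exactly with the mask. Auxiliary
covariates are standard normal with a chosen correlation to the latent
intercept and/or slope.

The study-emulation preset encodes the cohort shape the package was built
around: N = 1072 students, loadings (0, 1.17, 2.17), growth parameters near
the memorizing-scale ML solution (μ_I = 3.28, μ_S = −0.06, ψ_II = 0.41,
ψ_SS = 0.02, ψ_IS = 0, θ = 0.27), MCAR mechanism. The attrition and
non-response rates were solved once from the observed response margins
(1029/442/278 of 1072 observed per wave; 225 complete; 43 wave-1
non-respondents who returned later) under the mixed model above:
with intermittent rates i₂ = i₃ = 0.08,

* P(obs₂) = (1 − h₂)(1 − i₂) = 442/1072 ⇒ h₂ = 0.552,
* P(obs₃) = (1 − h₂)(1 − h₃)(1 − i₃) = 278/1072 ⇒ h₃ = 0.371,
* wave-1 non-response 43 / E[#later-observed] ≈ 0.093,

giving an expected complete-case fraction of ≈ 0.22 (the empirical 20-draw
mean is checked against the band 0.18–0.26, which brackets the cohort's
observed 225/1072 = 0.21). What the generator does **not** emulate:
bounded 1–5 Likert scores (draws are unbounded normal), item-level
non-response, non-normal latent distributions, and any genuine MAR/MNAR
structure in the preset (its mechanism is MCAR by construction). Passing
tests on preset data therefore demonstrate estimator correctness under the
model's own assumptions, not robustness to the distributional quirks of
real rating scales.

## Agreement classification

Classification is a pure function of the assembled (estimate, SE, p) table.
Significance is judged at α (default .05, strict inequality; stars at
.05/.01/.001); p in [α, .10] is flagged "at the verge" but counted as not
significant. Per parameter:

* option 3 — ML's significance differs from the shared verdict of the other
  MAR-class techniques (MI, MLaux, MIaux) *and* the MNAR class: report both
  classes, prefer the concordant majority;
* option 1 — otherwise, the MAR class and the MNAR class each agree
  internally but disagree with each other: present both, choose cautiously;
* option 2 — otherwise (the classes agree): report the MAR models in
  detail and note the MNAR models do not contradict them.

The category "=" additionally requires every technique (including LD) to
agree in significance with all pairwise 95% CIs overlapping; otherwise the
raw significance pattern is printed so three-way splits are never forced
into a single verdict. LD is flagged separately when its 95% CI excludes
the ML estimate — the signature of MCAR failure at the first wave.
Option 3 is checked before option 1 because an ML-only divergence would
otherwise masquerade as a class-level split.

## Numerical and design notes

* Deterministic behaviour everywhere: EM starts from complete-case moments,
  the optimizer's restarts use fixed jitter factors, and every stochastic
  operation takes an explicit integer seed (the orchestrator derives
  sub-seeds for MI by fixed offsets from its master seed). Reports render
  byte-identically for identical inputs.
* Degenerate inputs: subjects observed at no wave are excluded with a
  logged count on ingest; a zero-variance auxiliary, an empty dropout
  stratum, or a stratum that cannot identify its free slope each raise a
  named error; perfect separation in the auxiliary screen reports the
  Nagelkerke R² at its upper limit with a flag.
* Problem sizes in the test battery were chosen to give the simulations
  clear resolution at desk scale: 200 replicates at n = 1000 for parameter
  recovery, 200 at n = 600 for the listwise-deletion bias direction, 1000
  at n = 300 for the MCAR test's type-I calibration, 100 at n = 800 for the
  MNAR divergence direction, and 20 preset draws for the complete-case
  band.

## Known limitations

* Growth is linear with normal latents and residuals; no fit indices
  (CFI/RMSEA), robust (sandwich) SEs, categorical outcomes, or selection
  models (Heckman/Diggle–Kenward) — the MNAR family here is pattern-mixture
  only, and latent-class pattern mixtures for unlabeled dropout are out of
  scope.
* Wald inference on variance parameters near zero is unreliable
  (boundary); the slope-variance verdicts should be read with that in
  mind.
* The imputation model is joint normal; chained equations and predictive
  mean matching are not provided, so heavily non-normal auxiliaries enter
  at some cost.
* Subscale scores are taken as given: the upstream rule that a wave's score
  exists only when all its items were answered is documented, not
  implemented (item-level data are outside the package's inputs).
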