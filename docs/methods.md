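# Methods

This note documents the statistical procedures implemented in
`lifespan`, the choices made where the methodology is genuinely open,
and what the synthetic-data tests do and do not establish.

## Abridged life tables

Life expectancy at birth e₀ is computed from age-grouped deaths Dᵢ and
person-years PYᵢ on the 19-interval abridged schedule
(<1, 1–4, sixteen 5-year intervals, 85+). Person-years come from
census-style population counts multiplied by the study length in years
(default 5). The construction is the adjusted Chiang II method:

- central rate mᵢ = Dᵢ/PYᵢ; an empty stratum (0 deaths, 0 exposure) is
  treated as rate 0 rather than undefined, and deaths with zero exposure
  raise an error rather than producing an infinite rate;
- qᵢ = nᵢmᵢ/(1 + nᵢ(1 − aᵢ)mᵢ) for closed intervals, clamped to 1 when
  extreme inputs push it above 1 (later survival is then zero); q = 1 in
  the open interval;
- survivorship, deaths, person-years lived, and remaining expectation by
  the standard recursions, with L = l/m in the open interval. A tract
  whose survivors reach the open interval with zero tail rate raises a
  degenerate-tail error — no rate floor is substituted, because any
  floor would silently fabricate an e₀.

**Interval-lived fractions.** aᵢ = 0.5 everywhere by default (deaths
spread evenly within intervals). Demographic practice often uses a
smaller infant fraction (deaths in the first year of life cluster early);
`build_default_age_schedule(infant_a=0.1)` supports this, but the even
default is the package's baseline assumption.

**Radix** is 100 000; the radix cancels in e₀ and enters the variance
only as a normalizer.

**Variance of e₀.** Closed intervals contribute binomially,
Var(qᵢ) = qᵢ²(1 − qᵢ)/Dᵢ (zero when Dᵢ = 0), weighted by
lᵢ²[(1 − aᵢ)nᵢ + eᵢ₊₁]². The open interval contributes
(l₈₅₊/l₀)²/(m² D): the delta-method variance of l/m when D is Poisson, a
final-interval adjustment without which the tail's sampling error is
ignored entirely. There is no single canonical printed formula for the
adjusted method's tail term, so the implementation is validated against
a 2000-replicate parametric bootstrap (resample Dᵢ ~ Poisson(Dᵢ),
recompute e₀): the analytic SE stays within ×[0.8, 1.25] of the
bootstrap SD on tracts with ≥ 200 deaths, and the √n scaling of the SE
is checked directly. Confidence intervals are normal, e₀ ± 1.96·SE; the
95% level is a convention, not a derived quantity.

**Reliability screening.** A tract is excluded when (a) total deaths
< 50, (b) total person-years < 5000, or (c) SE(e₀) > 2 years. The
inequalities are strict exactly as stated: 50 deaths, 5000 person-years
and SE = 2.0 all pass. All failed criteria are listed per tract; the
screen is a pure function of the estimate.

## Spatial weights

Queen contiguity: two tracts are neighbors when their polygon boundaries
share at least one point. Polygon inputs (GeoJSON) use an exact
intersects predicate via an STR-tree; a snapping buffer (default 0) is
available for shapefiles whose shared borders do not coincide exactly.
Lattice adjacency is also available directly by index arithmetic and is
tested to be identical to the polygon computation.

Weights are row-standardized, wᵢⱼ = 1/|N(i)|, so the spatial lag Wx is
the mean of neighbors' values. Islands (no neighbors) keep all-zero rows
and are reported; the pipeline drops them before estimation by default,
since a zero row has no meaningful place in the error process λWu.
Tract ordering is everywhere the canonical sort of tract identifiers.

Eigenvalues of W are computed on the symmetric similarity
D^{-1/2}AD^{-1/2} (A the binary adjacency, D the degree matrix), which
has the same spectrum as W and guarantees real eigenvalues; for a
connected graph they lie in (−1, 1] with largest exactly 1.

## Spatial Durbin error model

y = α + Xβ + WXθ + u with u = λWu + ε, ε ~ N(0, σ²I). With
A = I − λW, the Gaussian likelihood concentrates over (γ, σ²): γ̂(λ) is
the least-squares solution of Ay on AZ (Z = [1 | X | WX]),
σ̂²(λ) = RSS/n, and

ℓ(λ) = −(n/2)(ln 2π + 1 + ln σ̂²) + Σᵢ ln(1 − λωᵢ).

λ is maximized by bounded scalar search over (1/ω_min + 10⁻⁶, 1 − 10⁻⁶)
at tolerance 10⁻⁸ (admissibility of |A| > 0 for row-standardized W).
A fit whose λ̂ lands on the search boundary is flagged unconverged. A
perfect trend fit (RSS numerically zero) returns +∞ as a guard instead
of overflowing in ln σ̂².

Numerical choices and conventions:

- **Coefficient covariance** is σ̂²((AZ)ᵀAZ)⁻¹, conditional on λ̂. The
  λ–γ cross-information is asymptotically zero for error models, and
  conditioning matches the common ML-software convention; SE(λ̂) comes
  from the numerical curvature of the profile likelihood.
- **p-values** are two-sided standard-normal (ML asymptotics), starred
  at ≤ 0.05 / ≤ 0.01 / ≤ 0.001 (inclusive thresholds).
- **AIC** = 2(k + 2) − 2ℓ, counting the k regression coefficients plus
  λ and σ².
- **R²** is the squared Pearson correlation between y and the trend
  prediction Zγ̂. Several pseudo-R² definitions exist for spatial error
  models; this one is the most common and the definition is recorded in
  the JSON output.
- **Impacts:** direct = β, indirect = θ, total = β + θ, with no
  significance measure on totals (the covariance between β̂ₖ and θ̂ₖ is
  not propagated to the sum).
- **Model comparison:** likelihood-ratio statistic 2(ℓ_full − ℓ_nested)
  clamped at zero, χ² with df = difference in regression-column count;
  requires genuinely nested specifications on the same data.
- **Rank deficiency** (e.g. a constant covariate, whose lag equals
  itself and collides with the intercept) raises an error naming the
  problem rather than silently pseudo-inverting.

The estimator verifies two exact reductions in tests: with λ fixed at 0
and no lag block it reproduces closed-form least squares to 10⁻⁸, and at
the fitted λ̂ its coefficients solve the corresponding GLS problem with
covariance [(I − λ̂W)ᵀ(I − λ̂W)]⁻¹ computed independently.

## Diagnostics

**Collinearity.** VIFₖ = 1/(1 − R²ₖ) from regressing covariate k on the
others plus an intercept; the default flags are VIF > 10 and pairwise
Pearson |r| > 0.7. Flags are advisory only: the pipeline never
auto-drops a covariate, because which member of a correlated pair to
keep is an analyst's judgement (the config's `excluded_covariates` list
records that choice).

**Moran's I.** I = (n/S₀)(eᵀWe)/(eᵀe) on mean-centered values, with
E[I] = −1/(n − 1) under the null. The default test is a seeded
two-sided permutation test (999 permutations). The two-sided comparison
is centered at E[I] — a permuted |I| is counted as extreme when
|I_perm − E[I]| ≥ |I_obs − E[I]| — because the permutation-null
distribution is centered at E[I], not at zero; this is what keeps the
test's size at its nominal level (verified at 1000 replicates against
99% binomial bounds). A normal approximation under randomization is
available as an alternative. In the pipeline the test runs on the
whitened innovations ε̂ = (I − λ̂W)(y − Zγ̂): the trend residuals contain
the modeled λ-autocorrelation by construction, so testing them would
always "find" the autocorrelation the model already accounts for.

**Residual checks** (advisory, never blocking): the skewness/kurtosis
omnibus normality test and a fitted-value-on-squared-residual slope
test for heteroscedasticity; constant residual vectors are flagged
degenerate and skipped.

## Pipeline

Stages: load CSVs and neighbor structure (GeoJSON polygons or GAL file)
→ person-years → life tables → SEs → reliability screen (or the
`--no-filters` sensitivity mode that keeps every tract) → rebuild and
re-standardize W on the retained tracts → VIF screen → SDEM fit →
impacts → Moran's I on innovations → report files. The tract join is
an inner join on tract ID with orphan counts logged. W is rebuilt on
the retained subset (neighbors lost to filtering are dropped, remaining
rows re-standardized) rather than sliced from the full matrix, which
preserves the row-stochastic contract. Tracts with missing covariates
are dropped with a logged count; no imputation. All outputs are
deterministic given the config and seed, byte for byte.

## Synthetic data

The generator emulates the statistical structure of a tract-level
mortality study on a rows × cols lattice:

- **Covariates**: xⱼ = (I − ρₓW)⁻¹ηⱼ with iid standard-normal η,
  standardized to mean 0 / variance 1 (default ρₓ = 0.4, mild positive
  spatial autocorrelation of the kind social indicators show).
- **Outcome (direct mode)**: drawn from the exact SDEM equation with
  chosen (α, β, θ, λ, σ). The default truth used across the recovery
  material is α = 80.75 years (a realistic tract-level LE intercept),
  β = (1.0, −0.5), θ = (0.3, 0.0), λ = 0.5, σ = 1 — strong but plausible
  effect sizes against a years-scale outcome.
- **Outcome (mechanistic mode)**: e₀ computed from simulated mortality,
  exercising the full chain at the cost of attenuated, nonlinear
  covariate effects. Direct mode is the default because it separates
  estimator correctness from life-table sampling noise.
- **Mortality**: Gompertz baseline m(age) = a·exp(b·age) with
  a = 5·10⁻⁵, b = 0.085 (adult doubling time ≈ 8 years, e₀ ≈ 80 years —
  a contemporary US-like schedule), scaled per tract by exp(xᵀδ);
  person-years from a fixed age-pyramid share vector × base population
  (default 4000 per tract) × 5 study years; deaths Poisson. The open
  interval's rate is evaluated at age 90. The pyramid is a fixture
  constant, not a demographic claim.

Named fixtures: `tiny` (5×5, base population 12 000 so every simulated
tract clears the screen), `recovery` (30×30 with the truth above), and
`filterable` (6×6 whose last six tracts are engineered deterministically:
one failing each screening criterion with a single reason, and one
sitting exactly on each boundary — 50 deaths, 5000 person-years,
SE = 2.0 — which must be retained). The engineered tracts put all deaths
in the open interval with integer per-interval populations, so their SEs
and person-year totals are exact to the last bit through the CSV
round-trip.

**What passing tests show, and what they do not.** The generator
matches the model's assumptions exactly (Gaussian errors, correct
functional form, exogenous covariates, clean topology). Recovery and
calibration results therefore establish correctness of the estimator
and variance formulas, not robustness to the things real vital-statistics
data add: geocoding error, census denominator error, migration,
non-Gaussian outcomes, misspecified neighborhood structure, and
covariate measurement error. Problem sizes were chosen desk-scale: 900
tracts for recovery (50 replicates), 225 for model-selection
simulations (100 power / 500 size replicates), 100 for Moran
calibration (1000 replicates × 999 permutations).

## Known limitations

- The SDEM is local-spillover by design; global-spillover models
  (spatial lag of y) are out of scope, as are GMM estimation and
  heteroscedasticity-robust standard errors.
- The open-interval variance term is delta-method, validated by
  bootstrap rather than derived from a canonical reference.
- No small-area smoothing: tracts that fail the screen are dropped, not
  stabilized by borrowing strength.
- Significance of the lagged coefficients uses the same conditional-on-λ̂
  covariance as the direct ones; this is a convention choice.
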