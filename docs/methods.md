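# Methods

## The estimation problem

Radiation protection extrapolates the risk of low-dose and protracted
exposures from acute, mostly high-dose, observations using the dose and
dose-rate effectiveness factor (DDREF). Under a linear-quadratic (LQ) dose
response, excess risk is α·D + β·D², the quadratic term is attenuated by
fractionation (β·D²/fractions for a dose split into fractions separated by
enough time for repair), and

DDREF(D) = 1 + (β/α)·D,  with DDREF at 1 Gy ≈ DDREF_LSS.

This package fits that model to stratified animal lifespan data and profiles
the shared ratio θ = β/α. Critically, θ can be identified from two distinct
signals: the *curvature* of acute dose response within strata, and the
*direct contrast* between acute and protracted exposures at the same total
dose. The LQ model asserts these must agree; the package's headline
likelihood-ratio contrast tests exactly that.

## Group-level regression

The outcome is inverse mean lifespan, y = 1/mean(lifespan), a mortality
proxy that is exact when mortality follows a Gompertz law (hazard rising
exponentially with age) and the log-hazard shift is small. Each treatment
group contributes one observation with delta-method variance
Var(y) = SEM²/mean⁴ and weight 1/Var(y). Weights live on the outcome scale:
"inverse variance in lifespan" is implemented as the inverse variance of
*inverse mean lifespan*, because that is the regression outcome.

At each candidate θ, every stratum is refit by weighted least squares of y
on x = D + θ·D²/fractions with a free intercept and slope α_s (so
β_s = θ·α_s exactly), and the exact weighted-Gaussian log-likelihood

Σ_g [ −½·log(2π·v_g) − ½·w_g·ε_g² ]

is summed over all groups. The per-group variances are treated as known.
Because only likelihood *differences* across θ matter for profiling, any
variant of this likelihood differing by data-only constants produces the
same profile. One consequence of the known-variance form is worth noting:
multiplying every variance by a common constant preserves the profile's
argmax and ordering but rescales likelihood differences, so interval widths
are calibrated in the variances' absolute units. The delta-method variances
provide that calibration; the empirical coverage checks below confirm it.

## Grid and intervals

θ is profiled over a grid uniform in u = DDREF/(1+DDREF) ∈ [0, 1]
(401 points by default), so DDREF 0 (θ = −1) and DDREF ∞ are exact
endpoints. The u = 1 endpoint is fitted as the pure-quadratic model: the
covariate becomes D²/fractions and the slope is β itself with α = 0.

The 95% credible interval is all grid points within 1.92 log-likelihood
units of the maximum — 1.92 = χ²₁(0.95)/2, the standard profile-likelihood
construction. (The source phrase "within 1.92 fold of the likelihood" is
interpreted as a 1.92 log-unit drop; a literal 1.92-fold likelihood ratio
would be an ~80% interval and does not correspond to any conventional
level.) Ties at the maximum resolve to the lowest DDREF — conservative
toward a smaller protraction benefit. When the ∞ endpoint is inside the
cut set the interval reports +∞.

## Positivity constraints (hormetic correction)

Some strata show hormesis — exposed animals outliving controls — which makes
DDREF paradoxical (the same θ then predicts protraction is *less
beneficial*). The hormetic variant restricts α_s ≥ 0 and β_s ≥ 0. Since
β = θ·α, a finite θ < 0 makes every α > 0 infeasible, so the feasible set
collapses to the boundary α = 0, implemented as an intercept-only fit (the
weighted mean of y) rather than rejecting those grid points — the profile
stays defined on the whole grid. A negative unconstrained slope likewise
collapses to the boundary, flagged on the returned fit.

## Heterogeneity correction

Within-group sampling variance understates the real variation between
treatment groups (husbandry, dosimetry drift — whole-group effects). The
between-group variance τ² is estimated by the DerSimonian–Laird
method-of-moments estimator for weighted meta-regression:

τ² = max(0, (Q − (n − df)) / (tr(W) − tr(W·X·(XᵀWX)⁻¹·XᵀW)))

with Q = Σ(ε/σ)², W = V⁻¹, and X the stacked design (one intercept and one
effective-dose column per stratum, evaluated at the stage-1 profile
maximum). Q referred to χ²(n − df) is Cochran's evidence test. Every group
variance is then inflated to σ² + τ² and the profile is rerun with the new
weights. τ² is estimated once, from the stage-1 fit at its own profile
maximum, not re-estimated per grid point — mirroring the two-stage "fit,
estimate random effects, rerun" description of the procedure. The
positivity constraints stay on in this variant (it builds on the hormetic
correction), and the by-study variant is identical except that study joins
the stratification key.

## Survival variant

With individual records available, mortality is modelled directly: a Cox
proportional-hazards model with baseline hazard stratified by analysis
stratum (risk sets never cross strata),

h_i(t) = h_s(t) · exp( α_s·(D_i + θ·D_i²/fractions_i) + Z_g ),

with α_s ≥ 0 and Z_g a group-level random effect. Z enters the log-hazard
additively (standard Gaussian frailty) rather than inside the α_s
multiplier: a multiplicative placement makes Z's scale depend on α_s and is
not estimable when α_s = 0. Ties use Breslow's approximation by default
(exactly matched by small-sample enumeration oracles); Efron's is available
behind an option flag.

For fixed θ and frailty variance σ_Z², the per-stratum coefficients and
group effects jointly maximize the Gaussian-penalized partial likelihood
(L-BFGS-B with nonnegativity bounds on α). σ_Z² is chosen to maximize the
Laplace-approximate integrated likelihood,

ℓ_m(σ²) = pl(ẑ) − |ẑ|²/2σ² − (q/2)·log σ² − ½·log det(H + I/σ²),

with H the analytic Hessian of the negative partial likelihood in the group
effects. When profiling θ, σ_Z² is estimated once at a preliminary θ (the
no-frailty profile argmax) and held fixed across the grid — the same
two-stage treatment as τ² in the regression variant; re-estimating per grid
point was considered and rejected as it multiplies runtime ~tenfold for
estimates that barely move. The 1.92-unit rule is applied to the profiled
integrated partial likelihood.

## Data rules

The inclusion cascade applies, in order: individual data available,
external exposure, low-LET whole-body, total dose ≤ 1.5 Gy (= 1.5 Sv for
low-LET radiation), no other treatments, and at least three distinct
treatment groups per stratum (an LQ model needs three points). Controls
(dose 0) pass the exposure-quality steps regardless of their labels and are
classified acute. The three-group minimum is re-applied after *every*
subsetting operation, not only at ingest.

Subsets: *acute* keeps single-fraction groups (a fraction being any dose
delivered in one hour or less); *comparison* keeps whole strata that
contain at least one acute non-zero-dose group and at least one protracted
group. The by-study variant adds study to the stratum key before the
three-group rule, which silently drops control groups shared across studies
— the expected behavior, since such controls have no within-study
comparators. How shared controls were originally assigned to pooled strata
is not derivable from group keys alone; the package groups purely by the
key fields.

## Synthetic cohorts

The simulator draws lifespans from a Gompertz law whose log-hazard is
shifted by the LQ effective dose:

h(t) = a·e^{bt} · exp( α_s·(D + θ·D²/F) + Z_g ),  Z_g ~ N(0, σ_RE²),

sampled exactly by inverse transform of the closed-form survival function.
Defaults: a = 1e-7/day, b = 0.013/day (median control lifespan ≈ 878 days,
mortality-rate doubling time ≈ 53 days — a realistic laboratory mouse
colony) and α = 0.3 per effective Gy (≈ 23 days of life lost per Gy, in the
range reported for low-LET mouse lifespan studies). The standard design is
6 strata × 5 groups: control, acute 0.75 and 1.5 Gy, and 1.5 Gy delivered
in 10 and in 60 fractions — the same-total-dose multi-schedule structure
through which the archives actually probe protraction. The 16-stratum
archive-shaped fixture (4 strata with protracted exposures, 12 acute-only,
sizes ~100–7000) is generated deterministically from a seed.

The α default deserves a note: inverse mean lifespan is a *first-order*
mortality proxy. Its convexity in the log-hazard shift leaks a small
positive bias into θ̂ that grows with the effect size (about +0.1 at these
settings, versus ±0.3 recovery tolerance). The default effect size was
chosen to be realistic *and* inside the proxy's near-linear regime; with
much larger per-Gy effects the group-level regression would systematically
overstate curvature — a property of the method itself, not of the
implementation, and one reason the survival variant exists.

What the simulator does **not** emulate: cause-of-death attribution,
age-dependent radiosensitivity over a fractionation course, time-varying
dose rates, inter-animal frailty beyond the group level, and real archives'
ragged dose designs. Passing recovery and coverage tests therefore show the
estimator is correct *under the model's own assumptions*, not that the LQ
model describes real archive data — the package's contrast machinery exists
precisely to test the latter.

## Operating characteristics

`scripts/acceptance.py --seed N --out results/acceptance.json` recomputes,
from scratch at each run: recovery of θ = 1 within ±0.3 across 50 simulated
cohorts (6 strata × 5 groups × 500 animals); coverage of the 1.92-unit
interval across 200 cohorts at θ = 0.5 (200 animals/group, sized to keep
the study fast at unchanged calibration); overlap of acute- and
comparison-subset intervals and the LRT false-positive rate across 50 null
(θ = 0) cohorts with three comparison-capable and three acute-only strata;
the constructed contradiction instance — exactly linear acute response,
exactly null protracted response — which drives the comparison subset to
the infinite-DDREF endpoint while the acute subset stays at DDREF 1; flat
(dose-independent) data yielding a flat profile with a (0, ∞) interval and
a hormetic stratum collapsing to the α = 0 boundary; and maximum deviations
from three independent oracles (dense normal equations, explicit
hat-matrix algebra for τ², exhaustive enumeration of the Breslow partial
likelihood on ≤ 8 subjects).

## Numerical notes and limitations

- WLS fits use closed-form two-parameter normal equations; a constant
  effective-dose covariate raises a rank-deficiency error naming the
  stratum.
- Likelihood ties at the profile maximum are broken toward the lowest
  DDREF; the tie tolerance is 1e-9 log-units.
- The LRT contrast compares disjoint strata partitions (strata with vs
  without protracted exposures), so the H0 profile is the pointwise sum of
  the two curves; a flat (unidentified) partition degenerates to p = 1 with
  a warning. In null calibration the test runs slightly hot (~8% at nominal
  5%) from grid discretization and boundary effects; it is used here as
  strong-evidence screening (the archive-data contrast is p < 0.01), not as
  an exact-level test.
- Frailty variance search is bounded to σ_Z² ∈ [1e-6, 4] on the log scale
  with Brent's method; Laplace integration uses the analytic z-block
  Hessian.
- Group observations with undefined variance (n = 1 or all lifespans equal)
  are excluded from the regression with a warning; they cannot carry a
  finite weight.
- Censoring is supported throughout (Kaplan–Meier risk sets, Cox partial
  likelihood, an administrative-censoring age in the simulator) but is off
  by default: the archives record deaths.
- Doses are in Gy, lifespans in days; 1 Gy = 1 Sv for the low-LET radiation
  this package covers. High-LET and internal-emitter dosimetry are out of
  scope, as is any Bayesian combination of profile likelihoods across data
  sources.
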