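# Methods

This note records the models implemented in `hekie`, the assumptions behind
them, the numerical and statistical choices made where the design was open,
and what the synthetic-data pipeline does and does not establish.

## Kinetic and biophysical models

All closed-form models live in `hekie.models` as pure functions; the fitting
layer, the simulator and the data generators all call the same code.

**Units.** Substrate concentrations are mM, protein concentrations µM, rates
s⁻¹, catalytic efficiencies M⁻¹ s⁻¹, energies J mol⁻¹. These conventions are
fixed because reported kinetic tables conventionally mix them (K_M in mM,
k_cat/K_M in M⁻¹ s⁻¹): every conversion happens inside a named operation
(`catalytic_efficiency`, `absorbance_to_conc`), never implicitly.
Thermodynamic expressions always take kelvin internally; `as_kelvin` converts
from Celsius under an explicit unit tag, since melts are recorded in °C and
Eyring profiles in K.

**Consecutive-step lag model.** Product formed through two sequential
irreversible first-order steps is

P(t) = ES/(k₂−k₃)·[k₂(1−e^{−k₃t}) − k₃(1−e^{−k₂t})],

the standard solution of A→B→C kinetics. It is symmetric under exchange of
k₂ and k₃ (only the *set* of rate constants is identifiable, not their
order), has zero value and zero slope at t = 0 (the lag), and tends to ES.
Some sources print this expression with a summed denominator; that variant
fails both limiting behaviours (it tends to ES·(k₂−k₃)/(k₂+k₃) rather than
ES), so the difference-denominator form is used and verified against direct
numerical integration of the underlying rate equations. When
|k₂−k₃| < 10⁻⁶·max(k₂,k₃) the expression is a numerically catastrophic 0/0
and the code switches to the analytic equal-rate limit
ES·[1−(1+kt)e^{−kt}] with k the mean rate; the switch is continuous to
~10⁻⁶·ES.

**Tight-binding titration.** Holoenzyme concentration is the smaller root of
(G−c)(Z−c) = K_D·c. Discriminant values in [−10⁻¹²·(G+Z+K_D)², 0) are clamped
to zero (floating-point noise exactly at the stoichiometric point); anything
more negative raises, since it indicates corrupted inputs rather than
round-off. The titration rate model is identically V_max·c/G, and this
identity is property-tested.

**MMRT.** The temperature–rate model is the Eyring expression extended with
an activation heat capacity ΔC_P‡ that makes ln(k_cat/T) curved; ΔH‡ and ΔS‡
are quoted at a reference temperature T₀ = 298 K which is fixed, never
fitted (it is a reparameterisation point, not a physical parameter). With
ΔC_P‡ = 0 the expression reduces exactly to the linear Eyring plot, which is
what makes the nested F-test below meaningful. Physical constants are CODATA
(k_B/h = 2.0837×10¹⁰ K⁻¹ s⁻¹).

## Fitting

Estimators follow the scikit-learn protocol (`fit`/`predict`,
`get_params`/`set_params`, fitted attributes with trailing underscores) on
top of `scipy.optimize.least_squares` (trust-region reflective, box bounds
keeping rate-like parameters positive, xtol = ftol = gtol = 10⁻¹²).

* **Unweighted least squares by default.** With no stated weighting scheme,
  ordinary LS is the convention under which the reported "fitting error" is
  the standard error from the scaled covariance: SE = √(diag((JᵀJ)⁻¹)·RSS/dof),
  computed via SVD with a rank threshold so singular Jacobians are flagged
  rather than silently inverted.
* **Pooled replicates.** Replicate measurements enter one fit as separate
  points (the fitted line goes through all shown points); replicates are
  never averaged first.
* **Initial guesses** are per-model heuristics (documented on each
  estimator): max-ordinate/half-max abscissa for saturation and titration,
  percentile baselines and midpoint crossing for melts, a log-gap regression
  on the 50–90% rise window for the slower rate of the lag model, the linear
  Eyring fit as the seed for MMRT.
* **Restart ladder.** On non-convergence the initial guess is perturbed by
  the deterministic multiplicative ladder (1, 0.5, 2, 0.25, 4) — reproducible
  without random seeds in the fit path. If no attempt converges, the result
  is returned with `converged=False` and the solver message; fitting never
  raises for non-convergence.
* **Model comparison.** Non-nested candidates (lag vs single-exponential)
  are ranked by AICc; nested pairs (linear Eyring inside MMRT) use the
  extra-sum-of-squares F-test at α = 0.05, so the curved model must earn its
  extra parameter.
* **HE-KIE statistics.** The ratio SE is first-order quadrature propagation
  assuming independent numerator/denominator errors (validated against
  10⁵-draw Monte Carlo to within 5% of SE at the relevant CVs). Row
  significance is a two-sided Welch t-test with Welch–Satterthwaite degrees
  of freedom built from each fit's residual dof; the flag threshold is fixed
  at p < 0.01. How to assign dof to a pooled fit of duplicate experiments is
  genuinely underdetermined — per-replicate fits of duplicates would be
  underpowered — so the Welch construction on fit dof is a declared package
  choice, and worked examples on published-style estimates use dof = 16 (a
  7-concentration duplicate design minus two fitted parameters); the
  significance pattern is insensitive to any dof ≳ 8. No multiple-testing
  correction is applied across isotopologue rows (panels are conventionally
  reported with per-row tests); this is deliberate and documented.

## Mechanistic simulator

The catalytic cycle is modelled as four irreversible first-order steps:
Michaelis-complex isomerisation (k_iso), chemistry including fast
pyrophosphate release (k_chem), product-complex isomerisation (k_prod_iso,
the mass-sensitive step, divided by φ ≥ 1), and diffusional product release
(k_off, the viscosity-sensitive step, divided by η_rel ≥ 1). Substrate
binding is collapsed to rapid equilibrium (consistent with a rapid
equilibrium random bisubstrate mechanism at saturating co-substrate), and a
pyrophosphatase couple justifies full irreversibility. The observable counts
all product-containing states, bound and free, because the chromophore
exists from the chemical step onward — a stated convention.

Because the network is linear, the default propagator is the matrix
exponential, which is exact for this class of system (cached per unique time
step, so uniform grids cost one `expm`). A stiff BDF integration at
rtol 10⁻⁸ / atol 10⁻¹² is retained as `method="bdf"` and cross-checked
against the exact propagator in the tests; the exact route is preferred
because rate constants spanning ≥4 orders of magnitude make the problem stiff
and the expm solution sidesteps tolerance tuning entirely.

Three identities tie the simulator to the closed forms and are enforced in
tests: (1) the single-turnover observable equals the consecutive-step model
with k₂ = k_iso, k₃ = k_chem (the post-chemistry steps only redistribute
signal among chromophore-bearing states); (2) steady-state k_cat is the
harmonic combination 1/Σ(1/kᵢ) of the effective rates and matches the
asymptotic multiple-turnover slope; (3) the k_cat-ratio-vs-η_rel line is
exactly linear with slope equal to the fraction of turnover time spent in
the release step — which is why a slope of 1 diagnoses rate-determining
diffusion and a slope of 0 excludes it, and why a diffusion-limited cycle
masks the HE-KIE (bounded in [1, φ], reaching φ only when the mass-sensitive
step carries the full turnover time).

Absolute values of k_prod_iso and k_off are not constrained by published
tables; they are free simulator inputs. The bundled
`vibration_limited_scheme` (30, 8, 6, 72 s⁻¹) gives k_cat ≈ 2.9 s⁻¹ with the
product isomerisation slowest and a near-zero viscosity slope, and
`diffusion_limited_scheme` (1000, 1500, 600, 11 s⁻¹) gives k_cat ≈ 10 s⁻¹
dominated by release — cold- and warm-regime archetypes respectively.

## Synthetic data

Generators add Gaussian noise to the ordinate only, in three flavours:
`relative` (homoscedastic, σ × max signal — the "2% of max rate" convention
used for saturation data), `absolute` (instrument units, e.g. 0.002–0.003 AU
for stopped-flow traces, ~2% of the 0.144 AU full-scale signal), and
`proportional` (per-point σ × signal, used for temperature profiles so the
ln(k_cat/T) transform stays homoscedastic). Default magnitudes are 2%
(saturation, melts, viscosity), 3% (titrations, temperature profiles) —
plausible replicate scatter for these assay types. Defaults are seeded and
byte-reproducible.

Designs mirror the real assay geometry: two replicates; a two-fold dilution
ladder to 1.6 mM substrate; HisZ titration to 0.5 µM at G = 0.04 µM; melts
scanned 25–93 °C at 1 °C resolution; profiles 278–318 K in 5 K steps;
stopped-flow traces with 0.5 cm path, ε₂₉₀ = 3600 M⁻¹ cm⁻¹ and a 0.9 ms dead
time, with pre-dead-time samples dropped rather than extrapolated, so
fitters must handle truncated lags.

Not emulated: baseline drift, photobleaching, mixing artifacts,
heteroscedasticity beyond the proportional option, or correlated replicate
errors. Passing recovery tests therefore demonstrates correctness of the
estimators under the assumed error model, not robustness to instrument
pathologies.

The glycerol %(v/v) → η_rel table bundled in `pipeline.GLYCEROL_ETA_REL` is
an approximate, literature-shaped synthetic stand-in (the calibrated
conversion is instrument- and buffer-specific); η_rel is therefore a
required input column, and the table is an overridable convenience only.

## Analysis pipeline decisions

* Saturation analysis refuses designs with fewer than five distinct
  substrate concentrations; viscosity analysis refuses fewer than three
  distinct viscosities (slope dof ≥ 2) and requires the η_rel = 1 reference.
* Viscosity classification uses the 95% CI of the slope: diffusion-limited
  if it includes 1 and excludes 0; viscosity-insensitive if it includes 0
  and excludes 1; otherwise partial/ambiguous.
* The lag model exposes both a floated completion amplitude (default) and a
  fixed-amplitude mode (`fix_amplitude`), since either convention is
  defensible when the enzyme-complex concentration is known; fixing the
  amplitude removes its uncertainty from the covariance.
* Temperatures are Celsius at the CLI and in melt files, kelvin in profile
  files, always tagged.

## Problem sizes and tolerances used in the test suite

Exact-data inversion is asserted to 10⁻⁶ relative for every model.
Coverage of the reported standard errors uses 200 seeded replicates per
model with a ≥90% criterion on the (estimate ± 2·SE) interval per parameter.
Simulator/closed-form agreement is checked on 100 random log-uniform schemes
(rates 0.5–500 s⁻¹) at ≤10⁻⁶ relative to the amplitude, and harmonic-sum
k_cat against asymptotic slopes to 1%. Model-selection behaviour is checked
over 10 seeded profiles per scenario, allowing the ~5% false-positive rate
inherent to the α = 0.05 F-test. The full suite runs in well under a minute.

## Known limitations

* All steps irreversible and binding collapsed: the simulator cannot
  represent product rebinding, reverse chemistry, or substrate-binding
  limited single-turnover rates (relevant when measured k_STO rises with
  enzyme concentration, which indicates a bimolecular contribution).
* The error model is Gaussian and uncorrelated; fitted SEs inherit those
  assumptions.
* Ratio propagation is first-order; it is accurate for CVs below ~10% and
  degrades for noisier estimates.
* The HE-KIE masking analysis assumes exactly one mass-sensitive step; a
  cycle with several would need the perturbation hooks generalised.
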