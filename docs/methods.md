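# Methods

`sletherm` correlates the temperature dependence of saturation mole-fraction
solubility of a crystalline solute in pure solvents. It implements three
model families on a shared data model, plus a synthetic-data generator and a
descriptor-correlation utility. This note records the science, the numerical
choices, and the limits of what the test suite demonstrates.

## Data model and conventions

A dataset is an ordered series of (T, x) points for one solute/solvent pair:
absolute temperature in kelvin, solute mole fraction at saturation
(dimensionless, natural scale), optional absolute uncertainty on x. Celsius
input is rejected, never converted; silent unit conversion is the classic
failure mode in this domain. Mole fractions printed in the 10³·x convention
must be divided down before loading — the built-in dataset transcription
does this once, at the source.

The gas constant R = 8.31446 J mol⁻¹ K⁻¹ is defined in one module and
imported everywhere, so regression slopes, ideal solubility and the SLE
right-hand side cannot disagree on it.

Component indexing for the activity models is fixed package-wide:
component 1 is the solute, component 2 the solvent. Published binary
Wilson/NRTL equations appear in both index conventions (and occasionally
typographically garbled); this package uses the standard literature forms
written out below, and always applies the *solute* activity coefficient in
the equilibrium condition.

## Modified van't Hoff analysis

With u = 1/T − 1/T_hm and T_hm = n / Σ(1/Tᵢ) the mean harmonic temperature
of the measurement grid, ordinary least squares of ln x on u gives the
apparent dissolution functions

    ΔH_sol = −R · slope,   ΔG_sol = −R · T_hm · intercept,
    ΔS_sol = (ΔH_sol − ΔG_sol) / T_hm.

"Apparent" means activity-uncorrected: these are properties of the observed
saturation curve, not of an ideal dissolution process. Choices that matter:

* **T_hm from the union of all experimental temperatures** in a
  multi-solvent study (identical grids here), so every solvent is referenced
  to the same temperature.
* **Unweighted OLS.** The per-point uncertainties are roughly proportional
  to x (~1–3 % relative), so weighting in log space would be nearly uniform
  anyway.
* Centring on 1/T_hm makes the slope — and therefore ΔH_sol, and by the
  algebra of the centred line also ΔS_sol — invariant to the choice of
  T_hm; only ΔG_sol tracks the reference temperature. The entropy identity
  is enforced to 1e-9 relative on every result object.

The entropy of fusion is derived from DSC values as ΔS_fus = ΔH_fus / T_m.
For the built-in solute (T_m = 410.15 K, ΔH_fus = 121 300 J mol⁻¹) this
gives 295.7 J K⁻¹ mol⁻¹, agreeing with the rounded literature value
(295.5) to 0.1 %.

## Modified Apelblat correlation

    ln x = A + B/T + C·ln T

is linear in (A, B, C) given ln x, so the fit is initialised by an exact
linear least-squares solve and then polished by Levenberg–Marquardt under
the configured objective. The default objective stays in log space,
Σ(ln x_calc − ln x_exp)²; `objective="relative"` minimises
Σ((x_calc − x_exp)/x_exp)² instead. For deviations of a few percent the two
are nearly identical; both are provided because reported correlations in
this literature rarely state their loss.

The parameters are deliberately unbounded: both sign patterns of (A, B, C)
occur in practice, and strong A↔C trade-offs mean that *predictions*, not
parameter values, are the meaningful recovery criterion. Goodness of fit is
summarised by the average relative deviation,

    ARD% = (100/N) · Σ |x_calc,i − x_exp,i| / x_exp,i.

A caution learned from the built-in dataset: published Apelblat parameter
tables can sit far from the converged optimum (a stalled B near its
initial value is a recognisable signature). A converged refit can
therefore legitimately produce a *smaller* ARD% than originally reported
for the same data — for the ethanol series here, 2.6 % against a reported
5.3 %. The package reports its own converged values and makes no attempt to
reproduce stalled fits.

## Activity-coefficient models and the SLE solve

Below the melting point, saturation satisfies

    ln(x·γ₁(x, T)) = (ΔH_fus/R) · (1/T_m − 1/T),

with constant ΔH_fus (no ΔCp correction — consistent with how such data are
conventionally correlated, and untestable from solubility data alone). With
γ₁ ≡ 1 this yields the ideal solubility, capped at x = 1 at and above T_m.

Binary Wilson model (Λᵢⱼ = exp(aᵢⱼ + bᵢⱼ/T) > 0 by construction):

    ln γ₁ = −ln(x₁ + Λ₁₂x₂) + x₂·[Λ₁₂/(x₁ + Λ₁₂x₂) − Λ₂₁/(x₂ + Λ₂₁x₁)]

Binary NRTL model (τᵢⱼ = aᵢⱼ + bᵢⱼ/T, Gᵢⱼ = exp(−σ·τᵢⱼ)):

    ln γ₁ = x₂²·[τ₂₁(G₂₁/(x₁ + x₂G₂₁))² + τ₁₂G₁₂/(x₂ + x₁G₁₂)²]

The companion γ₂ forms are implemented as well, so thermodynamic
consistency (Gibbs–Duhem) is testable by finite differences. The
non-randomness parameter σ is held at 0.3 during regression — the
conventional choice for solubility work — but is exposed as a constructor
argument, range-checked to the meaningful 0.2–0.47 interval; treating σ as
a third adjustable parameter is possible but changes the model class and is
not done by default.

**Root solve.** The equilibrium is implicit in x. It is solved per
temperature on ln x (solubilities span 1e-5–1e-2; log-domain bracketing is
robust): a damped fixed-point iteration ln x ← rhs − ln γ₁(x, T) first —
for dilute systems γ₁ barely depends on x, so this converges in a handful
of iterations — with a bracketed Brent solve on [−700, 0) as fallback. A
fixed point pinned at the clamp boundary is rejected rather than reported
as a root. Converged solutions satisfy |ln(xγ) − rhs| < 1e-10; an
unbracketable equation (possible in extreme parameter corners) is reported
through a `converged=False` flag, never an exception. Gamma evaluations use
scalar `math` arithmetic: regression makes ~1e5 calls on 7-point series,
where small-array numpy overhead costs two orders of magnitude.

**Parameter regression.** (a₁₂, b₁₂, a₂₁, b₂₁) minimise
Σ((x_calc − x_exp)/x_exp)², x_calc from the SLE solve at each experimental
temperature. The landscape has genuine local minima, so a bounded
trust-region least-squares run is restarted from (i) the origin, (ii) a
fixed 2⁴ coarse grid over the sign patterns (a₁₂ ∈ {−15, 0},
b₁₂ ∈ {0, 5000}, a₂₁ ∈ {0, 10}, b₂₁ ∈ {−5000, 0}), and (iii) 16 seeded
uniform random points by default; the best objective wins. The
deterministic grid makes the outcome effectively seed-independent on the
built-in data. Bounds |a| ≤ 40, |b| ≤ 15 000 K keep the exponentials finite
while comfortably covering parameter magnitudes seen in this class of
system; `x_scale = (1, 1000, 1, 1000)` handles the a/b scale split. Failed
SLE solves inside the objective contribute a large flat penalty (99 per
point) so the optimiser retreats from pathological regions. The grid starts
can be disabled (`grid_starts=False`) for replicate studies, where a zero
start plus a couple of random starts suffices to land in the
data-supported basin.

As with the Apelblat fits, a converged multistart regression can out-fit
originally reported correlations: on the built-in data the Wilson results
match the reported per-solvent ARD% closely (mean 1.33 vs 1.30), while the
NRTL optimum (mean ARD ≈ 1.2 %) is substantially better than the reported
2.44 % — the reported NRTL parameters do not reproduce their own data when
evaluated through the standard binary NRTL forms, so the original NRTL
regression evidently stalled. The package again reports its converged
values.

## Synthetic data

The generator emulates the regime of the built-in study: seven temperatures
on the 288.2–318.2 K grid, mole fractions 1e-5–1e-2, and multiplicative
log-normal noise x_obs = x_model·exp(ε), ε ~ N(0, noise_cv), defaulting to
noise_cv = 0.02 to match the ~2 % relative uncertainty typical of
shake-flask/HPLC saturation measurements. Noise is multiplicative because
measured uncertainties scale with x; additive noise would distort the
small-x solvents. Any of the four model families can generate; the ground
truth (parameters, seed, noise level, noise-free curve) is returned as a
sidecar.

What the generator does *not* emulate: temperature-correlated errors,
solvent impurity effects, polymorph transitions, incomplete equilibration,
or model misspecification (data generated from a Wilson curve are exactly
Wilson). Passing recovery tests therefore demonstrates the correctness of
the estimation machinery, not that real systems follow these models.

Recovery study sizes (package defaults, used by the test suite): noise-free
refits from each family must reproduce the generating curve to below
0.01 % ARD; at noise_cv = 0.02, the median Wilson refit ARD over 200 seeded
replicates (light optimiser: zero start + 2 random starts) is compared
against the log-normal expectation E|exp(ε) − 1| ≈ noise_cv·√(2/π) ≈ 1.6 %,
within a factor of two — the fitted value sits below the expectation
because four parameters absorb part of the noise on seven points.

## Descriptor correlations

`correlate_descriptor` computes the Pearson correlation, across solvents,
between ln x at a reference temperature (default 298.2 K, the conventional
comparison point) and one named solvent descriptor (pKa, dielectric
constant, Hansen parameters, …). When a dataset lacks a point at the
reference temperature, ln x is interpolated linearly in 1/T, consistent
with its near-linear behaviour in reciprocal temperature. No descriptor
database ships with the package — values are user-supplied via a
`solvent,descriptor,value` CSV — so this module is a thin, well-tested
utility rather than an acceptance surface. For the built-in solute,
literature discussion reports |r| ≈ 0.96 between ln x in the alcohols and
solvent pKa (negative) and dielectric constant (positive); with a
user-supplied descriptor table the function reproduces this kind of
screening analysis.

## Known limitations

* Binary systems only; no mixed-solvent (ternary) Wilson/NRTL extension.
* The solute is treated as a single non-dissociating pseudo-component,
  although succinate salts can in principle dissociate.
* Apparent thermodynamics are not γ-corrected "true" dissolution functions.
* ΔCp of fusion is neglected in the ideal-solubility reference.
* Model selection between Wilson and NRTL on 7 points with 4 parameters is
  weakly identified; ARD% differences of a few tenths of a percent are not
  meaningful.
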