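# Methods

## Model

Disposition is a linear two-compartment model with an added saturable
(Michaelis–Menten) elimination acting on the central compartment,
driven by plasma concentration.  State is drug amount per kg body
weight (μg/kg) rather than concentration, so the saturable velocity —
a whole-body quantity in μg/day/kg — subtracts naturally; plasma
concentration is derived as C = A₁/V₁.  Dosing is an intravenous bolus
(A₁(0) = dose×10³ μg/kg); there is no absorption phase, no explicit
target binding/internalization states (the Michaelis–Menten term is the
quasi-steady-state reduction of target-mediated disposition), no FcRn
recycling mechanics, and no multiple dosing.

Canonical units: time in days, plasma concentration in μg/mL, rate
constants 1/day, central volume mL/kg.  Substrate concentrations for
cellular kinetics are canonically nM, with the μg/mL view derived from
the antibody molar mass.  Maximal velocities carry an explicit scale
tag (`per_assay_cells` vs `per_kg`); mixing scales raises instead of
silently computing.

With the saturable term absent the model is linear and C(t) is the
biexponential A·e^(−αt) + B·e^(−βt), with α+β = k₁₀+k₁₂+k₂₁ and
α·β = k₁₀·k₂₁.  This closed form is implemented separately from the
integrator and serves as an internal oracle: the ODE solution must
match it to rtol 10⁻⁶ whenever Vmax = 0.

## Numerical choices

* Integration: `solve_ivp` with LSODA, rtol 10⁻⁸ / atol 10⁻¹⁰.  The
  fast phase (t½ ≈ 25 min) against a 2-day horizon makes the system
  moderately stiff.
* The saturable term is evaluated as Vmax·C/(Km + |C|) so that the
  atol-scale negative overshoot the integrator can produce near C = 0
  does not create a derivative discontinuity (which stalls LSODA).
* In the joint in vivo fit, Km is bounded to [10⁻³, 10⁹] nM on the log
  scale: far below any physical antibody Km the saturable term
  degenerates toward a sign discontinuity at C = 0 and integration
  stalls.  The bound is four orders of magnitude away from any
  plausible estimate.
* Degenerate inputs: zero dose returns an all-zero profile; negative
  state amounts, nonpositive Km/molar mass, and non-increasing time
  grids are rejected with explicit errors.

## Estimation

All fits minimize Σ wᵢ(obsᵢ − predᵢ)² with wᵢ = 1/obsᵢ ("1/Y"
weighting, the usual reading of reciprocal-of-observed weighting in
commercial PK software); uniform weighting is available for
sensitivity analysis.  Reciprocal weighting requires strictly positive
observations, so zero/below-floor values are excluded before fitting.

Parameters are estimated on the log scale (positivity by construction)
with Levenberg–Marquardt (lmfit), multi-start: a deterministic
heuristic start — curve stripping (terminal log-linear fit for β/B,
residual fit for α/A, then the standard macro→micro identities) for
the 2-compartment model; (Km₀ = median S, Vmax₀ = max v) for the
saturable models — plus seeded log-uniform random restarts.  Ties
between converged starts break by lowest objective, then lowest
parameter-vector norm.

CV% is 100×SE/estimate from the linearized covariance at the optimum;
on the log scale SE(log p) is directly the relative SE of p.  The
covariance is scaled by reduced chi-square (the lmfit default, matching
commercial-tool convention), which has one consequence worth knowing:
on noise-free data every CV% is ~0 even for directions the data barely
constrain.  Identifiability warnings therefore also trigger on the
scale-invariant Km–Vmax correlation (|r| > 0.999) and, for the uptake
fit, on Km CV% > 100 (data far below saturation determine only
Vmax/Km).

The 2-compartment fit uses the mean profile across animals of the dose
group, not pooled individual points.  The joint all-dose nonlinear
refit fixes the linear parameters to the saturating-dose estimates by
default (`free_linear=True` refits all six) and reports Km/Vmax back on
the assay-cell scale via the inverse body scaling, so they are directly
comparable with the in vitro fit.

## Noncompartmental analysis

AUC(0–t) uses the linear-up/log-down trapezoid by default (log
trapezoid on strictly decreasing positive segments), with the plain
linear trapezoid retained for cross-checking.  λz comes from log-linear
regression over terminal suffixes of ≥3 points excluding Cmax,
selecting the suffix with maximal adjusted R² (mirroring common NCA
software defaults; a fixed `last_n` option exists).  Then
AUC(0–∞) = AUC(0–t) + C_last/λz, CL = dose/AUC(0–∞), Vd = CL/λz,
t½ = ln2/λz (reported in hours).  Results with >20% extrapolated AUC
are flagged.

## Body scaling (IVIVE)

The per-well in vitro Vmax is multiplied by the ratio of
target-expressing liver cells to assay cells, converted pmol→μg with
the antibody molar mass and min→day, and divided by body weight.  The
per-liver velocity is treated as the whole-animal velocity and divided
by body weight (not liver weight), because the target receptor is
essentially liver-restricted and the disposition model is written per
kg.  Defaults: 5×10⁵ assay cells, 7.6×10⁶ target-expressing cells per
liver, 148 kDa (the antibody's own molar/mass conversion implies
≈148 kDa; never stated directly), 0.020 kg (6-week male C57BL/6J; also
never stated).  All four are configurable.  No receptor-expression
correction is applied by default; an `expression_ratio` multiplier is
exposed, since expression differences between the assay cell line and
liver cells are a known, unquantified bias source.

## Synthetic data

The generator emulates the reference study design: doses 1, 3, 10, 30,
100 mg/kg; sampling at 5, 15, 30 min, 1, 2, 7 h, 1, 2 days; n = 3 per
dose; uptake assay at 12 log-spaced concentrations over 0.01–30 μg/mL,
15-min incubation, 3 replicates.  Residual noise is
multiplicative-lognormal (σ² = ln(1+cv²), median-unbiased, positive by
construction) with proportional CV 10% for plasma and 15% for uptake —
the source figures report only mean ± SD, so these are stated round
defaults, not inferred values.  A Gaussian proportional option exists.
Only residual-style noise is emulated: no inter-animal parameter
variability, no assay artifacts (nonspecific binding, wash
inefficiency, label decay).  Passing closed-loop tests therefore
demonstrates estimator/pipeline consistency under the model's own
assumptions, not robustness to model misspecification in real data.

A quantification floor is exposed (`lloq`, default off).  Closed-loop
and noise-robustness checks use 0.05 μg/mL — a realistic
electrochemiluminescence ligand-binding floor — so that comparisons
exclude points a real study could not report (the 1 mg/kg profile falls
below it within a day).

## The saturated-dose approximation

Fitting the linear model to a saturating-dose profile is an
approximation, not an identity: even at 100 mg/kg the saturable route
contributes, and its share of elimination *grows* as C falls toward Km
late in the profile.  Fed a profile generated *with* the saturable
term, the linear fit absorbs part of it (k₁₀ biased high ~14% under the
reference parameters) and late low-dose predictions degrade well beyond
the headline accuracy; the same mechanism shortens the apparent NCA
half-life of the full nonlinear profile (8.2 h vs the 10.8 h β-phase
value) and keeps NCA clearance at 30 vs 100 mg/kg about 20% apart
rather than indistinguishable.  Closed-loop recovery tests therefore
generate the anchor profile from the linear model (the saturated-limit
idealization); the bias of the real-data workflow is a property of the
method itself, visible in the package by fitting a
hybrid-simulated profile, and is the reason the workflow logs the
C(t)/Km ratio over the fit window.

## Problem sizes in the checks

Closed-loop and recovery checks use the full reference design (5 doses
× 8 times, 12-concentration assay).  The noise-robustness check pools
100 replicate studies at proportional CV 10% (plasma) / 15% (uptake);
the Monte-Carlo recovery check in the unit suite uses 40 replicates at
5% CV.  The acceptance script runs the identical computations and
finishes in well under a minute.

## Known limitations

* Single IV bolus only; no multiple dosing or subcutaneous absorption.
* The Michaelis–Menten reduction assumes fast target binding relative
  to disposition; a full TMDD model is out of scope.
* Equivalence with the commercial tools that produced the reference
  estimates is claimed only at the level of recovered parameters on
  synthetic data; their internal defaults are not public.
* Human extrapolation and interspecies allometry are out of scope.
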