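# Methods

This note documents the model chain, the synthetic study design, the
numerical choices, and the limits of what the tests demonstrate.

## Model chain

The package estimates daily canopy transpiration T_c (mm d⁻¹) for a
temperate deciduous broadleaf forest by coupling three classical
components under the two-leaf canopy representation, in which physiology
is computed for one representative sunlit and one representative shaded
leaf and scaled by the corresponding leaf areas.

**Radiation.** Half-hourly shortwave irradiance is converted to PAR with
the fixed factor 0.45.  The clearness index R = SW/(S₀ cos θ) drives a
quartic diffuse-fraction polynomial (clipped to [0.1, 1]; the default fit
exceeds 1 as R → 0 so the overcast limit is exactly all-diffuse).  Sunlit
leaf area follows the gap-probability form with clumping index Ω; the
shaded area is its exact complement.  Absorbed PAR per class combines the
direct beam term PAR_dir·cos β/cos θ (sunlit only; β = 60° is the
spherical leaf-angle proxy; the ratio is capped at 10 near the horizon)
with a scattered term shared by both classes: the canopy-trapped diffuse
flux (PAR_dif − PAR_dif,u)/LAI, where PAR_dif,u uses Beer extinction at a
representative diffuse zenith of 57.5°, plus a multiple-scattering
contribution C = 0.07 Ω PAR_dir (1.1 − 0.1 LAI) e^(−cos θ), floored at
zero.  All zenith-dependent quantities are evaluated at the native
half-hourly resolution and integrated to MJ m⁻² d⁻¹; computing them from
daily means would bias the sunlit/shaded split.  Because the C term
declines beyond LAI = 5.5 and reaches zero at LAI = 11, total absorption
is monotone in LAI only over the deciduous range (LAI ≲ 7); the package
targets canopies below that.

**GPP.** Each leaf class converts its absorbed PAR with a maximum
light-use efficiency (ε_msu for sunlit, ε_msh for shaded; bounds
0.34–1.50 and 2.71–4.79 gC MJ⁻¹) down-regulated by a linear VPD ramp
(open ≤ 0.65 kPa, closed ≥ 2.5 kPa by default) and the TEM temperature
scalar f = (T−T_min)(T−T_max)/[(T−T_min)(T−T_max) − (T−T_opt)²]
(defaults −1/25/40 °C), both evaluated on daytime means.  Defaults are
deciduous-broadleaf-like and config-exposed, since published threshold
sets vary and calibrated LUE magnitudes are conditional on them.

**Conductance and transpiration.** Daily GPP per class is converted back
to a mean daytime molar rate and enters the two-leaf Ball–Berry relation
with slopes g_su, g_sh (bounds 0–60) and intercept
G_s,min = 0.001 mol m⁻² s⁻¹.  The Penman–Monteith equation then uses:
FAO-56 psychrometrics (Tetens e_sat, linear λ(T), γ = C_p P/(0.622 λ),
ideal-gas air density); a neutral logarithmic-profile aerodynamic
conductance with d = 0.67 H, z₀ = 0.1 H (no stability correction; molar
units, converted through the molar density of air where m s⁻¹ is needed —
the G_a/G_s ratio is unit-free); canopy-allocated energy
A_c = FPAR·(R_n − G) integrated over daytime; the wet-canopy fraction
F_wet = 0 below RH 0.70 and RH⁴ above, applied to the whole numerator;
and the aerodynamic drying term integrated over the daytime duration.
The form is inverted algebraically for a reference G_s from observed T_c;
forward and inverse round-trip to better than 1e-10 relative.  Near the
energy-limited asymptote λE_max = numer/(s+γ) the sensitivity dT_c/dG_s
vanishes, so the inversion of a noisy T_c is unbounded there; an
asymptote-fraction guard (0.9 where the inversion feeds evaluation) flags
such days non-invertible.

## Calibration and the EGS/SEA experiment

Calibration is two-stage: (ε_msu, ε_msh) are fitted to observed daily GPP
first; with the fitted GPP components held fixed, (g_su, g_sh) are fitted
to observed transpiration through the forward Penman–Monteith model.
Fitting the slopes to inverted conductances is available as a mode but is
not the default: the inversion amplifies observation noise asymmetrically
(convex in λE), and at realistic noise the inverted reference correlates
negatively with the true conductance, driving slope estimates into the
bounds.  The default objective maximizes Willmott's agreement index
d = 1 − Σ(P−O)²/Σ(|P−Ō|+|O−Ō|)²; a minimize-RMSE mode exists (measured on
the synthetic experiment it performed slightly worse for T_c and was not
made default).

Each stage is a 2-parameter SCE-UA search: uniform initial population,
systematic deal into 4 complexes of 2n+1 points, competitive complex
evolution with triangular selection, reflection/contraction/random
replacement, shuffling, convergence when the best value improves by less
than a relative tolerance over 10 loops (defaults 3000 evaluations /
1e-6 for the repeated experiments; tighter settings for one-off
recovery runs).  The search is deterministic given a seed.  On a pooled
dataset the conductance objective forms a curved, nearly flat valley
(≈3e-7 objective change for a 1 % parameter move), so the independent
oracle used to verify the pooled optimum is exhaustive refined grid
enumeration polished by Nelder–Mead.

The EGS scheme fits one parameter quadruple to all growing-season days;
SEA fits one per season window.  Season windows come from the 25th/75th
percentiles of the multi-year daytime-temperature climatology (per
day-of-year mean, smoothed with a 15-day circular running mean so the
windows are contiguous): summer is the contiguous block above P75 around
the annual maximum, winter the days below P25, spring/autumn the warming
and cooling transitions.  The randomized experiment repeats a
season-stratified 70/30 split (|train| = round(0.7·n) per season), with
splits shared between schemes within an experiment so comparisons are
paired, and per-experiment random streams derived from the master seed by
index.  AIC = n·ln(SSE/n) + 2k (SSE floored at 1e-12) charges k = 2 per
stage for EGS and 6 for SEA, so the seasonal scheme pays for its extra
parameters; transpiration, inheriting both stages, is charged their sum.

## Synthetic study design

The generator emulates a DE-Hai-like site (51.08° N, canopy 23 m,
measurement 44 m, three years): sinusoidal annual (mean 8.5 °C,
half-amplitude 9.5 °C) and diurnal (±3 °C) temperature cycles with AR(1)
synoptic anomalies; clear-sky shortwave (transmittance 0.75) modulated by
AR(1) day-to-day cloudiness in (0.35, 1), which makes the clearness index
— hence the direct/diffuse split and the sunlit/shaded contrast — vary
realistically; dawn-peaked relative humidity with VPD tied to T and RH
through the saturation vapor pressure; a double-logistic LAI phenology
(max 6, green-up doy 120, senescence doy 290) sampled at 8-day steps with
FPAR = 1 − exp(−0.5·LAI), which keeps the FPAR-based and two-leaf APAR
directly comparable (their growing-season correlation exceeds 0.99).

The true parameters vary by season with contrasts of the size reported
for such forests — ε_msu 0.52/0.78/0.60 (summer/spring ratio 1.5),
ε_msh 3.35/4.10/4.75, g_su 11/9/10.5, g_sh 14/13/15.6 (autumn/summer
ratio ≈1.2) for spring/summer/autumn — chosen so the forward fluxes land
in observed ranges (daily GPP up to ~20 gC m⁻², T_c up to ~4.5 mm,
G_s ~0.1–0.5 mol m⁻² s⁻¹).  Winter days (foliage absent, fluxes ≈ 0)
borrow the nearest shoulder season's parameters.  Observation noise is
additive Gaussian at daily scale, homoscedastic, with sd 1.0 gC m⁻² d⁻¹
for GPP and 0.3 mm d⁻¹ for T_c — typical daily flux-partitioning
uncertainty.  ET is derived from T_c through a fixed canopy-development
ratio schedule T_c/ET = clip(0.5 + 0.4·LAI/LAI_max, 0.5, 0.9), giving the
underlying-water-use-efficiency partitioning step real signal.  Daily
observations are distributed back onto the half-hourly records
proportionally to shortwave, so daytime aggregation of the written
FLUXNET-style CSV reproduces the daily series exactly (mass-conserving).

Because the unclamped uWUE partition returns GPP·√VPD/uWUE_p regardless
of ET, no ET schedule can make the partition reproduce the forward-model
T_c exactly; the generator therefore provides daily observed T_c directly
(as real studies provide partitioning-derived T_c), and the uWUE method —
exact closed-form weighted-quantile slope at τ = 0.95, through the
origin — is validated on its own terms (exact on proportional series,
ratio clamped to [0, 1], cross-checked against an independent quantile
regression).

**What the synthetic world does not contain:** gaps and gap-filling
artifacts, energy-balance-closure error, u*-filtering, understory
evaporation entangled with transpiration in a weather-dependent way,
phenology–climate feedbacks, or model-structure error (the forward
simulator and the fitted model share one structure).  Passing recovery
tests therefore demonstrates the correctness and identifiability of the
implementation under its own assumptions, not field accuracy; the
experiment's effect sizes (≈30 % GPP and ≈5–10 % T_c validation-RMSE
reduction for SEA over EGS) are properties of these study conditions.

## Numerical choices and degenerate inputs

Strict SW_IN > 5 W m⁻² daytime filter; records with QC flags > 1 dropped
where flags exist.  Missing values −9999 in the FLUXNET dialect; RH
written as percent and VPD as hPa, converted at the interface.  Days with
no retained records are absent from the daily table.  The uWUE slope
requires ≥ 60 valid days; season calibration requires ≥ 10 usable days
per window and raises naming the season.  A constant temperature
climatology (no percentile crossing) raises "no seasonal cycle".
Linear-interpolated LAI/FPAR is smoothed with a 15-day, order-2
Savitzky–Golay filter (exact on quadratics) and clipped to physical
ranges.  Calm half-hours floor the aerodynamic conductance at
1e-3 mol m⁻² s⁻¹; G_s predictions are floored at G_s,min inside the
transpiration evaluation; negative Penman–Monteith results (possible with
negative available energy) are floored at zero.

## Known limitations

The g_su–g_sh pair is weakly identified within a single season (their
conductance contributions are nearly collinear day-to-day), so individual
slope estimates can wander along a ridge while predictions remain stable;
sums, not splits, should be interpreted.  Truth values adjacent to a
physiological bound are recovered at the bound.  The neutral aerodynamic
profile omits stability corrections; timestamps are treated as local
solar time; leap-day LAI reuses day-365 values.
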