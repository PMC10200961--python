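# twoleaf

Two-leaf conductance–photosynthesis modelling of canopy carbon and water
fluxes for temperate deciduous forests, with a seasonal-parameterization
experiment: are ecosystem models better served by physiological parameters
fitted once for the whole growing season (EGS) or refitted per season
(SEA)?

The package is aimed at ecohydrologists and flux-tower analysts.  It
implements the full model chain at daily resolution:

1. **Two-leaf radiation** — solar geometry, clearness-index partitioning of
   PAR into direct and diffuse components, and the sunlit/shaded canopy
   split

   LAI_sun = 2 cos θ [1 − exp(−0.5 Ω LAI / cos θ)],  LAI_sh = LAI − LAI_sun

   with per-class absorbed PAR combining the direct beam (sunlit only) and
   the shared scattered field.

2. **Light-use-efficiency GPP** —

   GPP = ε_msu · APAR_sun · f(VPD) f(T) + ε_msh · APAR_sh · f(VPD) f(T)

   with a linear VPD ramp and the low/high-temperature TEM scalar.

3. **Two-leaf Ball–Berry conductance** —

   G_s = g_su · A_sun · RH/C_a + g_sh · A_sh · RH/C_a + G_s,min,
   G_s,min = 0.001 mol m⁻² s⁻¹

   where A_sun/A_sh are the leaf-class photosynthesis rates (µmol m⁻² s⁻¹).

4. **Penman–Monteith transpiration** —

   λT_c = [s·A_c + ρ C_p FPAR·VPD·g_a Δt] (1 − F_wet) / [s + γ (1 + G_a/G_s)]

   with an exact algebraic inversion for a reference G_s from observed T_c.

5. **Calibration** — the four physiological parameters
   (ε_msu, ε_msh, g_su, g_sh) are estimated with a shuffled-complex-evolution
   (SCE-UA) global search inside physiological bounds, in two stages (LUEs
   against GPP, then Ball–Berry slopes against transpiration), under both
   the EGS and SEA schemes, over many randomized season-stratified 70/30
   calibration/validation splits; skill is scored with Willmott's agreement
   index d, RMSE, Pearson r and AIC.

Because flux-tower and satellite inputs cannot ship with the package, a
first-class synthetic-site generator (`twoleaf.synthetic_flux`) produces
FLUXNET-style half-hourly drivers and forward-simulated fluxes with known
seasonally varying parameters, so the whole chain is testable end to end
against ground truth.

## Worked example

```python
from twoleaf import synthetic_flux as sf
from twoleaf import calibration as cal

spec = sf.SyntheticSiteSpec(years=3, seed=0)          # DE-Hai-like site
daily, hh, windows = sf.forward_simulate(spec)
print({s: getattr(windows, s) for s in ("spring", "summer", "autumn")})

data = cal.CalibrationData(daily, windows)
cfg = cal.CalibrationConfig(n_experiments=10, seed=0)
res = cal.run_randomized_experiments(data, cfg)
print(res["SEA"].parameter_summary().round(3))
comp = cal.compare_schemes(res["EGS"], res["SEA"])
print(comp.loc["validation",
               ["rmse_change_pct_mean", "rmse_change_pct_sd",
                "b_win_fraction"]].round(2))
```

prints

```
{'spring': (63, 147), 'summer': (148, 233), 'autumn': (234, 328)}
       eps_msu        eps_msh           g_su           g_sh
          mean    std    mean    std    mean    std    mean    std
season
autumn   0.639  0.021   4.789  0.003   0.000  0.000  16.881  0.208
spring   0.520  0.024   3.381  0.040  15.675  3.309  14.492  0.573
summer   0.832  0.028   4.063  0.032   9.723  0.997  13.200  0.240
          rmse_change_pct_mean  rmse_change_pct_sd  b_win_fraction
variable
GPP                     -31.02                2.43             1.0
Gs                       -0.49                0.37             1.0
Tc                       -4.81                1.69             1.0
```

The season windows are identified from the 25th/75th percentiles of the
daytime-temperature climatology.  The parameter table is the
across-experiment mean (sd) of the SEA estimates: the spring/summer LUEs
and the summer slopes are recovered close to the generating truth
(ε_msu 0.52/0.78, ε_msh 3.35/4.10, g_su 9, g_sh 13), while the autumn
slope pair illustrates the g_su–g_sh ridge (their weighted sum is
identified, the split is not, and ε_msh sits against its physiological
bound).  The comparison rows give the paired validation change of SEA
relative to EGS: negative RMSE change means the seasonal parameterization
is more accurate — here a ~31 % error reduction for GPP and ~5 % for
transpiration, with SEA winning every paired split.

The same experiment is available from the shell:

```bash
twoleaf simulate --out site/ --seed 0
twoleaf run --site site/ --n-experiments 50
```

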