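"""Psychrometrics, conductances and Penman-Monteith canopy transpiration.

The canopy latent-heat flux follows the Penman-Monteith combination form

    λE_c = [s·A_c + ρ·C_p·FPAR·VPD·g_a·Δt_day] · (1 − F_wet)
           ---------------------------------------------------
                        s + γ·(1 + G_a/G_s)

with A_c the energy available to the canopy (MJ m⁻² d⁻¹, FPAR-weighted
available energy), VPD the daytime-mean vapor deficit (kPa), g_a the
aerodynamic conductance in m s⁻¹, Δt_day the daytime duration in seconds
and F_wet the wet-canopy fraction.  Transpiration is Tc = λE_c / λ in
mm d⁻¹.  Canopy conductance comes from the two-leaf Ball-Berry relation

    G_s = g_su·GPP_sunlit·RH/Ca + g_sh·GPP_shaded·RH/Ca + G_s,min

in mol m⁻² s⁻¹ (GPP rates in µmol CO₂ m⁻² s⁻¹).  Conductances are carried
in molar units and converted via the molar density of air only where the
aerodynamic term needs m s⁻¹; the G_a/G_s ratio is unit-free.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .params import GS_MIN

__all__ = [
    "Psychrometrics",
    "psychrometrics",
    "fwet",
    "aerodynamic_conductance",
    "canopy_conductance",
    "penman_monteith_tc",
    "invert_pm_for_gs",
    "molar_density_air",
]

#: Specific heat of air at constant pressure, MJ kg-1 °C-1.
CP_AIR = 1.013e-3
#: Specific gas constant of dry air, J kg-1 K-1.
R_DRY_AIR = 287.05
#: Universal gas constant, J mol-1 K-1.
R_GAS = 8.314462
#: von Karman constant.
VON_KARMAN = 0.41
#: Standard surface pressure, kPa.
P_STANDARD = 101.325


class Psychrometrics(NamedTuple):
    s: float          # slope of saturation vapor pressure curve, kPa °C-1
    gamma: float      # psychrometric constant, kPa °C-1
    lam: float        # latent heat of vaporization, MJ kg-1
    rho: float        # air density, kg m-3
    e_sat: float      # saturation vapor pressure, kPa


def psychrometrics(t_air, pressure_kpa=P_STANDARD):
    """FAO-56 psychrometric quantities at air temperature T (°C).

    Tetens saturation vapor pressure, linear λ(T), γ = C_p·P/(0.622·λ) and
    dry-air density from the ideal gas law.
    """
    t = np.asarray(t_air, dtype=float)
    e_sat = 0.6108 * np.exp(17.27 * t / (t + 237.3))
    s = 4098.0 * e_sat / (t + 237.3) ** 2
    lam = 2.501 - 0.002361 * t
    gamma = CP_AIR * pressure_kpa / (0.622 * lam)
    rho = pressure_kpa * 1000.0 / (R_DRY_AIR * (t + 273.15))
    return Psychrometrics(s, gamma, lam, rho, e_sat)


def molar_density_air(t_air, pressure_kpa=P_STANDARD):
    """Molar density of air, mol m⁻³ (ideal gas)."""
    return pressure_kpa * 1000.0 / (R_GAS * (np.asarray(t_air, dtype=float) + 273.15))


def fwet(rh):
    """Wet-canopy (water-covered) fraction from relative humidity.

    Zero below RH = 0.70, RH⁴ at or above; RH given as a fraction.
    """
    rh = np.asarray(rh, dtype=float)
    if np.any((rh < 0) | (rh > 1)):
        raise ValueError("RH must be a fraction in [0, 1]")
    return np.where(rh < 0.70, 0.0, rh ** 4)


def aerodynamic_conductance(wind, z_measure, h_canopy, t_air=15.0,
                            pressure_kpa=P_STANDARD, min_ga=1e-3):
    """Neutral log-profile aerodynamic conductance, mol m⁻² s⁻¹.

    g_a [m s⁻¹] = k²·u / ln²((Z−d)/z0) with displacement d = 0.67·H and
    roughness z0 = 0.1·H, converted to molar units with the molar density
    of air.  Non-positive wind is floored so the conductance never
    vanishes entirely (calm half-hours still mix).

    Raises if the measurement height does not clear the roughness layer
    (Z − d ≤ z0).
    """
    d = 0.67 * h_canopy
    z0 = 0.1 * h_canopy
    if z_measure - d <= z0:
        raise ValueError(
            f"invalid geometry: measurement height {z_measure} m does not "
            f"clear displacement {d:.2f} m + roughness {z0:.2f} m"
        )
    u = np.maximum(np.asarray(wind, dtype=float), 0.0)
    log_term = np.log((z_measure - d) / z0)
    ga_ms = VON_KARMAN ** 2 * u / log_term ** 2
    ga_mol = ga_ms * molar_density_air(t_air, pressure_kpa)
    return np.maximum(ga_mol, min_ga)


def canopy_conductance(gpp_sunlit_rate, gpp_shaded_rate, rh, ca, g_su, g_sh,
                       gs_min=GS_MIN):
    """Two-leaf Ball-Berry canopy conductance, mol m⁻² s⁻¹.

    Parameters
    ----------
    gpp_sunlit_rate, gpp_shaded_rate : array
        Leaf-class photosynthesis rates, µmol CO₂ m⁻² s⁻¹.
    rh : array
        Canopy-surface relative humidity, fraction.
    ca : array
        Ambient CO₂ mole fraction, µmol mol⁻¹; must be positive.
    g_su, g_sh : float
        Ball-Berry slopes for sunlit/shaded leaves.
    """
    ca = np.asarray(ca, dtype=float)
    if np.any(ca <= 0):
        raise ValueError("CO2 concentration must be positive")
    rh = np.asarray(rh, dtype=float)
    idx_su = np.asarray(gpp_sunlit_rate, dtype=float) * rh / ca
    idx_sh = np.asarray(gpp_shaded_rate, dtype=float) * rh / ca
    return g_su * idx_su + g_sh * idx_sh + gs_min


@dataclass(frozen=True)
class PMInputs:
    """Daily drivers of the Penman-Monteith evaluation (vector fields).

    ``a_c`` is the canopy-allocated available energy in MJ m⁻² d⁻¹
    (FPAR × (Rn − G) integrated over daytime), ``ga_mol`` the aerodynamic
    conductance in mol m⁻² s⁻¹, ``daytime_s`` the daytime duration in
    seconds used to integrate the aerodynamic drying term.
    """

    t_air: np.ndarray
    a_c: np.ndarray
    vpd: np.ndarray
    rh: np.ndarray
    fpar: np.ndarray
    ga_mol: np.ndarray
    daytime_s: np.ndarray
    pressure_kpa: float = P_STANDARD


def _pm_terms(inp: PMInputs):
    psy = psychrometrics(inp.t_air, inp.pressure_kpa)
    ga_ms = inp.ga_mol / molar_density_air(inp.t_air, inp.pressure_kpa)
    # numerator before the (1 - Fwet) factor, MJ m-2 d-1 * kPa/°C
    numer = (
        psy.s * inp.a_c
        + psy.rho * CP_AIR * inp.fpar * inp.vpd * ga_ms * inp.daytime_s
    )
    wet = fwet(inp.rh)
    return psy, numer * (1.0 - wet), wet


def penman_monteith_tc(inp: PMInputs, gs_mol):
    """Canopy transpiration Tc (mm d⁻¹) for given canopy conductance.

    Monotone increasing in G_s; tends to 0 as G_s → 0 and to the
    energy-limited asymptote as G_s → ∞.  Negative results (possible with
    negative available energy) are floored at zero.
    """
    gs = np.asarray(gs_mol, dtype=float)
    if np.any(gs <= 0):
        raise ValueError("canopy conductance must be positive")
    psy, numer, _ = _pm_terms(inp)
    denom = psy.s + psy.gamma * (1.0 + inp.ga_mol / gs)
    lam_e = numer / denom
    return np.maximum(lam_e / psy.lam, 0.0)


def invert_pm_for_gs(tc_obs, inp: PMInputs, max_asymptote_fraction: float = 1.0):
    """Invert the Penman-Monteith form for the canopy conductance.

    Returns ``(gs_mol, invertible)``.  Days with Tc ≤ 0 return G_s = 0 with
    ``invertible = False`` (boundary); days whose Tc meets or exceeds
    ``max_asymptote_fraction`` of the energy-limited asymptote
    λE_max = numer/(s+γ) are flagged non-invertible (NaN) — at the
    asymptote dTc/dG_s → 0, so the inversion is unbounded and a noisy Tc
    near it yields arbitrarily large conductances.  Round-trips the forward
    evaluation to ~1e-10 relative precision on valid days.
    """
    tc = np.asarray(tc_obs, dtype=float)
    psy, numer, _ = _pm_terms(inp)
    lam_e = tc * psy.lam
    with np.errstate(divide="ignore", invalid="ignore"):
        x = (numer / np.where(lam_e > 0, lam_e, np.nan) - psy.s - psy.gamma) / psy.gamma
        frac = lam_e * (psy.s + psy.gamma) / numer
    gs = inp.ga_mol / x
    invertible = (
        (tc > 0) & np.isfinite(x) & (x > 0) & (frac < max_asymptote_fraction)
    )
    gs = np.where(invertible, gs, np.where(tc <= 0, 0.0, np.nan))
    return gs, invertible
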