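"""Two-leaf light-use-efficiency GPP with VPD and temperature down-regulation.

GPP of each leaf class is linear in its absorbed PAR,

    GPP_sunlit = eps_msu · APAR_sunlit · f(VPD) · f(T)
    GPP_shaded = eps_msh · APAR_shaded · f(VPD) · f(T)
    GPP        = GPP_sunlit + GPP_shaded,

with a MOD17-style linear VPD ramp and the TEM temperature scalar that
penalizes both low and high temperatures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ParameterSet

__all__ = [
    "EnvScalarConfig",
    "f_vpd",
    "f_temp",
    "estimate_gpp",
    "gpp_daily_to_molar_rate",
    "GC_PER_UMOL",
]

#: grams of carbon per µmol CO2.
GC_PER_UMOL = 12.011e-6


@dataclass(frozen=True)
class EnvScalarConfig:
    """Thresholds of the environmental limiting scalars.

    The VPD ramp is fully open below ``vpd_open`` and fully closed above
    ``vpd_close`` (kPa); defaults are deciduous-broadleaf-like MOD17 values.
    The temperature scalar uses the TEM form with ``t_min < t_opt < t_max``
    (°C).
    """

    vpd_open: float = 0.65
    vpd_close: float = 2.5
    t_min: float = -1.0
    t_opt: float = 25.0
    t_max: float = 40.0

    def __post_init__(self) -> None:
        if not self.vpd_close > self.vpd_open:
            raise ValueError("vpd_close must exceed vpd_open")
        if not self.t_min < self.t_opt < self.t_max:
            raise ValueError("need t_min < t_opt < t_max")


def f_vpd(vpd, config: EnvScalarConfig = EnvScalarConfig()):
    """Linear VPD down-regulation scalar in [0, 1].

    1 at or below the open threshold, 0 at or above the closure threshold,
    linear in between.
    """
    vpd = np.asarray(vpd, dtype=float)
    return np.clip(
        (config.vpd_close - vpd) / (config.vpd_close - config.vpd_open), 0.0, 1.0
    )


def f_temp(t_air, config: EnvScalarConfig = EnvScalarConfig()):
    """TEM temperature scalar in [0, 1].

    f = (T−Tmin)(T−Tmax) / [(T−Tmin)(T−Tmax) − (T−Topt)²], zero outside
    [Tmin, Tmax] and exactly one at Topt.
    """
    t = np.asarray(t_air, dtype=float)
    num = (t - config.t_min) * (t - config.t_max)
    den = num - (t - config.t_opt) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(np.abs(den) > 0, num / np.where(den != 0, den, 1.0), 1.0)
    f = np.where((t <= config.t_min) | (t >= config.t_max), 0.0, f)
    return np.clip(f, 0.0, 1.0)


def estimate_gpp(apar_sunlit, apar_shaded, vpd, t_air, params: ParameterSet,
                 config: EnvScalarConfig = EnvScalarConfig()):
    """Daily GPP of the two leaf classes, gC m⁻² d⁻¹.

    Parameters
    ----------
    apar_sunlit, apar_shaded : array
        Daily absorbed PAR per leaf class, MJ m⁻² d⁻¹.
    vpd, t_air : array
        Daytime-mean vapor pressure deficit (kPa) and air temperature (°C).
    params : ParameterSet
        Maximum LUEs in gC MJ⁻¹ (bounds enforced by the type).

    Returns
    -------
    (gpp_sunlit, gpp_shaded, gpp_total)
    """
    scal = f_vpd(vpd, config) * f_temp(t_air, config)
    gpp_su = params.eps_msu * np.asarray(apar_sunlit, dtype=float) * scal
    gpp_sh = params.eps_msh * np.asarray(apar_shaded, dtype=float) * scal
    return gpp_su, gpp_sh, gpp_su + gpp_sh


def gpp_daily_to_molar_rate(gpp_daily, daytime_seconds):
    """Convert daily GPP (gC m⁻² d⁻¹) to a mean daytime CO₂ flux (µmol m⁻² s⁻¹).

    Inverse of the daytime integration used in preprocessing; requires a
    positive daytime duration.
    """
    dt = np.asarray(daytime_seconds, dtype=float)
    if np.any(dt <= 0):
        raise ValueError("daytime duration must be positive")
    return np.asarray(gpp_daily, dtype=float) / (GC_PER_UMOL * dt)
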