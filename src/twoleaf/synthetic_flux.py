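"""Synthetic flux-tower site: FLUXNET-style drivers plus forward-simulated
carbon and water fluxes with known seasonally varying parameters.

The generator emulates a temperate deciduous broadleaf forest site:
sinusoidal annual and diurnal temperature cycles with AR(1) synoptic
anomalies, clear-sky shortwave modulated by day-to-day cloudiness (so the
clearness index — and with it the direct/diffuse split — varies), dawn-peaked
relative humidity with VPD tied to temperature and RH through the saturation
vapor pressure, and a double-logistic leaf-area phenology sampled at 8-day
steps with FPAR = 1 − exp(−0.5·LAI).

``forward_simulate`` runs the full two-leaf model chain (radiation → GPP →
Ball-Berry conductance → Penman-Monteith transpiration) with per-season
"true" parameters, adds additive Gaussian observation noise at daily scale,
and back-distributes the daily observations onto the half-hourly records so
the preprocessing path reproduces them exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from . import canopy_radiation as cr
from . import gpp_model as gm
from . import preprocess as pp
from . import water_flux as wf
from .params import ParameterSet, SeasonWindows

__all__ = [
    "MeteoParams",
    "SyntheticSiteSpec",
    "default_true_params",
    "generate_meteo",
    "generate_lai_fpar",
    "forward_simulate",
    "write_fluxnet_csv",
    "read_fluxnet_csv",
    "write_lai_fpar_csv",
    "read_lai_fpar_csv",
]

MISSING = -9999.0

#: internal name -> FLUXNET FULLSET column, with unit scale (internal*scale=file)
_FLUXNET_COLUMNS = {
    "SW_IN": ("SW_IN_F", 1.0),
    "TA": ("TA_F", 1.0),
    "RH": ("RH", 100.0),        # fraction -> percent
    "VPD": ("VPD_F", 10.0),     # kPa -> hPa
    "WS": ("WS_F", 1.0),
    "CA": ("CO2_F_MDS", 1.0),
    "LE": ("LE_F_MDS", 1.0),
    "H": ("H_F_MDS", 1.0),
    "G": ("G_F_MDS", 1.0),
    "P": ("P_F", 1.0),
    "GPP": ("GPP_DT_VUT_REF", 1.0),
}

#: fraction of incoming shortwave available as Rn − G to the surface
AVAILABLE_ENERGY_FRACTION = 0.675
GROUND_HEAT_FRACTION = 0.075


@dataclass(frozen=True)
class MeteoParams:
    """Climate of the synthetic site.

    Temperatures in °C (annual mean, annual half-amplitude, diurnal
    half-range), ``transmittance`` the clear-sky shortwave transmittance,
    RH as fractions, wind in m s⁻¹, CO₂ in µmol mol⁻¹.
    """

    t_mean: float = 8.5
    t_amp: float = 9.5
    t_diurnal: float = 6.0
    transmittance: float = 0.75
    rh_mean: float = 0.75
    rh_range: float = 0.30
    wind_mean: float = 2.5
    co2: float = 400.0


def default_true_params() -> Dict[str, ParameterSet]:
    """Per-season truth with contrasts typical of temperate DBF sites:
    maximum sunlit LUE peaks in summer (≈1.5× spring), Ball-Berry slopes
    dip in summer and rise again in autumn (≈1.2× summer).  Magnitudes are
    chosen so the forward fluxes land in the observed ranges for such
    forests (daily GPP up to ~15 gC m⁻², Tc up to ~4 mm, G_s of order
    0.1–0.5 mol m⁻² s⁻¹)."""
    return {
        "spring": ParameterSet(0.52, 3.35, 11.0, 14.0, "spring"),
        "summer": ParameterSet(0.78, 4.10, 9.0, 13.0, "summer"),
        "autumn": ParameterSet(0.60, 4.75, 10.5, 15.6, "autumn"),
    }


@dataclass(frozen=True)
class SyntheticSiteSpec:
    """Full description of a synthetic flux site (Table-1-style metadata,
    phenology, climate, truth parameters and observation noise)."""

    latitude: float = 51.08
    longitude: float = 10.45
    canopy_height: float = 23.0
    measurement_height: float = 44.0
    years: int = 3
    true_params: Dict[str, ParameterSet] = field(default_factory=default_true_params)
    lai_curve: Tuple[float, float, float, float] = (6.0, 120.0, 290.0, 10.0)
    meteo_params: MeteoParams = field(default_factory=MeteoParams)
    noise: Tuple[float, float] = (1.0, 0.3)   # GPP sd gC m-2 d-1, Tc sd mm d-1
    seed: int = 0
    start_year: int = 2001

    def __post_init__(self) -> None:
        if not -90 <= self.latitude <= 90:
            raise ValueError("latitude outside [-90, 90]")
        if self.measurement_height <= self.canopy_height:
            raise ValueError("measurement_height must exceed canopy_height")
        if self.years < 1:
            raise ValueError("years must be at least 1")
        lai_max, greenup, senesce, slope = self.lai_curve
        if lai_max <= 0:
            raise ValueError("lai_curve max must be positive")
        if not greenup < senesce:
            raise ValueError("lai_curve green-up doy must precede senescence doy")
        if slope <= 0:
            raise ValueError("lai_curve slope must be positive")
        if self.noise[0] < 0 or self.noise[1] < 0:
            raise ValueError("noise standard deviations must be non-negative")
        for season in ("spring", "summer", "autumn"):
            if season not in self.true_params:
                raise ValueError(f"true_params missing season {season!r}")


def _ar1(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    eps = rng.normal(0.0, sd * np.sqrt(1 - rho ** 2), n)
    out = np.empty(n)
    out[0] = rng.normal(0.0, sd)
    for i in range(1, n):
        out[i] = rho * out[i - 1] + eps[i]
    return out


def generate_meteo(spec: SyntheticSiteSpec) -> pd.DataFrame:
    """Half-hourly meteorological drivers over ``spec.years`` years.

    Returns a DataFrame indexed by timestamp (interval start, local solar
    time) with internal column names; flux columns GPP/LE/H are placeholders
    until :func:`forward_simulate` fills them (H carries the available
    energy so daily A is defined by radiation alone).
    """
    mp = spec.meteo_params
    rng = np.random.default_rng(spec.seed)

    start = pd.Timestamp(year=spec.start_year, month=1, day=1)
    end = pd.Timestamp(year=spec.start_year + spec.years, month=1, day=1)
    idx = pd.date_range(start, end, freq="30min", inclusive="left")
    n = len(idx)
    doy = idx.dayofyear.to_numpy()
    hour = idx.hour.to_numpy() + idx.minute.to_numpy() / 60.0 + 0.25  # midpoint

    n_days = (idx.normalize().max() - idx.normalize().min()).days + 1
    day_index = (idx.normalize() - idx.normalize().min()).days.to_numpy()
    syn_t = _ar1(rng, n_days, 0.85, 2.0)                 # synoptic temperature
    cloud_z = _ar1(rng, n_days, 0.6, 1.0)                # cloudiness driver
    cloud = 0.35 + 0.65 / (1.0 + np.exp(-cloud_z))       # in (0.35, 1)
    rh_anom = _ar1(rng, n_days, 0.7, 0.06)
    wind_anom = _ar1(rng, n_days, 0.5, 0.5)

    t_season = mp.t_mean - mp.t_amp * np.cos(2 * np.pi * (doy - 15.0) / 365.0)
    t_air = (
        t_season
        + syn_t[day_index]
        + 0.5 * mp.t_diurnal * np.cos(2 * np.pi * (hour - 14.0) / 24.0)
    )

    cosz, _ = cr.solar_zenith(spec.latitude, doy, hour)
    sw = np.where(
        cosz > 0,
        cr.SOLAR_CONSTANT * mp.transmittance * cloud[day_index] * np.maximum(cosz, 0.0),
        0.0,
    )

    rh = (
        mp.rh_mean
        + 0.5 * mp.rh_range * np.cos(2 * np.pi * (hour - 5.0) / 24.0)
        + rh_anom[day_index]
    )
    rh = np.clip(rh, 0.2, 0.98)
    e_sat = wf.psychrometrics(t_air).e_sat
    vpd = e_sat * (1.0 - rh)

    wind = np.maximum(0.5, mp.wind_mean + wind_anom[day_index])

    avail = AVAILABLE_ENERGY_FRACTION * sw
    hh = pd.DataFrame(
        {
            "SW_IN": sw,
            "TA": t_air,
            "RH": rh,
            "VPD": vpd,
            "WS": wind,
            "CA": np.full(n, mp.co2),
            "LE": np.zeros(n),
            "H": avail,
            "G": GROUND_HEAT_FRACTION * sw,
            "P": np.zeros(n),
            "GPP": np.zeros(n),
        },
        index=idx,
    )
    return hh


def generate_lai_fpar(spec: SyntheticSiteSpec) -> pd.DataFrame:
    """8-day LAI and FPAR series (single year of composites, doy 1, 9, ...).

    LAI follows a double-logistic phenology; FPAR maps from LAI through the
    Beer law 1 − exp(−0.5·LAI), keeping FPAR-based and two-leaf APAR
    directly comparable.
    """
    lai_max, greenup, senesce, slope = spec.lai_curve
    doy = np.arange(1.0, 366.0, 8.0)
    lai = lai_max * (
        1.0 / (1.0 + np.exp(-(doy - greenup) / slope))
        * 1.0 / (1.0 + np.exp((doy - senesce) / slope))
    )
    lai[lai < 1e-3] = 0.0
    fpar = 1.0 - np.exp(-0.5 * lai)
    return pd.DataFrame({"doy": doy.astype(int), "LAI": lai, "FPAR": fpar})


def _params_for_doy(doy: np.ndarray, windows: SeasonWindows,
                    true_params: Dict[str, ParameterSet]):
    """Season label per day; winter days borrow the nearest shoulder season
    (spring before midsummer, autumn after) — foliage is absent there, so
    fluxes are near zero regardless."""
    mid = windows.summer[0]
    labels = []
    for d in doy:
        s = windows.season_of_doy(int(d))
        if s == "winter":
            s = "spring" if d < mid else "autumn"
        labels.append(s)
    return np.array(labels)


def forward_simulate(
    spec: SyntheticSiteSpec,
    hh: pd.DataFrame | None = None,
    radiation_config: cr.RadiationConfig = cr.RadiationConfig(),
    env_config: gm.EnvScalarConfig = gm.EnvScalarConfig(),
):
    """Run the forward model chain with the site's true parameters.

    Returns ``(daily, hh, windows)`` where ``daily`` holds observed columns
    (``GPP_obs``, ``Tc_obs``, ``ET_obs``) and truth columns (``GPP_true``,
    ``Gs_true``, ``Tc_true``) plus all drivers the calibration needs, and
    ``hh`` is the half-hourly table with GPP and LE back-filled so that
    daytime aggregation reproduces the daily observations exactly.  With
    zero noise the observed columns equal the truth.
    """
    if hh is None:
        hh = generate_meteo(spec)
    from .pipeline import build_daily_dataset

    daily, windows = build_daily_dataset(
        hh, generate_lai_fpar(spec), spec.latitude,
        spec.measurement_height, spec.canopy_height, radiation_config,
    )

    doy = daily["doy"].to_numpy()
    season = _params_for_doy(doy, windows, spec.true_params)

    # truth GPP per leaf class
    gpp_su = np.zeros(len(daily))
    gpp_sh = np.zeros(len(daily))
    for name in ("spring", "summer", "autumn"):
        m = season == name
        if not m.any():
            continue
        su, sh, _ = gm.estimate_gpp(
            daily["APAR_sunlit"].to_numpy()[m],
            daily["APAR_shaded"].to_numpy()[m],
            daily["VPD"].to_numpy()[m],
            daily["T_air"].to_numpy()[m],
            spec.true_params[name],
            env_config,
        )
        gpp_su[m], gpp_sh[m] = su, sh
    gpp_true = gpp_su + gpp_sh

    # truth conductance and transpiration
    dt_day = daily["daytime_s"].to_numpy()
    rate_su = gm.gpp_daily_to_molar_rate(gpp_su, dt_day)
    rate_sh = gm.gpp_daily_to_molar_rate(gpp_sh, dt_day)
    gs_true = np.zeros(len(daily))
    for name in ("spring", "summer", "autumn"):
        m = season == name
        if not m.any():
            continue
        p = spec.true_params[name]
        gs_true[m] = wf.canopy_conductance(
            rate_su[m], rate_sh[m],
            daily["RH"].to_numpy()[m], daily["Ca"].to_numpy()[m],
            p.g_su, p.g_sh,
        )
    ga = daily["Ga_mol"].to_numpy()
    pm_in = wf.PMInputs(
        t_air=daily["T_air"].to_numpy(),
        a_c=daily["A_MJ"].to_numpy() * daily["FPAR"].to_numpy(),
        vpd=daily["VPD"].to_numpy(),
        rh=daily["RH"].to_numpy(),
        fpar=daily["FPAR"].to_numpy(),
        ga_mol=ga,
        daytime_s=dt_day,
    )
    tc_true = wf.penman_monteith_tc(pm_in, gs_true)

    # observation noise (daily, additive, homoscedastic)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))
    gpp_obs = gpp_true + rng.normal(0.0, spec.noise[0], len(daily)) if spec.noise[0] > 0 else gpp_true.copy()
    tc_obs = tc_true + rng.normal(0.0, spec.noise[1], len(daily)) if spec.noise[1] > 0 else tc_true.copy()

    # ET from transpiration via a fixed T/ET ratio schedule tied to canopy
    # development, so the uWUE partition has signal to recover
    lai_max = spec.lai_curve[0]
    t_et_ratio = np.clip(0.5 + 0.4 * daily["LAI"].to_numpy() / lai_max, 0.5, 0.9)
    et_obs = np.maximum(tc_obs, 0.0) / t_et_ratio

    daily["GPP_true"] = gpp_true
    daily["GPP_sunlit_true"] = gpp_su
    daily["GPP_shaded_true"] = gpp_sh
    daily["Gs_true"] = gs_true
    daily["Tc_true"] = tc_true
    daily["GPP_obs"] = gpp_obs
    daily["Tc_obs"] = tc_obs
    daily["ET_obs"] = et_obs
    daily["T_ET_ratio"] = t_et_ratio

    hh = _distribute_daily_to_halfhourly(hh, daily)
    return daily, hh, windows


def _distribute_daily_to_halfhourly(hh: pd.DataFrame, daily: pd.DataFrame) -> pd.DataFrame:
    """Back-fill half-hourly GPP and LE so daytime aggregation reproduces the
    daily observations exactly (weights proportional to shortwave)."""
    hh = hh.copy()
    idx = pd.DatetimeIndex(hh.index)
    dates = idx.normalize()
    retained = hh["SW_IN"].to_numpy() > pp.SW_DAYTIME_THRESHOLD
    sw = np.where(retained, hh["SW_IN"].to_numpy(), 0.0)
    sw_day_sum = pd.Series(sw, index=dates).groupby(level=0).transform("sum").to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(sw_day_sum > 0, sw / sw_day_sum, 0.0)

    gpp_day = daily["GPP_obs"].reindex(dates).to_numpy()
    et_day = daily["ET_obs"].reindex(dates).to_numpy()
    gpp_day = np.nan_to_num(gpp_day)
    et_day = np.nan_to_num(et_day)

    step = pp.STEP_SECONDS
    lam = wf.psychrometrics(hh["TA"].to_numpy()).lam
    hh["GPP"] = w * gpp_day / (gm.GC_PER_UMOL * step)
    hh["LE"] = w * et_day * lam * 1e6 / step
    hh["H"] = AVAILABLE_ENERGY_FRACTION * hh["SW_IN"].to_numpy() - hh["LE"].to_numpy()
    return hh


# ---------------------------------------------------------------- file I/O

def write_fluxnet_csv(hh: pd.DataFrame, path) -> None:
    """Write half-hourly records as a FLUXNET2015 FULLSET-style CSV.

    TIMESTAMP_START/END in YYYYMMDDHHMM, RH in percent, VPD in hPa,
    missing values encoded as −9999, numbers at 6 significant digits.
    """
    if len(hh) == 0:
        raise ValueError("no records to write")
    idx = pd.DatetimeIndex(hh.index)
    out = pd.DataFrame(
        {
            "TIMESTAMP_START": idx.strftime("%Y%m%d%H%M"),
            "TIMESTAMP_END": (idx + pd.Timedelta(seconds=pp.STEP_SECONDS)).strftime("%Y%m%d%H%M"),
        }
    )
    for internal, (col, scale) in _FLUXNET_COLUMNS.items():
        vals = hh[internal].to_numpy(dtype=float) * scale
        out[col] = np.where(np.isfinite(vals), vals, MISSING)
    out.to_csv(path, index=False, float_format="%.6g")


def read_fluxnet_csv(path) -> pd.DataFrame:
    """Read a FLUXNET-style CSV back into internal units (name-based,
    column order irrelevant); −9999 becomes NaN."""
    raw = pd.read_csv(path)
    idx = pd.to_datetime(raw["TIMESTAMP_START"].astype(str), format="%Y%m%d%H%M")
    data = {}
    for internal, (col, scale) in _FLUXNET_COLUMNS.items():
        if col not in raw.columns:
            continue
        vals = raw[col].to_numpy(dtype=float)
        vals = np.where(vals <= MISSING, np.nan, vals)
        data[internal] = vals / scale
    return pd.DataFrame(data, index=idx)


def write_lai_fpar_csv(eight_day: pd.DataFrame, path) -> None:
    eight_day.to_csv(path, index=False, float_format="%.6g")


def read_lai_fpar_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
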