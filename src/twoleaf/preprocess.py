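"""Flux-tower preprocessing: QC, daily aggregation, uWUE partitioning,
LAI/FPAR interpolation and temperature-percentile season identification.

Half-hourly tables use the FLUXNET-style internal column names
``SW_IN`` (W m⁻²), ``TA`` (°C), ``RH`` (fraction), ``VPD`` (kPa),
``WS`` (m s⁻¹), ``CA`` (µmol mol⁻¹), ``LE``/``H``/``G`` (W m⁻²) and
``GPP`` (µmol CO₂ m⁻² s⁻¹), indexed by timestamp.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .gpp_model import GC_PER_UMOL
from .params import SeasonWindows

__all__ = [
    "qc_filter_daytime",
    "aggregate_daily",
    "uwue_potential",
    "partition_transpiration_uwue",
    "identify_seasons",
    "interpolate_lai_fpar",
]

#: Daytime shortwave threshold, W m-2 (records at exactly the threshold are
#: dropped: the filter is a strict inequality).
SW_DAYTIME_THRESHOLD = 5.0

STEP_SECONDS = 1800.0


def qc_filter_daytime(hh: pd.DataFrame, qc_max: int = 1) -> pd.DataFrame:
    """Retain daytime records passing quality screening, order preserved.

    A record is kept when SW_IN > 5 W m⁻² and, where ``*_QC`` flag columns
    exist, every flag is ≤ ``qc_max`` (0 = measured, 1 = good gap-fill).
    """
    mask = hh["SW_IN"].to_numpy(dtype=float) > SW_DAYTIME_THRESHOLD
    for col in hh.columns:
        if col.endswith("_QC"):
            mask &= hh[col].to_numpy(dtype=float) <= qc_max
    return hh.loc[mask]


def aggregate_daily(hh: pd.DataFrame, step_seconds: float = STEP_SECONDS) -> pd.DataFrame:
    """Integrate QC-filtered daytime records into daily values.

    Fluxes are integrated over the retained daytime steps: GPP via
    µmol s⁻¹ → gC m⁻² d⁻¹ (× 12.011e-6 × Δt summed), latent heat via the
    temperature-dependent latent heat of vaporization into mm d⁻¹, and the
    available energy A = Σ(LE + H)·Δt in MJ m⁻² d⁻¹.  State variables are
    daytime means.  Days with no retained records are simply absent.
    """
    if len(hh) == 0:
        raise ValueError("no records to aggregate")
    from .water_flux import psychrometrics

    idx = pd.DatetimeIndex(hh.index)
    df = hh.copy()
    df["date"] = idx.normalize()
    lam = psychrometrics(df["TA"].to_numpy(dtype=float)).lam  # MJ kg-1
    df["_gpp_g"] = df["GPP"].to_numpy(dtype=float) * GC_PER_UMOL * step_seconds
    df["_et_mm"] = df["LE"].to_numpy(dtype=float) * step_seconds * 1e-6 / lam
    df["_a_mj"] = (df["LE"].to_numpy(dtype=float) + df["H"].to_numpy(dtype=float)) * step_seconds * 1e-6

    daily = df.groupby("date").agg(
        T_air=("TA", "mean"),
        RH=("RH", "mean"),
        VPD=("VPD", "mean"),
        wind=("WS", "mean"),
        Ca=("CA", "mean"),
        GPP_obs=("_gpp_g", "sum"),
        ET_obs=("_et_mm", "sum"),
        A_MJ=("_a_mj", "sum"),
        n_records=("TA", "size"),
    )
    daily["daytime_s"] = daily["n_records"] * step_seconds
    daily["doy"] = pd.DatetimeIndex(daily.index).dayofyear
    daily["year"] = pd.DatetimeIndex(daily.index).year
    return daily.drop(columns="n_records")


def uwue_potential(gpp, vpd, et, tau: float = 0.95, min_days: int = 60) -> float:
    """Potential underlying water-use efficiency, uWUE_p.

    The slope of the τ-quantile regression of y = GPP·√VPD on x = ET
    through the origin.  For a single through-origin regressor with x > 0
    the pinball-loss minimizer has a closed form: the x-weighted τ-quantile
    of the per-day ratios y/x, which is what is computed here (exact, no
    iteration).  Days with ET ≤ 0 are excluded.
    """
    gpp = np.asarray(gpp, dtype=float)
    vpd = np.asarray(vpd, dtype=float)
    et = np.asarray(et, dtype=float)
    ok = np.isfinite(gpp) & np.isfinite(vpd) & np.isfinite(et) & (et > 0) & (vpd >= 0)
    if ok.sum() < min_days:
        raise ValueError(
            f"need at least {min_days} valid days to estimate uWUE_p, have {int(ok.sum())}"
        )
    y = gpp[ok] * np.sqrt(vpd[ok])
    x = et[ok]
    ratio = y / x
    order = np.argsort(ratio)
    ratio, w = ratio[order], x[order]
    cum = np.cumsum(w)
    # smallest ratio whose cumulative weight reaches tau of the total:
    # the exact minimizer of sum_i rho_tau(y_i - c x_i) over c
    k = np.searchsorted(cum, tau * cum[-1])
    return float(ratio[min(k, len(ratio) - 1)])


def partition_transpiration_uwue(daily: pd.DataFrame, tau: float = 0.95,
                                 min_days: int = 60) -> pd.Series:
    """Daily transpiration from ET by the uWUE ratio method.

    Tc = ET · clamp(uWUE_a / uWUE_p, 0, 1) with uWUE_a = GPP·√VPD/ET per
    day and uWUE_p the site-level potential value.  Days with ET ≤ 0 get
    NaN (flagged undefined).
    """
    uwue_p = uwue_potential(daily["GPP_obs"], daily["VPD"], daily["ET_obs"],
                            tau=tau, min_days=min_days)
    et = daily["ET_obs"].to_numpy(dtype=float)
    gpp = daily["GPP_obs"].to_numpy(dtype=float)
    vpd = np.maximum(daily["VPD"].to_numpy(dtype=float), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        uwue_a = gpp * np.sqrt(vpd) / et
    ratio = np.clip(uwue_a / uwue_p, 0.0, 1.0)
    tc = np.where(et > 0, et * ratio, np.nan)
    return pd.Series(tc, index=daily.index, name="Tc_uwue")


def identify_seasons(daily: pd.DataFrame, smooth_days: int = 15) -> SeasonWindows:
    """Season windows from percentiles of the daytime temperature climatology.

    The multi-year mean daytime temperature per day-of-year is smoothed
    with a circular running mean, then thresholded at the 25th and 75th
    percentiles of all valid daily daytime means: winter below P25, summer
    the contiguous block above P75 around the annual maximum, spring the
    warming transition and autumn the cooling transition.  Raises when the
    climatology never crosses a threshold (no seasonal cycle).
    """
    t = daily["T_air"].to_numpy(dtype=float)
    doy = daily["doy"].to_numpy(dtype=int)
    p25, p75 = np.percentile(t[np.isfinite(t)], [25, 75])

    clim = pd.Series(t).groupby(doy).mean()
    full = clim.reindex(range(1, 367)).interpolate(limit_direction="both")
    arr = full.to_numpy()
    # circular running mean so the year boundary does not bias winter
    k = smooth_days
    pad = np.concatenate([arr[-k:], arr, arr[:k]])
    kernel = np.ones(2 * k + 1) / (2 * k + 1)
    smooth = np.convolve(pad, kernel, mode="same")[k:-k]

    above75 = smooth > p75
    below25 = smooth < p25
    if not above75.any() or not below25.any():
        raise ValueError("no seasonal cycle: climatology never crosses the "
                         "25th/75th temperature percentiles")

    peak = int(np.argmax(smooth))
    if not above75[peak]:
        raise ValueError("no seasonal cycle: annual maximum below the 75th percentile")
    # summer: contiguous block above P75 containing the annual maximum
    s0 = peak
    while s0 > 0 and above75[s0 - 1]:
        s0 -= 1
    s1 = peak
    while s1 < len(smooth) - 1 and above75[s1 + 1]:
        s1 += 1
    # spring starts after the last winter day before summer
    w_end = s0 - 1
    while w_end >= 0 and not below25[w_end]:
        w_end -= 1
    if w_end < 0:
        raise ValueError("no winter period found before summer")
    # autumn ends before the first winter day after summer
    w_start = s1 + 1
    while w_start < len(smooth) and not below25[w_start]:
        w_start += 1
    if w_start >= len(smooth):
        raise ValueError("no winter period found after summer")

    return SeasonWindows(
        spring=(w_end + 2, s0),          # doy is 1-based
        summer=(s0 + 1, s1 + 1),
        autumn=(s1 + 2, w_start),
    )


def interpolate_lai_fpar(eight_day: pd.DataFrame, window: int = 15,
                         polyorder: int = 2) -> pd.DataFrame:
    """Daily LAI and FPAR from an 8-day series.

    Linear interpolation to daily steps followed by Savitzky-Golay
    smoothing (constants and low-order polynomials are preserved), with
    outputs clipped to physical ranges.  ``eight_day`` needs columns
    ``doy``, ``LAI``, ``FPAR`` and strictly increasing doy.
    """
    doy = eight_day["doy"].to_numpy(dtype=float)
    if len(doy) < 2:
        raise ValueError("need at least two 8-day points")
    if np.any(np.diff(doy) <= 0):
        raise ValueError("8-day timestamps must be strictly increasing")
    days = np.arange(int(doy[0]), int(doy[-1]) + 1)
    out = {}
    for col, lo, hi in (("LAI", 0.0, np.inf), ("FPAR", 0.0, 1.0)):
        lin = np.interp(days, doy, eight_day[col].to_numpy(dtype=float))
        if len(lin) >= window:
            lin = savgol_filter(lin, window_length=window, polyorder=polyorder)
        out[col] = np.clip(lin, lo, hi)
    return pd.DataFrame(out, index=pd.Index(days, name="doy"))
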