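"""Assembly of the daily modelling dataset from half-hourly drivers.

Glue shared by the synthetic forward simulation and the command-line
pipeline: QC + daytime aggregation, season identification, daily LAI/FPAR,
the two-leaf radiation integrals and the aerodynamic conductance, all
joined into one daily table ready for calibration.
"""

from __future__ import annotations

import pandas as pd

from . import canopy_radiation as cr
from . import preprocess as pp
from . import water_flux as wf
from .params import SeasonWindows

__all__ = ["daily_lai_for_dates", "build_daily_dataset"]


def daily_lai_for_dates(eight_day: pd.DataFrame, dates: pd.DatetimeIndex):
    """Interpolate an 8-day LAI/FPAR table to the given dates.

    Linear interpolation + Savitzky-Golay smoothing over day-of-year,
    edge-extended so every calendar day (including doy 366) has a value.
    """
    daily = pp.interpolate_lai_fpar(eight_day)
    daily = daily.reindex(range(1, 367)).ffill().bfill()
    doys = pd.DatetimeIndex(dates).dayofyear
    lai = pd.Series(daily["LAI"].to_numpy()[doys - 1], index=dates)
    fpar = pd.Series(daily["FPAR"].to_numpy()[doys - 1], index=dates)
    return lai, fpar


def build_daily_dataset(
    hh: pd.DataFrame,
    eight_day_lai: pd.DataFrame,
    latitude: float,
    measurement_height: float,
    canopy_height: float,
    radiation_config: cr.RadiationConfig = cr.RadiationConfig(),
) -> tuple[pd.DataFrame, SeasonWindows]:
    """Daily driver/observation table plus season windows.

    The returned table carries daytime-mean states, daily integrals
    (GPP_obs, ET_obs, A_MJ, APARs, PAR), LAI/FPAR, the aerodynamic
    conductance ``Ga_mol`` and a ``season`` label per day.
    """
    qc = pp.qc_filter_daytime(hh)
    daily = pp.aggregate_daily(qc)
    windows = pp.identify_seasons(daily)

    dates = pd.DatetimeIndex(daily.index)
    lai, fpar = daily_lai_for_dates(eight_day_lai, dates)
    rad = cr.daily_two_leaf_radiation(qc, latitude, lai, fpar, radiation_config)
    daily = daily.join(rad)
    daily["LAI"] = lai
    daily["FPAR"] = fpar
    daily["season"] = [windows.season_of_doy(int(d)) for d in daily["doy"]]
    daily["Ga_mol"] = wf.aerodynamic_conductance(
        daily["wind"].to_numpy(), measurement_height, canopy_height,
        daily["T_air"].to_numpy(),
    )
    return daily, windows
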