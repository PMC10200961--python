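"""Shared domain types: physiological parameter sets, season windows, metrics.

Unit conventions used throughout the package:

* light-use efficiencies ``eps_msu``/``eps_msh`` in gC MJ⁻¹ (per unit APAR),
* Ball-Berry slopes ``g_su``/``g_sh`` dimensionless,
* conductances in mol m⁻² s⁻¹ unless a name says otherwise,
* daily energy fluxes in MJ m⁻² d⁻¹, water fluxes in mm d⁻¹,
* carbon fluxes in gC m⁻² d⁻¹ (daily) or µmol CO₂ m⁻² s⁻¹ (rates).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

__all__ = [
    "PARAM_BOUNDS",
    "GS_MIN",
    "ParameterSet",
    "SeasonWindows",
    "MetricSet",
]

#: Calibration box constraints: maximum LUE of sunlit leaves is much lower
#: than that of shaded leaves (sunlit leaves saturate under high light),
#: Ball-Berry slopes share one broad range for both leaf classes.
PARAM_BOUNDS: Dict[str, Tuple[float, float]] = {
    "eps_msu": (0.34, 1.50),  # gC MJ-1
    "eps_msh": (2.71, 4.79),  # gC MJ-1
    "g_su": (0.0, 60.0),
    "g_sh": (0.0, 60.0),
}

#: Residual surface conductance (soil evaporative background) in
#: mol m-2 s-1; the intercept of the two-leaf Ball-Berry relation.
GS_MIN: float = 0.001

_SEASON_LABELS = ("spring", "summer", "autumn", "all")


@dataclass(frozen=True)
class ParameterSet:
    """The four calibrated physiological parameters of the model chain.

    ``eps_msu``/``eps_msh`` are the maximum light-use efficiencies of the
    representative sunlit and shaded leaf (gC MJ⁻¹); ``g_su``/``g_sh`` are
    the Ball-Berry slopes (sensitivity of stomatal conductance to the
    photosynthesis × RH / Ca index) for the two leaf classes.
    """

    eps_msu: float
    eps_msh: float
    g_su: float
    g_sh: float
    season_label: str = "all"

    def __post_init__(self) -> None:
        if self.season_label not in _SEASON_LABELS:
            raise ValueError(
                f"season_label must be one of {_SEASON_LABELS}, "
                f"got {self.season_label!r}"
            )
        for name in ("eps_msu", "eps_msh", "g_su", "g_sh"):
            lo, hi = PARAM_BOUNDS[name]
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(
                    f"{name}={v} outside allowed range [{lo}, {hi}]"
                )

    def as_array(self):
        import numpy as np

        return np.array([self.eps_msu, self.eps_msh, self.g_su, self.g_sh])


@dataclass(frozen=True)
class SeasonWindows:
    """Day-of-year windows of the three growing-season segments.

    Windows are inclusive ``(doy_start, doy_end)`` pairs and must be
    contiguous: spring ends the day before summer starts, summer the day
    before autumn starts.  Days outside all three windows are winter.
    """

    spring: Tuple[int, int]
    summer: Tuple[int, int]
    autumn: Tuple[int, int]

    def __post_init__(self) -> None:
        for name in ("spring", "summer", "autumn"):
            a, b = getattr(self, name)
            if not a <= b:
                raise ValueError(f"{name} window {a}-{b} is empty")
        if self.spring[1] + 1 != self.summer[0]:
            raise ValueError("spring and summer windows are not contiguous")
        if self.summer[1] + 1 != self.autumn[0]:
            raise ValueError("summer and autumn windows are not contiguous")

    def season_of_doy(self, doy: int) -> str:
        """Return 'spring' / 'summer' / 'autumn' / 'winter' for a day of year."""
        if self.spring[0] <= doy <= self.spring[1]:
            return "spring"
        if self.summer[0] <= doy <= self.summer[1]:
            return "summer"
        if self.autumn[0] <= doy <= self.autumn[1]:
            return "autumn"
        return "winter"

    @property
    def growing_season(self) -> Tuple[int, int]:
        return (self.spring[0], self.autumn[1])


@dataclass(frozen=True)
class MetricSet:
    """Model-evaluation statistics for one predicted/observed pairing.

    ``aic`` is n·ln(SSE/n) + 2k, ``rmse`` is in the units of the target
    variable, ``r`` is Pearson correlation and ``d`` is Willmott's index
    of agreement in [0, 1].
    """

    aic: float
    rmse: float
    r: float
    d: float
    n: int

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ValueError("rmse must be non-negative")
        if not (-1.0 - 1e-12 <= self.r <= 1.0 + 1e-12):
            raise ValueError("r must lie in [-1, 1]")
        if not (0.0 <= self.d <= 1.0 + 1e-12):
            raise ValueError("d must lie in [0, 1]")
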