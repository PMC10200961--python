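"""Shared fixtures: synthetic sites generated once per session."""

import numpy as np
import pandas as pd
import pytest

from twoleaf import calibration as cal
from twoleaf import synthetic_flux as sf


@pytest.fixture(scope="session")
def clean_site():
    """Noise-free 3-year synthetic site: the self-consistency fixture —
    every downstream module must reproduce its truth columns exactly."""
    spec = sf.SyntheticSiteSpec(years=3, noise=(0.0, 0.0), seed=42)
    daily, hh, windows = sf.forward_simulate(spec)
    return spec, daily, hh, windows


@pytest.fixture(scope="session")
def noisy_site():
    """3-year site at the default observation noise."""
    spec = sf.SyntheticSiteSpec(years=3, seed=42)
    daily, hh, windows = sf.forward_simulate(spec)
    return spec, daily, hh, windows


@pytest.fixture(scope="session")
def clean_data(clean_site):
    spec, daily, hh, windows = clean_site
    return spec, cal.CalibrationData(daily, windows), daily


@pytest.fixture(scope="session")
def one_year_site():
    spec = sf.SyntheticSiteSpec(years=1, noise=(0.0, 0.0), seed=7)
    daily, hh, windows = sf.forward_simulate(spec)
    return spec, daily, hh, windows
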