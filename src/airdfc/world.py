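"""Synthetic air-pollution monitoring world.

Generates (i) a daily monitoring panel — site x date x pollutant
concentrations built as site offset x seasonal sinusoid x exponentiated
AR(1) noise, so concentrations are strictly positive — and (ii) an annual
pollutant surface assigning land-use-regression-style annual means to
addresses, correlated across pollutants and optionally tilted along a
socioeconomic gradient (the planted confounding pathway).

Traffic pollutants (NOx, NO2, PM2.5 absorbance) share one latent daily
factor and the particulate-mass pollutants (PM2.5, PM10, PMcoarse) another,
reproducing the empirical pattern of high (>0.75) within-group temporal
correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

POLLUTANTS = ("NO2", "NOX", "PM10", "PM25", "PMCOARSE", "PM25ABS")

#: μg/m³ except PM25ABS (1e-5 m^-1); levels in the range reported for
#: Dutch urban cohorts (median NOx ~36-47, PM2.5 ~11-12 μg/m³)
DEFAULT_ANNUAL_MEAN = {
    "NO2": 25.0,
    "NOX": 40.0,
    "PM10": 18.0,
    "PM25": 11.5,
    "PMCOARSE": 6.5,
    "PM25ABS": 1.2,
}

_FACTOR_GROUP = {
    "NO2": 0,
    "NOX": 0,
    "PM25ABS": 0,
    "PM10": 1,
    "PM25": 1,
    "PMCOARSE": 1,
}


@dataclass
class MonitoringWorld:
    """Daily monitoring panel plus the parameters that generated it."""

    panel: pd.DataFrame  # columns: site, date, pollutant, concentration
    sites: tuple[str, ...]
    pollutants: tuple[str, ...]
    dates: pd.DatetimeIndex
    reference_period: tuple[pd.Timestamp, pd.Timestamp]
    params: dict = field(default_factory=dict)


def _ar1(n: int, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Standardized AR(1) path (unit marginal variance when |rho|<1)."""
    innov_sd = np.sqrt(1.0 - rho**2) if abs(rho) < 1 else 0.0
    x = np.empty(n)
    x[0] = rng.standard_normal()
    eps = rng.standard_normal(n)
    for t in range(1, n):
        x[t] = rho * x[t - 1] + innov_sd * eps[t]
    return x


def simulate_monitoring_world(
    n_sites: int = 7,
    pollutants: tuple[str, ...] = POLLUTANTS,
    start: str = "2009-01-01",
    n_days: int = 365 * 6,
    seasonal_amplitude: float = 0.25,
    ar1_coefficient: float = 0.8,
    noise_sd: float = 0.3,
    site_offset_sd: float = 0.15,
    site_noise_sd: float = 0.08,
    factor_loading: float = 0.92,
    seed: int = 0,
) -> MonitoringWorld:
    """Simulate the routine monitoring network's daily panel.

    The first 365 days serve as the reference measurement period against
    which daily-to-annual ratios are formed.
    """
    if n_sites < 1 or not pollutants:
        raise ValueError("need at least one site and one pollutant")
    if n_days < 365:
        raise ValueError("need at least one year of days")
    for p in pollutants:
        if p not in POLLUTANTS:
            raise ValueError(f"unknown pollutant {p!r}")
    rng = np.random.default_rng(seed)
    dates = pd.date_range(start, periods=n_days, freq="D")
    sites = tuple(f"site{j+1}" for j in range(n_sites))

    doy = dates.dayofyear.to_numpy()
    seasonal = 1.0 + seasonal_amplitude * np.cos(2 * np.pi * (doy - 15) / 365.25)

    factors = {g: _ar1(n_days, ar1_coefficient, rng) for g in (0, 1)}
    frames = []
    for p in pollutants:
        own = _ar1(n_days, ar1_coefficient, rng)
        shared = factors[_FACTOR_GROUP[p]]
        e = factor_loading * shared + np.sqrt(1 - factor_loading**2) * own
        common = DEFAULT_ANNUAL_MEAN[p] * seasonal * np.exp(noise_sd * e - 0.5 * noise_sd**2)
        offsets = np.exp(rng.normal(0.0, site_offset_sd, size=n_sites))
        for s_i, site in enumerate(sites):
            site_eps = np.exp(site_noise_sd * rng.standard_normal(n_days) - 0.5 * site_noise_sd**2) if site_noise_sd > 0 else 1.0
            frames.append(
                pd.DataFrame(
                    {
                        "site": site,
                        "date": dates,
                        "pollutant": p,
                        "concentration": offsets[s_i] * common * site_eps,
                    }
                )
            )
    panel = pd.concat(frames, ignore_index=True)
    reference_period = (dates[0], dates[364])
    params = {
        "n_sites": n_sites,
        "pollutants": list(pollutants),
        "start": str(dates[0].date()),
        "n_days": n_days,
        "seasonal_amplitude": seasonal_amplitude,
        "ar1_coefficient": ar1_coefficient,
        "noise_sd": noise_sd,
        "site_offset_sd": site_offset_sd,
        "site_noise_sd": site_noise_sd,
        "factor_loading": factor_loading,
        "seed": seed,
    }
    return MonitoringWorld(panel, sites, tuple(pollutants), dates, reference_period, params)


def simulate_annual_surface(
    addresses: list[str] | int,
    pollutants: tuple[str, ...] = POLLUTANTS,
    spatial_sd: float = 0.18,
    cross_loading: float = 0.8,
    ses: np.ndarray | None = None,
    ses_gradient: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Annual LUR-style means per address (rows) and pollutant (columns).

    A shared log-normal spatial factor correlates pollutants within an
    address; ``ses_gradient`` tilts concentrations multiplicatively along a
    standardized socioeconomic score (negative gradient = cleaner air in
    better-off addresses), which is the planted exposure-confounding path.
    """
    rng = np.random.default_rng(seed)
    if isinstance(addresses, int):
        addresses = [f"addr{j+1}" for j in range(addresses)]
    n = len(addresses)
    if ses is None:
        ses = np.zeros(n)
    ses = np.asarray(ses, dtype=float)
    if ses.shape != (n,):
        raise ValueError("ses must have one value per address")
    shared = rng.standard_normal(n)
    data = {}
    for p in pollutants:
        own = rng.standard_normal(n)
        z = cross_loading * shared + np.sqrt(1 - cross_loading**2) * own
        tilt = np.clip(1.0 + ses_gradient * ses, 0.2, None)
        data[p] = DEFAULT_ANNUAL_MEAN[p] * np.exp(spatial_sd * z - 0.5 * spatial_sd**2) * tilt
    return pd.DataFrame(data, index=pd.Index(addresses, name="address"))
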