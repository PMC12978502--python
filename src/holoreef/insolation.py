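"""Daily, monthly and annual mean insolation at a latitude.

Geometric (top-of-atmosphere) daily-mean flux from total solar irradiance
(TSI) and the orbital elements: the standard formulation in which the
declination follows from obliquity and true solar longitude, the sun-hour
angle handles polar day and night, and the Earth--Sun distance follows
Kepler's relation through eccentricity and the longitude of perihelion.
No atmospheric attenuation is applied; TSI here stands in for
photosynthetically available radiation at the sea surface.

The calendar is a fixed 365-day year with standard month lengths and the
vernal equinox at day 80.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from holoreef.orbital import OrbitalElements, orbital_elements

#: Reference total solar irradiance, W/m^2; anomalies are offsets from this.
TSI_REFERENCE = 1365.0

MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31], dtype=float)
#: Day-of-year of each month's midpoint (Jan 15.5, Feb 45.0, ...).
MONTH_MIDPOINTS = np.cumsum(MONTH_LENGTHS) - MONTH_LENGTHS / 2.0
DAYS_PER_YEAR = 365.0
VERNAL_EQUINOX_DAY = 80.0


def solar_longitude_of_day(day, elements: OrbitalElements) -> np.ndarray:
    """True solar longitude (radians) for a calendar day of the 365-day year.

    Uses the classical series inversion of Kepler's equation: the mean
    longitude advances uniformly in time, anchored so that the true
    longitude is zero at the vernal equinox (day 80), and the true
    longitude follows from the equation of center expanded to third order
    in eccentricity.
    """
    day = np.asarray(day, dtype=float)
    e = np.asarray(elements.eccentricity, dtype=float)
    w = np.asarray(elements.perihelion_geocentric_rad, dtype=float)
    beta = np.sqrt(1.0 - e**2)
    # Mean longitude of the vernal equinox (true longitude zero).
    lam_m0 = -2.0 * (
        (e / 2.0 + e**3 / 8.0) * (1.0 + beta) * np.sin(-w)
        - e**2 / 4.0 * (0.5 + beta) * np.sin(-2.0 * w)
        + e**3 / 8.0 * (1.0 / 3.0 + beta) * np.sin(-3.0 * w)
    )
    lam_m = lam_m0 + (day - VERNAL_EQUINOX_DAY) * 2.0 * np.pi / DAYS_PER_YEAR
    nu_m = lam_m - w
    lam = (
        lam_m
        + (2.0 * e - e**3 / 4.0) * np.sin(nu_m)
        + 1.25 * e**2 * np.sin(2.0 * nu_m)
        + (13.0 / 12.0) * e**3 * np.sin(3.0 * nu_m)
    )
    return np.mod(lam, 2.0 * np.pi)


def daily_mean_insolation(latitude, solar_longitude, tsi, elements: OrbitalElements):
    """Daily-mean insolation (W/m^2) at ``latitude`` for a solar longitude.

    ``W = (tsi/pi) * (dbar/d)^2 * (H0 sin(phi) sin(delta)
    + cos(phi) cos(delta) sin(H0))`` with declination ``delta`` from
    obliquity and solar longitude, and the sun-hour angle ``H0`` clamped to
    [0, pi] so polar night yields exactly zero and polar day the full
    24-hour integral.  Broadcasts over all arguments.
    """
    phi = np.deg2rad(np.asarray(latitude, dtype=float))
    lam = np.asarray(solar_longitude, dtype=float)
    tsi = np.asarray(tsi, dtype=float)
    if np.any(tsi <= 0):
        raise ValueError("tsi must be positive")
    e = np.asarray(elements.eccentricity, dtype=float)
    eps = np.deg2rad(np.asarray(elements.obliquity_deg, dtype=float))
    w = np.asarray(elements.perihelion_geocentric_rad, dtype=float)

    sin_delta = np.sin(eps) * np.sin(lam)
    delta = np.arcsin(np.clip(sin_delta, -1.0, 1.0))
    # Inverse-square distance factor from Kepler's relation.
    dist2 = ((1.0 + e * np.cos(lam - w)) / (1.0 - e**2)) ** 2
    cos_h0 = np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0)
    h0 = np.arccos(cos_h0)
    flux = (tsi / np.pi) * dist2 * (
        h0 * np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.sin(h0)
    )
    return np.maximum(flux, 0.0)


def monthly_mean_insolation(latitude, age, tsi) -> np.ndarray:
    """Insolation at the 12 month midpoints; last axis indexes the month.

    ``latitude``, ``age`` and ``tsi`` broadcast against each other.
    """
    lat, age_b, tsi_b = np.broadcast_arrays(
        np.asarray(latitude, dtype=float),
        np.asarray(age, dtype=float),
        np.asarray(tsi, dtype=float),
    )
    shape = lat.shape
    lat, age_b, tsi_b = lat.ravel(), age_b.ravel(), tsi_b.ravel()
    elements = orbital_elements(age_b)
    months = np.empty((12, lat.size))
    for m, day in enumerate(MONTH_MIDPOINTS):
        lam = solar_longitude_of_day(day, elements)
        months[m] = daily_mean_insolation(lat, lam, tsi_b, elements)
    return np.moveaxis(months, 0, -1).reshape(shape + (12,))


def annual_mean_insolation(latitude, age, tsi):
    """Month-length-weighted annual mean insolation, W/m^2.

    ``latitude``, ``age`` and ``tsi`` broadcast against each other; ``tsi``
    is the absolute irradiance (reference 1365 W/m^2 plus anomaly).
    """
    flux = monthly_mean_insolation(latitude, age, tsi)
    weights = MONTH_LENGTHS / MONTH_LENGTHS.sum()
    out = (flux * weights).sum(axis=-1)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class InsolationResult:
    """Daily, monthly and annual insolation at one latitude and age."""

    latitude: float
    age: float
    tsi: float                      # absolute, W/m^2
    daily: np.ndarray               # by day of the 365-day year
    monthly: np.ndarray             # at the 12 month midpoints
    annual: float                   # month-length-weighted mean


def insolation_summary(latitude: float, age: float, tsi_anomaly: float = 0.0) -> InsolationResult:
    """Full insolation profile from a TSI anomaly (vs 1365 W/m^2)."""
    tsi = TSI_REFERENCE + tsi_anomaly
    elements = orbital_elements(age)
    days = np.arange(1.0, DAYS_PER_YEAR + 1.0)
    lam = solar_longitude_of_day(days, elements)
    daily = daily_mean_insolation(latitude, lam, tsi, elements)
    monthly = monthly_mean_insolation(latitude, age, tsi)
    return InsolationResult(
        latitude=float(latitude), age=float(age), tsi=float(tsi),
        daily=daily, monthly=np.atleast_1d(monthly).ravel(),
        annual=float(annual_mean_insolation(latitude, age, tsi)),
    )
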