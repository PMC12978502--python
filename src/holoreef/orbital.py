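"""Orbital elements of Earth through the late Quaternary.

Implements the classical trigonometric-series solution (Berger-type) for
eccentricity ``e``, obliquity ``epsilon`` and the longitude of perihelion,
from coefficient tables shipped with the package.  The climatic precession
index ``e * sin(varpi)`` is derived from these, with ``varpi`` the
heliocentric longitude of perihelion measured from the moving vernal
equinox.

Ages follow the paleo convention: calibrated years before present, where
"present" is 1950 CE and negative ages are years after 1950.  Over the
Holocene the truncated series used here differs from the full solution by
far less than the 0.1-degree level at which obliquity is usually quoted.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

ARCSEC = np.pi / (180.0 * 3600.0)  # arcseconds -> radians

#: Constant term of the obliquity expansion, degrees.
EPS_STAR_DEG = 23.320556
#: Linear rate of general precession in longitude, arcsec / yr.
PSI_BAR_ARCSEC = 50.439273
#: Constant of the general-precession expansion, degrees.
ZETA_DEG = 3.392506

#: Validity window of the implemented (truncated) series, years.
MAX_AGE = 1_000_000.0


def _load_table(name: str) -> np.ndarray:
    text = resources.files("holoreef.data").joinpath(name).read_text()
    rows = [
        ln for ln in text.splitlines()
        if ln and not ln.startswith("#") and ln[0].isdigit()
    ]
    return np.loadtxt(rows, delimiter=",", usecols=(1, 2, 3), ndmin=2)


_OBL = _load_table("obliquity_series.csv")
_ECC = _load_table("eccentricity_series.csv")
_PRE = _load_table("precession_series.csv")


@dataclass(frozen=True)
class OrbitalElements:
    """Orbital elements at one or more ages.

    Attributes
    ----------
    age : ndarray
        Calibrated years BP (1950 CE).
    eccentricity : ndarray
        Orbital eccentricity, dimensionless.
    obliquity_deg : ndarray
        Axial tilt, degrees.
    perihelion_rad : ndarray
        Heliocentric longitude of perihelion from the moving vernal
        equinox, radians in [0, 2*pi).  The geocentric longitude (the solar
        longitude at which Earth is closest to the Sun, ~283 deg today) is
        this value plus pi.
    precession_index : ndarray
        Climatic precession, ``e * sin(perihelion)``.
    """

    age: np.ndarray
    eccentricity: np.ndarray
    obliquity_deg: np.ndarray
    perihelion_rad: np.ndarray
    precession_index: np.ndarray

    @property
    def perihelion_geocentric_rad(self) -> np.ndarray:
        return np.mod(self.perihelion_rad + np.pi, 2.0 * np.pi)


def orbital_elements(age) -> OrbitalElements:
    """Evaluate the orbital solution at ``age`` (yr BP; scalar or array).

    Raises
    ------
    ValueError
        If any age lies outside the +/- 1 Myr validity window of the series.
    """
    age_arr = np.atleast_1d(np.asarray(age, dtype=float))
    if not np.all(np.isfinite(age_arr)):
        raise ValueError("ages must be finite")
    if np.any(np.abs(age_arr) > MAX_AGE):
        raise ValueError(
            f"age outside the +/-{MAX_AGE:.0f} yr validity window of the orbital series"
        )
    t = -age_arr[:, None]  # years from 1950, positive toward the future

    # Obliquity.
    amp, rate, phase = _OBL[:, 0], _OBL[:, 1], _OBL[:, 2]
    arg = rate[None, :] * ARCSEC * t + np.deg2rad(phase)[None, :]
    eps = EPS_STAR_DEG + (amp[None, :] * np.cos(arg)).sum(axis=1) / 3600.0

    # Eccentricity / fixed-equinox perihelion vector.
    amp, rate, phase = _ECC[:, 0], _ECC[:, 1], _ECC[:, 2]
    arg = rate[None, :] * ARCSEC * t + np.deg2rad(phase)[None, :]
    esin = (amp[None, :] * np.sin(arg)).sum(axis=1)
    ecos = (amp[None, :] * np.cos(arg)).sum(axis=1)
    ecc = np.hypot(esin, ecos)
    pi_fixed = np.arctan2(esin, ecos)

    # General precession moves the equinox; perihelion longitudes measured
    # from the moving equinox gain psi(t).
    amp, rate, phase = _PRE[:, 0], _PRE[:, 1], _PRE[:, 2]
    arg = rate[None, :] * ARCSEC * t + np.deg2rad(phase)[None, :]
    psi = (
        PSI_BAR_ARCSEC * ARCSEC * t[:, 0]
        + np.deg2rad(ZETA_DEG)
        + (amp[None, :] * np.sin(arg)).sum(axis=1) * ARCSEC
    )
    varpi = np.mod(pi_fixed + psi, 2.0 * np.pi)

    out = OrbitalElements(
        age=age_arr,
        eccentricity=ecc,
        obliquity_deg=eps,
        perihelion_rad=varpi,
        precession_index=ecc * np.sin(varpi),
    )
    return out
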