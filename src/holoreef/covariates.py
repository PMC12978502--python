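"""Per-sample environmental covariates from paleo records.

Each growth sample spans an interval [T1, T2] (yr BP).  Proxy records are
linearly interpolated inside their span and extended with the nearest
value outside it; sample-level covariates are means over an age grid at
the record's native resolution.  Specific rules:

* insolation/TSI: grid at 22-yr steps, annual-mean insolation at the site
  latitude per age point, averaged (in-record points only when the sample
  partially overlaps the TSI record);
* CO2 and ice-rafted debris: same grid-mean kernel at 8-yr and 70-yr steps;
* SST: nearest valid ~1-degree grid cell by great-circle distance, its
  series averaged over the segment with interpolated endpoint values;
* sea-level rate: mean year-to-year difference of the submergence curve
  interpolated at integer years, in mm/yr (positive = rising);
* volcanic forcing: monthly stratospheric aerosol optical depth -> annual
  means -> latitude interpolation -> 25 W/m^2 per unit optical depth ->
  sums over rolling 20-yr windows inside the segment -> mean of windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from holoreef.insolation import TSI_REFERENCE, annual_mean_insolation

#: Radiative forcing per unit stratospheric aerosol optical depth, W/m^2.
SAOD_FORCING_SCALE = 25.0
#: Length of the rolling cumulative volcanic-forcing window, years.
VOLCANIC_WINDOW_YEARS = 20

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# containers

@dataclass
class PaleoSeries:
    """An irregular age/value proxy record.

    ``native_step`` is the record's typical temporal resolution in years
    (22 for the TSI record, 8 for CO2, 70 for ice-rafted debris) and sets
    the within-segment averaging grid.
    """

    ages: np.ndarray
    values: np.ndarray
    native_step: float
    units: str = ""
    name: str = ""

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.ages.size == 0:
            raise ValueError(f"empty paleo series {self.name!r}")
        if self.ages.size != self.values.size:
            raise ValueError("ages and values must have equal length")
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError(f"ages of series {self.name!r} must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in series {self.name!r}")

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# units: {self.units}\n# native_step_yr: {self.native_step}\n")
            pd.DataFrame({"age_ybp": self.ages, "value": self.values}).to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path, native_step: float | None = None, name: str = "") -> "PaleoSeries":
        units, step = "", native_step
        with open(path) as fh:
            lines = fh.readlines()
        for ln in lines:
            if ln.startswith("# units:"):
                units = ln.split(":", 1)[1].strip()
            elif ln.startswith("# native_step_yr:"):
                step = float(ln.split(":", 1)[1])
        body = [ln for ln in lines if not ln.startswith("#")]
        df = pd.read_csv(pd.io.common.StringIO("".join(body)))
        if step is None:
            raise ValueError("native_step not given and not recorded in file")
        return cls(df["age_ybp"].to_numpy(), df["value"].to_numpy(), step, units, name)


@dataclass
class SaodRecord:
    """Monthly stratospheric aerosol optical depth by 10-degree latitude band."""

    ages_monthly: np.ndarray          # yr BP, ascending, fractional years
    band_lats: np.ndarray             # band-center latitudes, degrees
    saod: np.ndarray                  # (n_months, n_bands), >= 0

    _annual_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.ages_monthly = np.asarray(self.ages_monthly, dtype=float)
        self.band_lats = np.asarray(self.band_lats, dtype=float)
        self.saod = np.asarray(self.saod, dtype=float)
        if np.any(self.saod < 0):
            raise ValueError("stratospheric aerosol optical depth must be >= 0")
        if self.saod.shape != (self.ages_monthly.size, self.band_lats.size):
            raise ValueError("saod must be (n_months, n_bands)")

    def annual(self) -> tuple[np.ndarray, np.ndarray]:
        """Annual-mean optical depth per band; years are integer yr BP."""
        if "annual" not in self._annual_cache:
            yr = np.floor(self.ages_monthly).astype(int)
            y0 = yr.min()
            idx = yr - y0
            counts = np.bincount(idx)
            sums = np.zeros((counts.size, self.band_lats.size))
            np.add.at(sums, idx, self.saod)
            have = counts > 0
            years = np.nonzero(have)[0] + y0
            annual = sums[have] / counts[have, None]
            self._annual_cache["annual"] = (years.astype(float), annual)
        return self._annual_cache["annual"]

    def annual_forcing_at(self, latitude: float) -> tuple[np.ndarray, np.ndarray]:
        """Annual volcanic forcing (W/m^2) at a site latitude.

        Linear interpolation between the two flanking band centers,
        clamped at the outermost bands; scaled by 25 W/m^2 per unit SAOD.
        """
        years, annual = self.annual()
        lat = float(latitude)
        vals = np.empty(annual.shape[0])
        # np.interp per row is slow; interpolate the band axis once.
        j = np.searchsorted(self.band_lats, lat)
        if j == 0:
            vals = annual[:, 0]
        elif j >= self.band_lats.size:
            vals = annual[:, -1]
        else:
            l0, l1 = self.band_lats[j - 1], self.band_lats[j]
            f = (lat - l0) / (l1 - l0)
            vals = (1 - f) * annual[:, j - 1] + f * annual[:, j]
        return years, SAOD_FORCING_SCALE * vals

    def to_csv(self, path) -> None:
        n_m, n_b = self.saod.shape
        df = pd.DataFrame({
            "age_ybp": np.repeat(self.ages_monthly, n_b),
            "lat_band": np.tile(self.band_lats, n_m),
            "saod_monthly": self.saod.ravel(),
        })
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SaodRecord":
        df = pd.read_csv(path)
        ages = np.unique(df["age_ybp"].to_numpy())
        bands = np.unique(df["lat_band"].to_numpy())
        piv = df.pivot_table(index="age_ybp", columns="lat_band", values="saod_monthly")
        return cls(ages, bands, piv.to_numpy())


@dataclass
class SstGrid:
    """Gridded SST reconstruction: (lat, lon, age) with missing cells."""

    lats: np.ndarray
    lons: np.ndarray
    ages: np.ndarray                  # yr BP, ascending (200-yr steps)
    sst: np.ndarray                   # (n_lat, n_lon, n_age), NaN = missing

    def __post_init__(self):
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        self.ages = np.asarray(self.ages, dtype=float)
        self.sst = np.asarray(self.sst, dtype=float)
        present = self.sst[np.isfinite(self.sst)]
        if present.size and (present.min() < -5 or present.max() > 40):
            raise ValueError("SST outside plausible ocean range [-5, 40] degC")

    def valid_mask(self) -> np.ndarray:
        """Cells with a complete (all-age finite) series."""
        return np.all(np.isfinite(self.sst), axis=2)

    def to_netcdf(self, path) -> None:
        import xarray as xr

        ds = xr.Dataset(
            {"sst": (("lat", "lon", "age"), self.sst)},
            coords={"lat": self.lats, "lon": self.lons, "age": self.ages},
        )
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "SstGrid":
        import xarray as xr

        with xr.open_dataset(path, engine="scipy") as ds:
            return cls(
                ds["lat"].to_numpy(), ds["lon"].to_numpy(),
                ds["age"].to_numpy(), ds["sst"].to_numpy(),
            )


@dataclass
class SeaLevelCurve:
    """Regional relative sea level as submergence (m, positive = deeper)."""

    region: str
    ages: np.ndarray
    submergence_m: np.ndarray

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)
        self.submergence_m = np.asarray(self.submergence_m, dtype=float)
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError(f"sea-level curve ages must be strictly increasing ({self.region})")

    def to_csv(self, path) -> None:
        pd.DataFrame({"age_ybp": self.ages, "level_m": self.submergence_m}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, region: str) -> "SeaLevelCurve":
        df = pd.read_csv(path)
        return cls(region, df["age_ybp"].to_numpy(), df["level_m"].to_numpy())


@dataclass
class Environment:
    """The full covariate input bundle for one analysis."""

    tsi: PaleoSeries                  # anomaly vs 1365 W/m^2, 22-yr step
    co2: PaleoSeries                  # ppmv, 8-yr step
    ird: PaleoSeries                  # % lithic grains, 70-yr step
    saod: SaodRecord
    sst: SstGrid
    sea_level: dict[str, SeaLevelCurve]   # keyed by region


# ---------------------------------------------------------------------------
# interpolation kernels

def interp_at(series: PaleoSeries, query_ages) -> np.ndarray:
    """Piecewise-linear interpolation, nearest-value beyond the record."""
    q = np.asarray(query_ages, dtype=float)
    if not np.all(np.isfinite(q)):
        raise ValueError("query ages must be finite")
    return np.interp(q, series.ages, series.values)


def segment_grid(t1: float, t2: float, step: float) -> np.ndarray:
    """Age grid T1, T1+step, ... capped at T2 (T2 always included).

    Segments shorter than one step reduce to the endpoint ages alone.
    """
    if t2 <= t1:
        raise ValueError("T2 must exceed T1")
    if step <= 0:
        raise ValueError("step must be positive")
    inner = np.arange(t1, t2, step)
    # guard against an arange point landing on T2 within rounding
    inner = inner[(t2 - inner) > 1e-9 * max(step, abs(t2), 1.0)]
    return np.append(inner, t2)


def _grid_in_record(t1: float, t2: float, series: PaleoSeries) -> np.ndarray:
    """Averaging grid restricted to in-record points when partially overlapping."""
    grid = segment_grid(t1, t2, series.native_step)
    lo, hi = series.ages[0], series.ages[-1]
    inside = grid[(grid >= lo) & (grid <= hi)]
    return inside if inside.size else grid  # wholly outside: nearest-value extension


def sample_mean_series(t1: float, t2: float, series: PaleoSeries) -> float:
    """Mean of the series interpolated on the segment's native-step grid."""
    pts = _grid_in_record(t1, t2, series)
    return float(interp_at(series, pts).mean())


def sample_insolation(
    t1: float, t2: float, latitude: float, tsi_series: PaleoSeries
) -> tuple[float, float]:
    """Sample-level mean annual insolation and mean TSI (both W/m^2).

    TSI anomalies are interpolated on the 22-yr segment grid, converted to
    absolute irradiance against 1365 W/m^2, run through the annual-mean
    insolation at the site latitude per age point, and averaged.
    """
    pts = _grid_in_record(t1, t2, tsi_series)
    tsi_abs = TSI_REFERENCE + interp_at(tsi_series, pts)
    insol = annual_mean_insolation(latitude, pts, tsi_abs)
    return float(np.mean(insol)), float(np.mean(tsi_abs))


def great_circle_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Haversine distance in km; broadcasts."""
    p1, p2 = np.deg2rad(lat1), np.deg2rad(lat2)
    dl = np.deg2rad(lon2) - np.deg2rad(lon1)
    dp = p2 - p1
    a = np.sin(dp / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def nearest_valid_cell(grid: SstGrid, lat: float, lon: float) -> tuple[int, int]:
    """Indices of the nearest grid cell with a complete SST series."""
    mask = grid.valid_mask()
    if not mask.any():
        raise ValueError("SST grid has no valid cells")
    ii, jj = np.nonzero(mask)
    d = great_circle_km(lat, lon, grid.lats[ii], grid.lons[jj])
    k = int(np.argmin(d))
    return int(ii[k]), int(jj[k])


def sample_sst(t1: float, t2: float, lat: float, lon: float, grid: SstGrid) -> float:
    """Segment-mean SST from the nearest valid grid cell (degC).

    The cell's series is clipped to [T1, T2] at its native 200-yr steps,
    interpolated endpoint values are appended, and the set is averaged;
    for segments shorter than the native step this is the endpoint mean.
    """
    i, j = nearest_valid_cell(grid, lat, lon)
    cell = PaleoSeries(grid.ages, grid.sst[i, j], native_step=200.0, name="sst-cell")
    inner = grid.ages[(grid.ages > t1) & (grid.ages < t2)]
    pts = np.concatenate([[t1], inner, [t2]])
    return float(interp_at(cell, pts).mean())


def sea_level_rate(t1: float, t2: float, curve: SeaLevelCurve) -> float:
    """Mean year-to-year rate of sea-level change over [T1, T2], mm/yr.

    Submergence is interpolated at every integer year between ceil(T1) and
    floor(T2); the mean of successive differences (per year, converted to
    mm) is the rate.  Positive values mean sea level was rising through
    the segment.  Sub-annual segments fall back to the endpoint slope.
    """
    series = PaleoSeries(curve.ages, curve.submergence_m, native_step=1.0, name=curve.region)
    years = np.arange(math.ceil(t1), math.floor(t2) + 1, dtype=float)
    if years.size < 2:
        s1, s2 = interp_at(series, [t1, t2])
        return float((s2 - s1) / (t2 - t1) * 1000.0)
    s = interp_at(series, years)
    return float(np.diff(s).mean() * 1000.0)


def volcanic_metric(t1: float, t2: float, latitude: float, saod: SaodRecord) -> float:
    """Mean 20-yr cumulative volcanic forcing over the segment, W/m^2.

    Annual forcings at the site latitude are summed over every 20-yr
    window (1-yr stride) lying fully inside [T1, T2]; the metric is the
    mean of the window sums.  Segments shorter than 20 yr use a single
    window of all available years.
    """
    years, forcing = saod.annual_forcing_at(latitude)
    lo, hi = math.ceil(t1), math.floor(t2)
    span = np.arange(lo, hi + 1, dtype=float)
    if span.size == 0:
        span = np.array([math.floor(t1)], dtype=float)
    # Nearest-value extension outside the record.
    f = np.interp(span, years, forcing)
    w = VOLCANIC_WINDOW_YEARS
    if span.size < w:
        return float(f.sum())
    sums = np.convolve(f, np.ones(w), mode="valid")
    return float(sums.mean())


def correlation_screen(table: pd.DataFrame, threshold: float = 0.7) -> pd.DataFrame:
    """Pairwise Pearson correlations with flags for |r| above ``threshold``.

    Computed on pairwise-complete cases.  Zero-variance columns yield
    undefined (NaN) correlations, reported but never flagged.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 rows to screen correlations")
    num = table.select_dtypes(include=[np.number])
    corr = num.corr()
    rows = []
    cols = list(corr.columns)
    for a in range(len(cols)):
        for b in range(a + 1, len(cols)):
            r = corr.iloc[a, b]
            rows.append({
                "var1": cols[a], "var2": cols[b], "r": r,
                "flagged": bool(np.isfinite(r) and abs(r) > threshold),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# assembly

def build_covariates(samples: pd.DataFrame, env: Environment) -> pd.DataFrame:
    """Attach the full covariate vector to every growth sample.

    Returns a copy of ``samples`` with columns ``insolation, tsi, co2,
    ird, sst, sl_rate, volc, abs_latitude``.  Raises if any covariate
    comes out non-finite: silent missing values must not reach the model.
    """
    out = samples.copy()
    n = len(out)
    cols = {k: np.empty(n) for k in
            ["insolation", "tsi", "co2", "ird", "sst", "sl_rate", "volc"]}
    sst_cache: dict[tuple[float, float], tuple[int, int]] = {}
    for k, row in enumerate(out.itertuples(index=False)):
        t1, t2 = float(row.T1_age), float(row.T2_age)
        lat, lon = float(row.lat), float(row.lon)
        cols["insolation"][k], cols["tsi"][k] = sample_insolation(t1, t2, lat, env.tsi)
        cols["co2"][k] = sample_mean_series(t1, t2, env.co2)
        cols["ird"][k] = sample_mean_series(t1, t2, env.ird)
        key = (lat, lon)
        if key not in sst_cache:
            sst_cache[key] = nearest_valid_cell(env.sst, lat, lon)
        i, j = sst_cache[key]
        cell = PaleoSeries(env.sst.ages, env.sst.sst[i, j], 200.0, name="sst-cell")
        inner = env.sst.ages[(env.sst.ages > t1) & (env.sst.ages < t2)]
        pts = np.concatenate([[t1], inner, [t2]])
        cols["sst"][k] = float(interp_at(cell, pts).mean())
        curve = env.sea_level[row.region]
        cols["sl_rate"][k] = sea_level_rate(t1, t2, curve)
        cols["volc"][k] = volcanic_metric(t1, t2, lat, env.saod)
    for k, v in cols.items():
        out[k] = v
    out["abs_latitude"] = out["lat"].abs()
    bad = out[list(cols)].columns[~np.isfinite(out[list(cols)]).all().to_numpy()]
    if len(bad):
        raise ValueError(f"non-finite covariates in columns {list(bad)}")
    return out
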