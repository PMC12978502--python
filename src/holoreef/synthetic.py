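"""Seeded synthetic inputs with known ground truth.

Generates everything the pipeline consumes — sites, cores and dated
intervals; TSI, CO2, volcanic-aerosol, ice-rafted-debris and sea-level
records at their native resolutions; a gridded SST reconstruction with
missing cells — plus a forward gamma growth model (fixed effects, smooth
nonlinear effects, Matérn spatial field, iid group effects) whose
parameters are stored so recovery tests can be scored.

Every generator derives its random stream from the scenario seed by a
labelled hash, so adding a generator never perturbs existing output.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from holoreef.covariates import (
    Environment, PaleoSeries, SaodRecord, SeaLevelCurve, SstGrid, build_covariates,
)
from holoreef.records import reconstruct_segments
from holoreef.spatial import build_mesh, matern_parameters, project_local, sample_field, spde_precision

OCEAN_OF_REGION = {
    "WPacific-N": "Pacific", "WPacific-S": "Pacific",
    "Indian-N": "Indian", "Indian-S": "Indian",
    "Atlantic-N": "Atlantic", "Atlantic-S": "Atlantic",
}
REGIONS = list(OCEAN_OF_REGION)
REEF_ZONES = ["fringing", "reef crest", "back reef", "fore reef"]


def substream(seed: int, label: str) -> np.random.Generator:
    """Independent random stream for (seed, label)."""
    digest = hashlib.sha256(label.encode()).digest()
    key = int.from_bytes(digest[:4], "little")
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed) % 2**31, spawn_key=(key,)))


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic scenario (defaults: desk scale)."""

    n_sites: int = 40
    cores_per_site_mean: float = 2.4       # Poisson, floor 1
    extra_points_per_core_mean: float = 2.5  # points per core = 2 + Poisson
    age_span: tuple = (0.0, 11_700.0)
    lon_range: tuple = (120.0, 175.0)
    lat_range: tuple = (-28.0, 28.0)
    segment_median_years: float = 410.0    # lognormal median of gaps
    segment_log_sd: float = 0.7

    # environmental series
    tsi_step: float = 22.0
    tsi_span: tuple = (0.0, 9_389.0)       # length of the irradiance record
    tsi_noise_sd: float = 0.10             # W/m^2
    co2_step: float = 8.0
    co2_range: tuple = (255.0, 335.0)      # ppmv across the age span
    ird_step: float = 70.0
    bond_period_years: float = 1_470.0
    ird_baseline_pct: float = 8.0
    ird_amplitude_pct: float = 4.0
    eruptions_per_century: float = 3.0
    eruption_magnitude_log: tuple = (np.log(0.08), 0.9)  # lognormal SAOD peak
    saod_background: float = 0.002
    sst_step_years: float = 200.0
    sst_equator_degC: float = 29.0
    sst_pole_drop_degC: float = 5.5        # drop from equator to 30 deg lat
    htm_amplitude_degC: float = 1.2        # warm anomaly of the mid-Holocene
    htm_center_age: float = 8_000.0
    htm_width_years: float = 2_000.0
    stabilization_age: dict = field(default_factory=lambda: {
        "Pacific": 5_500.0, "Indian": 5_500.0, "Atlantic": 50.0})
    deglacial_rate_mm_yr: dict = field(default_factory=lambda: {
        "Pacific": 9.7, "Indian": 9.7, "Atlantic": 5.0})

    seed: int = 0


@dataclass
class SyntheticTruth:
    """Generating parameters of the forward growth model."""

    beta0: float = np.log(3.0)                 # log mm/yr at covariate centers
    beta_slrate: float = 0.10                  # per mm/yr of sea-level rise
    beta_sst: float = 0.0                      # per degC
    beta_volc: float = 0.0                     # per W/m^2
    co2_bumps: tuple = (275.0, 325.0)          # ppmv, centers of the bimodal effect
    co2_bump_sd: float = 9.0
    co2_amplitude: float = 0.25
    ird_slope: float = -0.03                   # per % lithic grains
    age_hump_center: float = 6_000.0
    age_hump_width: float = 2_500.0
    age_amplitude: float = 0.20
    seg_slope_per_kyr: float = -0.10
    gamma_shape: float = 8.0
    spatial_sigma: float = 0.25
    spatial_range_km: float = 1_200.0
    iid_sd: dict = field(default_factory=lambda: {
        "ocean": 0.05, "region": 0.10, "locality": 0.12, "core_uid": 0.20})
    centers: dict = field(default_factory=lambda: {
        "sl_rate": 0.0, "sst": 27.0, "volc": 10.0, "ird": 8.0})
    seed: int = 0
    field_nodes: np.ndarray | None = None
    field_values: np.ndarray | None = None
    iid_draws: dict = field(default_factory=dict)

    def smooth_co2(self, co2):
        co2 = np.asarray(co2, dtype=float)
        f = sum(np.exp(-0.5 * ((co2 - c) / self.co2_bump_sd) ** 2) for c in self.co2_bumps)
        return self.co2_amplitude * (f - 0.5)

    def smooth_ird(self, ird):
        return self.ird_slope * (np.asarray(ird, dtype=float) - self.centers["ird"])

    def smooth_age(self, age):
        age = np.asarray(age, dtype=float)
        return self.age_amplitude * (
            np.exp(-0.5 * ((age - self.age_hump_center) / self.age_hump_width) ** 2) - 0.3
        )

    def smooth_segment(self, years):
        return self.seg_slope_per_kyr * (np.asarray(years, dtype=float) - 410.0) / 1000.0


# ---------------------------------------------------------------------------
# environment

def gen_environment(config: ScenarioConfig) -> Environment:
    """All paleo forcing records, the SST grid and sea-level curves."""
    seed = config.seed
    a0, a1 = config.age_span

    rng = substream(seed, "tsi")
    ages = np.arange(config.tsi_span[0], config.tsi_span[1] + 1, config.tsi_step)
    anom = (0.25 * np.sin(2 * np.pi * ages / 2300.0)
            + 0.15 * np.sin(2 * np.pi * ages / 980.0 + 1.0)
            + config.tsi_noise_sd * rng.standard_normal(ages.size))
    tsi = PaleoSeries(ages, anom, config.tsi_step, units="W/m^2 anomaly vs 1365", name="tsi")

    rng = substream(seed, "co2")
    ages = np.arange(a0, a1 + 1, config.co2_step)
    lo, hi = config.co2_range
    base = hi - (hi - lo) * (ages / a1) ** 0.9
    wig = 3.0 * np.sin(2 * np.pi * ages / 2500.0) + 0.5 * rng.standard_normal(ages.size)
    co2 = PaleoSeries(ages, np.clip(base + wig, 150.0, 500.0), config.co2_step,
                      units="ppmv", name="co2")

    rng = substream(seed, "ird")
    ages = np.arange(a0, a1 + 1, config.ird_step)
    ird_vals = (config.ird_baseline_pct
                + config.ird_amplitude_pct * np.sin(2 * np.pi * ages / config.bond_period_years)
                + 0.5 * rng.standard_normal(ages.size))
    ird = PaleoSeries(ages, np.clip(ird_vals, 0.0, None), config.ird_step,
                      units="% lithic grains", name="ird")

    saod = _gen_saod(config)
    sst = _gen_sst(config)
    sea = _gen_sea_level(config)
    return Environment(tsi=tsi, co2=co2, ird=ird, saod=saod, sst=sst, sea_level=sea)


def _gen_saod(config: ScenarioConfig) -> SaodRecord:
    rng = substream(config.seed, "saod")
    a0, a1 = config.age_span
    months = np.arange(a0, a1, 1.0 / 12.0) + 1.0 / 24.0
    bands = np.arange(-85.0, 86.0, 10.0)
    saod = np.full((months.size, bands.size), config.saod_background)
    n_eruptions = rng.poisson(config.eruptions_per_century * (a1 - a0) / 100.0)
    times = rng.uniform(a0, a1, n_eruptions)
    lats = rng.uniform(-65.0, 65.0, n_eruptions)
    mags = rng.lognormal(*config.eruption_magnitude_log, n_eruptions)
    decay_months = 12.0
    for t, la, m in zip(times, lats, mags):
        i0 = int(np.searchsorted(months, t))
        # the pulse decays into the past-to-present direction (younger ages)
        i_lo = max(i0 - 36, 0)
        idx = np.arange(i_lo, i0)
        if idx.size == 0:
            continue
        dt = (t - months[idx]) * 12.0
        pulse = m * np.exp(-dt / decay_months)
        spread = np.exp(-0.5 * ((bands - la) / 20.0) ** 2)
        saod[idx] += pulse[:, None] * spread[None, :]
    return SaodRecord(months, bands, saod)


def _gen_sst(config: ScenarioConfig) -> SstGrid:
    rng = substream(config.seed, "sst")
    lats = np.arange(config.lat_range[0] - 3.0, config.lat_range[1] + 3.5, 1.0)
    lons = np.arange(config.lon_range[0] - 3.0, config.lon_range[1] + 3.5, 1.0)
    ages = np.arange(config.age_span[0], config.age_span[1] + 1, config.sst_step_years)
    lat_term = config.sst_equator_degC - config.sst_pole_drop_degC * (np.abs(lats) / 30.0) ** 2
    lon_term = 0.5 * np.sin(np.deg2rad(lons - lons.mean()))
    htm = config.htm_amplitude_degC * np.exp(
        -0.5 * ((ages - config.htm_center_age) / config.htm_width_years) ** 2)
    sst = (lat_term[:, None, None] + lon_term[None, :, None] + htm[None, None, :]
           + 0.15 * rng.standard_normal((lats.size, lons.size, ages.size)))
    # Missing data: a sparse block (exercises nearest-valid-cell search) plus
    # scattered dropouts.
    block_lat = (lats >= 5) & (lats <= 15)
    block_lon = (lons >= 150) & (lons <= 160)
    sst[np.ix_(block_lat, block_lon)] = np.nan
    dropout = rng.random((lats.size, lons.size)) < 0.08
    sst[dropout] = np.nan
    return SstGrid(lats, lons, ages, np.clip(sst, -4.9, 39.9))


def _gen_sea_level(config: ScenarioConfig) -> dict[str, SeaLevelCurve]:
    curves = {}
    for region, ocean in OCEAN_OF_REGION.items():
        rng = substream(config.seed, f"sealevel:{region}")
        t_s = config.stabilization_age[ocean]
        rate_m = config.deglacial_rate_mm_yr[ocean] / 1000.0
        scale = rng.uniform(0.9, 1.1)
        ages = np.arange(0.0, config.age_span[1] + 1500.0, 50.0)
        soft = 300.0 * np.log1p(np.exp((ages - t_s) / 300.0))  # smooth hinge
        wig = 0.3 * np.sin(2 * np.pi * ages / 3300.0 + rng.uniform(0, 2 * np.pi))
        curves[region] = SeaLevelCurve(region, ages, scale * rate_m * soft + wig - wig[0])
    return curves


# ---------------------------------------------------------------------------
# cores

def gen_cores(config: ScenarioConfig) -> pd.DataFrame:
    """Dated core points: per core, sorted ages with accumulated depths.

    Depth increments are positive by construction, so age--depth
    monotonicity always holds.  The provisional depths imply plausible
    rates; ``simulate_growth`` rewrites them from the generative model.
    """
    rng = substream(config.seed, "cores")
    rows = []
    lon = rng.uniform(*config.lon_range, config.n_sites)
    lat = rng.uniform(*config.lat_range, config.n_sites)
    lon_mid = np.mean(config.lon_range)
    for s in range(config.n_sites):
        if lon[s] < lon_mid - 10:
            region = "Indian-N" if lat[s] >= 0 else "Indian-S"
        elif lon[s] < lon_mid + 15:
            region = "WPacific-N" if lat[s] >= 0 else "WPacific-S"
        else:
            region = "Atlantic-N" if lat[s] >= 0 else "Atlantic-S"
        locality = f"loc_{int((lon[s] - config.lon_range[0]) // 8)}_{int((lat[s] - config.lat_range[0]) // 8)}"
        n_cores = max(1, rng.poisson(config.cores_per_site_mean))
        for c in range(n_cores):
            study = f"Study{1 + (s % 7)}"
            core = f"S{s:02d}C{c}"
            k = 2 + rng.poisson(config.extra_points_per_core_mean)
            t0 = rng.uniform(0.0, 8000.0)
            gaps = rng.lognormal(np.log(config.segment_median_years), config.segment_log_sd, k - 1)
            ages = t0 + np.concatenate([[0.0], np.cumsum(gaps)])
            depth0 = rng.uniform(0.0, 500.0)
            seg_rates = rng.lognormal(np.log(3.0), 0.5, k - 1)
            depths = depth0 + np.concatenate([[0.0], np.cumsum(seg_rates * gaps)])
            keep = ages <= config.age_span[1]
            if keep.sum() < 2:
                continue
            ages, depths = ages[keep], depths[keep]
            for age, depth in zip(ages, depths):
                rows.append({
                    "study": study, "core": core,
                    "lon": round(float(lon[s]), 4), "lat": round(float(lat[s]), 4),
                    "region": region, "ocean": OCEAN_OF_REGION[region],
                    "locality": locality,
                    "reef_zone": REEF_ZONES[int(rng.integers(len(REEF_ZONES)))],
                    "age_ybp": float(age), "depth_mm": float(depth),
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# forward growth model

def draw_rates(mu, shape: float, rng: np.random.Generator) -> np.ndarray:
    """Gamma growth rates with mean ``mu`` and shape ``shape`` (var mu^2/shape)."""
    mu = np.asarray(mu, dtype=float)
    return rng.gamma(shape, mu / shape)


def simulate_growth(
    points: pd.DataFrame,
    env: Environment,
    truth: SyntheticTruth,
    config: ScenarioConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Draw growth rates from the generative model and rebuild depths.

    Returns ``(points, samples, truth)`` where the points' depths are
    rewritten so that segment reconstruction reproduces the simulated
    rates exactly, the samples carry covariates, the drawn rate and the
    true linear predictor, and the truth stores the realized spatial
    field and group effects.
    """
    samples = reconstruct_segments(points)
    samples = build_covariates(samples, env)

    rng = substream(truth.seed, "growth")
    eta = (
        truth.beta0
        + truth.beta_slrate * (samples["sl_rate"] - truth.centers["sl_rate"])
        + truth.beta_sst * (samples["sst"] - truth.centers["sst"])
        + truth.beta_volc * (samples["volc"] - truth.centers["volc"])
        + truth.smooth_co2(samples["co2"])
        + truth.smooth_ird(samples["ird"])
        + truth.smooth_age(samples["mean_age"])
        + truth.smooth_segment(samples["segment_years"])
    ).to_numpy(dtype=float)

    # Spatial field drawn on a mesh over the sites, projected to samples.
    xy = project_local(samples["lon"].to_numpy(), samples["lat"].to_numpy())
    site_xy = np.unique(xy, axis=0)
    mesh = build_mesh(site_xy, fine_edge=250.0, coarse_edge=900.0, buffer=600.0)
    kappa, tau = matern_parameters(truth.spatial_range_km, truth.spatial_sigma)
    Q = spde_precision(mesh, kappa, tau)
    w = sample_field(Q, 1, substream(truth.seed, "field"))[0]
    eta = eta + (mesh.projector(xy) @ w)

    iid_draws = {}
    for col, sd in truth.iid_sd.items():
        levels = pd.unique(samples[col])
        draw = substream(truth.seed, f"iid:{col}").normal(0.0, sd, len(levels))
        lut = dict(zip(levels, draw))
        iid_draws[col] = lut
        eta = eta + samples[col].map(lut).to_numpy(dtype=float)

    mu = np.exp(eta)
    rates = draw_rates(mu, truth.gamma_shape, rng)
    samples["rate"] = rates
    samples["segment_mm"] = rates * samples["segment_years"]
    samples["eta_true"] = eta
    samples["x_km"], samples["y_km"] = xy[:, 0], xy[:, 1]

    # Rewrite depths so the record is internally consistent.
    points = points.reset_index(drop=True)
    seg_lookup = {(r.core_uid, r.T1_age): r.segment_mm for r in samples.itertuples()}
    from holoreef.records import build_core_uid

    points["core_uid"] = [build_core_uid(s, c) for s, c in zip(points["study"], points["core"])]
    new_depth = np.empty(len(points))
    for uid, grp in points.groupby("core_uid", sort=False):
        g = grp.sort_values("age_ybp")
        d = g["depth_mm"].iloc[0]
        depths = [d]
        ages = g["age_ybp"].to_numpy()
        for i in range(len(g) - 1):
            d = d + seg_lookup.get((uid, ages[i]), 0.0)
            depths.append(d)
        new_depth[g.index.to_numpy()] = depths
    points["depth_mm"] = new_depth

    realized = replace(truth)
    realized.field_nodes = mesh.points
    realized.field_values = w
    realized.iid_draws = iid_draws
    return points.drop(columns="core_uid"), samples, realized


def write_environment(env: Environment, out_dir) -> None:
    """Emit the environment in the file dialects the readers accept.

    Paleo series and sea-level curves as commented CSVs, the aerosol
    record as long CSV, the SST grid as NetCDF.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    env.tsi.to_csv(out / "tsi.csv")
    env.co2.to_csv(out / "co2.csv")
    env.ird.to_csv(out / "ird.csv")
    env.saod.to_csv(out / "saod.csv")
    env.sst.to_netcdf(out / "sst.nc")
    sl_dir = out / "sealevel"
    sl_dir.mkdir(exist_ok=True)
    for region, curve in env.sea_level.items():
        curve.to_csv(sl_dir / f"{region}.csv")


def read_environment(in_dir) -> Environment:
    from pathlib import Path

    src = Path(in_dir)
    return Environment(
        tsi=PaleoSeries.from_csv(src / "tsi.csv", name="tsi"),
        co2=PaleoSeries.from_csv(src / "co2.csv", name="co2"),
        ird=PaleoSeries.from_csv(src / "ird.csv", name="ird"),
        saod=SaodRecord.from_csv(src / "saod.csv"),
        sst=SstGrid.from_netcdf(src / "sst.nc"),
        sea_level={
            p.stem: SeaLevelCurve.from_csv(p, region=p.stem)
            for p in sorted((src / "sealevel").glob("*.csv"))
        },
    )


def write_truth(truth: SyntheticTruth, path) -> None:
    """Scoreable ground-truth record as JSON."""
    import json

    payload = {
        "beta0": truth.beta0, "beta_slrate": truth.beta_slrate,
        "beta_sst": truth.beta_sst, "beta_volc": truth.beta_volc,
        "co2_bumps": list(truth.co2_bumps), "co2_amplitude": truth.co2_amplitude,
        "ird_slope": truth.ird_slope, "gamma_shape": truth.gamma_shape,
        "spatial_sigma": truth.spatial_sigma,
        "spatial_range_km": truth.spatial_range_km,
        "iid_sd": truth.iid_sd, "seed": truth.seed,
        "field_values": None if truth.field_values is None
        else [round(float(v), 8) for v in truth.field_values],
        "iid_draws": {k: {str(kk): float(vv) for kk, vv in lut.items()}
                      for k, lut in truth.iid_draws.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def default_scenario(seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth, Environment]:
    """The default desk-scale study: ~40 sites, ~300 samples."""
    config = ScenarioConfig(seed=seed)
    truth = SyntheticTruth(seed=seed)
    env = gen_environment(config)
    points = gen_cores(config)
    points, samples, truth = simulate_growth(points, env, truth, config)
    return points, samples, truth, env


def paper_scale_scenario(seed: int = 0):
    """A larger layout (~290 sites, ~1,900 samples); not used by the tests."""
    config = ScenarioConfig(n_sites=290, cores_per_site_mean=2.4, seed=seed)
    truth = SyntheticTruth(seed=seed)
    env = gen_environment(config)
    points = gen_cores(config)
    return simulate_growth(points, env, truth, config) + (env,)


def nonlinear_scenario(n: int = 1500, seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Growth rates with a 25-degC temperature optimum and a sea-level-rate
    effect that plateaus near 20 mm/yr; the dataset for the network tests.

    Returns the data frame (rate, sst, sl_rate, abs_latitude) and the
    generating parameters.
    """
    rng = substream(seed, "nonlinear")
    sst = rng.uniform(18.0, 32.0, n)
    sl_rate = rng.uniform(0.0, 35.0, n)
    abs_lat = rng.uniform(0.0, 30.0, n)
    params = {"sst_optimum": 25.0, "sst_width": 3.0, "plateau_mm_yr": 20.0,
              "lat_slope": -0.01, "shape": 12.0, "base_rate": 4.0}
    mu = (params["base_rate"]
          * np.exp(-0.5 * ((sst - params["sst_optimum"]) / params["sst_width"]) ** 2)
          * (0.35 + 0.65 * (1.0 - np.exp(-3.0 * sl_rate / params["plateau_mm_yr"])))
          * np.exp(params["lat_slope"] * abs_lat))
    rate = rng.gamma(params["shape"], mu / params["shape"])
    df = pd.DataFrame({"rate": rate, "sst": sst, "sl_rate": sl_rate, "abs_latitude": abs_lat})
    return df, params
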