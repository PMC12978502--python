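"""Reef-core growth records.

Parses tables of radiocarbon-dated core depth/age points, reconstructs
per-segment growth rates (consecutive dated intervals within a core, where
the older bound of one interval is the younger bound of the next), applies
the age and outlier filters, and summarizes regional growth trends with a
local (LOESS-style) smoother.

Data are carried as pandas DataFrames.  Dated points use the columns
``study, core, lon, lat, region, ocean, locality, reef_zone, age_ybp,
depth_mm``; growth samples use ``core_uid, T1_age, T2_age, segment_mm,
segment_years, rate, mean_age`` plus the site columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Separator reserved for core identifiers; may not appear in study names.
UID_SEP = "::"

#: Ages older than this (yr BP) fall outside the Holocene window.
HOLOCENE_MAX_AGE = 11_700.0

#: No dated point may claim an age before this floor (yr BP; negative = after 1950).
AGE_FLOOR = -100.0

POINT_COLUMNS = [
    "study", "core", "lon", "lat", "region", "ocean", "locality",
    "reef_zone", "age_ybp", "depth_mm",
]

SITE_COLUMNS = ["lon", "lat", "region", "ocean", "locality", "reef_zone"]


def build_core_uid(study_name: str, core_name: str) -> str:
    """Unique core identifier: study and core name joined by ``::``.

    Core names repeat across studies, so neither alone identifies a core;
    the reserved separator keeps the mapping injective.
    """
    study = str(study_name).strip()
    core = str(core_name).strip()
    if not study or not core:
        raise ValueError(
            f"empty study or core name in record ({study_name!r}, {core_name!r})"
        )
    if UID_SEP in study:
        raise ValueError(f"study name may not contain {UID_SEP!r}: {study!r}")
    return f"{study}{UID_SEP}{core}"


def read_points(path_or_df, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read dated core points from CSV (or validate an existing frame).

    ``column_map`` optionally maps source column names onto the expected
    schema (useful for externally deposited tables).  Validation enforces
    coordinate bounds, the age floor, and age--depth monotonicity within
    each core; violations raise ``ValueError`` naming the offending core.
    """
    df = path_or_df.copy() if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in POINT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    df = df[POINT_COLUMNS].copy()

    if df[["lon", "lat", "age_ybp", "depth_mm"]].isna().any().any():
        raise ValueError("non-finite values in coordinate, age or depth columns")
    if (df["lon"].abs() > 180).any() or (df["lat"].abs() > 90).any():
        raise ValueError("coordinates out of range")
    if (df["age_ybp"] < AGE_FLOOR).any():
        bad = df.loc[df["age_ybp"] < AGE_FLOOR]
        raise ValueError(f"ages below the {AGE_FLOOR} yr BP floor: {bad.index.tolist()}")

    df["core_uid"] = [
        build_core_uid(s, c) for s, c in zip(df["study"], df["core"])
    ]
    for uid, grp in df.groupby("core_uid", sort=False):
        g = grp.sort_values("depth_mm")
        if (np.diff(g["age_ybp"].to_numpy()) < 0).any():
            raise ValueError(f"age-depth inversion in core {uid}")
    return df


def reconstruct_segments(points: pd.DataFrame) -> pd.DataFrame:
    """Turn dated points into growth samples: one per consecutive pair.

    Within each core, points sorted by depth yield ``n - 1`` segments; the
    older bound (``T2``) of one segment is the younger bound (``T1``) of the
    next.  The rate is depth difference over age difference (mm/yr).
    Pairs of tied ages cannot carry a rate and are skipped with a warning.
    """
    if "core_uid" not in points.columns:
        points = read_points(points)
    rows = []
    for uid, grp in points.groupby("core_uid", sort=False):
        g = grp.sort_values(["depth_mm", "age_ybp"], kind="mergesort")
        if len(g) < 2:
            continue
        ages = g["age_ybp"].to_numpy(dtype=float)
        depths = g["depth_mm"].to_numpy(dtype=float)
        site = g.iloc[0]
        for i in range(len(g) - 1):
            dt = ages[i + 1] - ages[i]
            dz = depths[i + 1] - depths[i]
            if dt <= 0:
                logger.warning("tied ages in core %s at %.1f yr BP; segment skipped", uid, ages[i])
                continue
            rows.append({
                "core_uid": uid,
                "T1_age": ages[i],
                "T2_age": ages[i + 1],
                "segment_mm": dz,
                "segment_years": dt,
                "rate": dz / dt,
                "mean_age": 0.5 * (ages[i] + ages[i + 1]),
                **{c: site[c] for c in SITE_COLUMNS},
            })
    return pd.DataFrame(rows, columns=[
        "core_uid", "T1_age", "T2_age", "segment_mm", "segment_years",
        "rate", "mean_age", *SITE_COLUMNS,
    ])


def filter_max_age(samples: pd.DataFrame, max_age: float = HOLOCENE_MAX_AGE) -> pd.DataFrame:
    """Drop samples whose older bound exceeds ``max_age`` (bound inclusive)."""
    return samples.loc[samples["T2_age"] <= max_age].copy()


def percentile_filter(samples: pd.DataFrame, total_mass: float = 0.97) -> pd.DataFrame:
    """Two-tailed percentile filter on the pooled rate distribution.

    Retains the central ``total_mass`` of the rates: values strictly below
    the lower or strictly above the upper cut are removed.  Cuts are
    quantiles of the pooled rates with the linear-interpolation estimator
    (numpy's default), so retained counts are bit-reproducible.
    """
    if not 0.0 < total_mass < 1.0:
        raise ValueError("total_mass must lie in (0, 1)")
    if len(samples) < 10:
        raise ValueError("need at least 10 samples for the percentile filter")
    tail = (1.0 - total_mass) / 2.0
    rates = samples["rate"].to_numpy(dtype=float)
    lo = np.quantile(rates, tail, method="linear")
    hi = np.quantile(rates, 1.0 - tail, method="linear")
    keep = (rates >= lo) & (rates <= hi)
    return samples.loc[keep].copy()


@dataclass(frozen=True)
class TrendCurve:
    """A smoothed regional growth trend with a pointwise 95% band."""

    age: np.ndarray
    mean_rate: np.ndarray
    lower: np.ndarray
    upper: np.ndarray


def loess(x: np.ndarray, y: np.ndarray, x_eval: np.ndarray, span: float = 0.75):
    """Local linear regression with tricube weights (LOESS, degree 1).

    At each evaluation point the nearest ``span`` fraction of the data is
    weighted by the tricube kernel on scaled distance and fitted with a
    weighted straight line.  Returns predictions and pointwise standard
    errors from the weighted-least-squares linearization.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    k = max(int(np.ceil(span * n)), 3)
    pred = np.empty(len(x_eval))
    se = np.empty(len(x_eval))
    # Residual scale from a pilot pass of local fits.
    for j, x0 in enumerate(np.asarray(x_eval, dtype=float)):
        d = np.abs(x - x0)
        h = np.partition(d, k - 1)[k - 1]
        if h == 0:  # k nearest points coincide with x0
            w = (d == 0).astype(float)
        else:
            w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
        use = w > 0
        if use.sum() < 2 or np.ptp(x[use]) == 0:
            # Degenerate neighborhood: weighted mean.
            pred[j] = np.average(y[use], weights=w[use])
            se[j] = 0.0
            continue
        X = np.column_stack([np.ones(use.sum()), x[use] - x0])
        W = w[use]
        XtW = X.T * W
        A = XtW @ X
        b = XtW @ y[use]
        coef = np.linalg.solve(A, b)
        resid = y[use] - X @ coef
        # Effective local sample size (Kish) gives the dof correction.
        n_eff = W.sum() ** 2 / (W**2).sum()
        sigma2 = (W * resid**2).sum() / (W.sum() * max(n_eff - 2.0, 1.0) / n_eff)
        Ainv = np.linalg.inv(A)
        var = sigma2 * (Ainv @ (X.T * W**2 @ X) @ Ainv)[0, 0]
        pred[j] = coef[0]
        se[j] = np.sqrt(max(var, 0.0))
    return pred, se


def regional_trend(
    samples: pd.DataFrame,
    span: float = 0.75,
    n_grid: int = 100,
    min_samples: int = 10,
) -> TrendCurve:
    """LOESS mean growth-rate trend over mean age for one region.

    Refuses regions with fewer than ``min_samples`` samples: sparse regions
    cannot support a meaningful local fit.
    """
    if len(samples) < min_samples:
        raise ValueError(
            f"regional trend needs >= {min_samples} samples, got {len(samples)}"
        )
    x = samples["mean_age"].to_numpy(dtype=float)
    y = samples["rate"].to_numpy(dtype=float)
    grid = np.linspace(x.min(), x.max(), n_grid)
    pred, se = loess(x, y, grid, span=span)
    return TrendCurve(age=grid, mean_rate=pred, lower=pred - 1.96 * se, upper=pred + 1.96 * se)


def write_samples(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, index=False)
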