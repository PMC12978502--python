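"""End-to-end convenience wrappers tying the modules together.

These are the entry points the examples, the recovery tests and the
acceptance checks share: simulate a scenario, filter the record, build
the mesh and fit the full hierarchical model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from holoreef.model import FitResult, ModelSpec, fit
from holoreef.records import filter_max_age, percentile_filter
from holoreef.spatial import build_mesh
from holoreef.synthetic import default_scenario

#: The model structure of the main analysis: three fixed effects, four
#: random-walk smooths, four iid groupings and the spatial field.
FULL_MODEL = dict(
    fixed=["sl_rate", "sst", "volc"],
    rw2=[("co2", 20), ("ird", 20), ("mean_age", 20), ("segment_years", 20)],
    iid=["ocean", "region", "locality", "core_uid"],
)


def filter_record(samples: pd.DataFrame) -> pd.DataFrame:
    """The record filters of the main analysis: age cap then outlier trim."""
    return percentile_filter(filter_max_age(samples))


def mesh_for(data: pd.DataFrame, fine_edge: float = 350.0,
             coarse_edge: float = 1200.0, buffer: float = 700.0):
    site_xy = np.unique(data[["x_km", "y_km"]].to_numpy(dtype=float), axis=0)
    return build_mesh(site_xy, fine_edge=fine_edge, coarse_edge=coarse_edge, buffer=buffer)


def fit_full_model(data: pd.DataFrame, seed: int = 0, n_draws: int = 800,
                   **fit_kwargs) -> FitResult:
    spec = ModelSpec(spatial=True, mesh=mesh_for(data), **FULL_MODEL)
    return fit(spec, data, seed=seed, n_draws=n_draws, **fit_kwargs)


def headline_replicate(seed: int, n_draws: int = 800):
    """One simulate-filter-fit replicate of the default scenario.

    Returns ``(fit_result, truth, data)``; the replicate is fully
    determined by ``seed``.
    """
    _, samples, truth, _ = default_scenario(seed=seed)
    data = filter_record(samples)
    result = fit_full_model(data, seed=seed, n_draws=n_draws)
    return result, truth, data
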