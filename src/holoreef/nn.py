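"""Nonlinear growth responses via a small feed-forward network.

A two-hidden-layer perceptron (20 and 10 rectified units) maps
(SST, sea-level rate, absolute latitude) to growth rate (mm/yr).  The
data are split 70/15/15 into training/testing/validation; each candidate
run trains for up to 100 epochs with early stopping after 5 rounds
without validation improvement, restarts are repeated with fresh
initializations, and the run with the lowest validation root
mean-squared error is selected.  Partial-dependence curves sweep one
input over a grid while the others keep their observed values.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler


@dataclass
class NNConfig:
    hidden_layers: tuple = (20, 10)
    epochs: int = 100
    early_stopping_rounds: int = 5
    split_fractions: tuple = (0.70, 0.15, 0.15)
    restarts: int = 30
    learning_rate: float = 1e-3
    seed: int = 0

    def validate(self):
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.restarts < 1:
            raise ValueError("need at least one restart")


#: Candidate architectures screened before settling on (20, 10) x 100 epochs.
CANDIDATE_CONFIGS = [
    {"hidden_layers": (20, 10), "epochs": 100},
    {"hidden_layers": (10,), "epochs": 100},
    {"hidden_layers": (20,), "epochs": 100},
    {"hidden_layers": (40, 20), "epochs": 100},
    {"hidden_layers": (20, 10), "epochs": 50},
    {"hidden_layers": (10, 10, 10), "epochs": 100},
]


def split_data(n: int, fractions=(0.70, 0.15, 0.15), seed: int = 0):
    """Disjoint, exhaustive train/test/validation index arrays."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    if n < 20:
        raise ValueError("need at least 20 samples to split")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    n_train = int(round(fractions[0] * n))
    n_test = int(round(fractions[1] * n))
    return idx[:n_train], idx[n_train:n_train + n_test], idx[n_train + n_test:]


@dataclass
class TrainedNN:
    """The selected network with its preprocessing and restart table."""

    model: MLPRegressor
    x_scaler: StandardScaler
    y_mean: float
    y_scale: float
    feature_names: list
    rmse_table: pd.DataFrame
    config: NNConfig
    splits: tuple = field(repr=False, default=None)

    def predict(self, X: np.ndarray) -> np.ndarray:
        z = self.model.predict(self.x_scaler.transform(np.asarray(X, dtype=float)))
        return z * self.y_scale + self.y_mean


def _train_one(Xtr, ytr, Xval, yval, config: NNConfig, seed: int):
    model = MLPRegressor(
        hidden_layer_sizes=config.hidden_layers,
        solver="adam",
        learning_rate_init=config.learning_rate,
        random_state=seed,
        max_iter=1,
        warm_start=False,
    )
    best_rmse, best_model, since_best = np.inf, None, 0
    for epoch in range(config.epochs):
        model.partial_fit(Xtr, ytr)
        pred = model.predict(Xval)
        rmse = float(np.sqrt(np.mean((pred - yval) ** 2)))
        if rmse < best_rmse - 1e-12:
            best_rmse, best_model, since_best = rmse, copy.deepcopy(model), 0
        else:
            since_best += 1
            if since_best >= config.early_stopping_rounds:
                break
    return best_model, best_rmse, epoch + 1


def train_select(data: pd.DataFrame, config: NNConfig,
                 features=("sst", "sl_rate", "abs_latitude"),
                 response: str = "rate") -> TrainedNN:
    """Train ``config.restarts`` seeded runs and keep the best-validation one."""
    config.validate()
    feats = list(features)
    X = data[feats].to_numpy(dtype=float)
    y = data[response].to_numpy(dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite inputs")
    tr, te, val = split_data(len(y), config.split_fractions, config.seed)

    x_scaler = StandardScaler().fit(X[tr])
    y_mean, y_scale = float(y[tr].mean()), float(y[tr].std() or 1.0)
    Xs = x_scaler.transform(X)
    ys = (y - y_mean) / y_scale

    rows, best = [], None
    for r in range(config.restarts):
        model, val_rmse_s, n_epochs = _train_one(
            Xs[tr], ys[tr], Xs[val], ys[val], config, seed=config.seed * 10_000 + r
        )
        val_rmse = val_rmse_s * y_scale
        test_rmse = float(np.sqrt(np.mean(
            (model.predict(Xs[te]) * y_scale + y_mean - y[te]) ** 2)))
        rows.append({"restart": r, "epochs_run": n_epochs,
                     "val_rmse": val_rmse, "test_rmse": test_rmse})
        if best is None or val_rmse < best[1]:
            best = (model, val_rmse)
    return TrainedNN(
        model=best[0], x_scaler=x_scaler, y_mean=y_mean, y_scale=y_scale,
        feature_names=feats, rmse_table=pd.DataFrame(rows), config=config,
        splits=(tr, te, val),
    )


def screen_configs(data: pd.DataFrame, base: NNConfig | None = None,
                   candidates=None, **train_kwargs) -> pd.DataFrame:
    """Evaluate the candidate architectures; returns one row per candidate
    with its best validation RMSE (the final architecture is selected by
    the caller from this table)."""
    import dataclasses

    base = base or NNConfig()
    rows = []
    for cand in (candidates or CANDIDATE_CONFIGS):
        config = dataclasses.replace(
            base, hidden_layers=tuple(cand["hidden_layers"]), epochs=cand["epochs"])
        nn = train_select(data, config, **train_kwargs)
        rows.append({
            "hidden_layers": str(cand["hidden_layers"]), "epochs": cand["epochs"],
            "best_val_rmse": nn.rmse_table.val_rmse.min(),
        })
    return pd.DataFrame(rows).sort_values("best_val_rmse", ignore_index=True)


@dataclass
class PdpResult:
    variable: str
    grid: np.ndarray
    mean_prediction: np.ndarray
    histogram: tuple                 # (counts, bin_edges) of the observed variable


def partial_dependence(nn: TrainedNN, data: pd.DataFrame, variable: str,
                       grid=None, n_grid: int = 40) -> PdpResult:
    """Average prediction as ``variable`` sweeps a grid, others held observed."""
    if variable not in nn.feature_names:
        raise ValueError(f"{variable!r} is not a model input")
    X = data[nn.feature_names].to_numpy(dtype=float)
    v = data[variable].to_numpy(dtype=float)
    if grid is None:
        grid = np.linspace(v.min(), v.max(), n_grid)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty grid")
    j = nn.feature_names.index(variable)
    means = np.empty(grid.size)
    for k, g in enumerate(grid):
        Xg = X.copy()
        Xg[:, j] = g
        means[k] = float(nn.predict(Xg).mean())
    hist = np.histogram(v, bins=20)
    return PdpResult(variable=variable, grid=grid, mean_prediction=means, histogram=hist)
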