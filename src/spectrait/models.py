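"""Regression model construction and evaluation for GPC estimation.

Four calibration algorithms are supported — partial least squares (PLSR),
RBF support vector regression (SVMR), random forest regression (RFR) and
Bayesian linear regression (BLR) — each tuned by grid search over a small
hyperparameter grid with fivefold cross-validated mean squared error.  The
same fold assignment is reused across every grid point so CV scores are
directly comparable.

Validation metrics follow chemometric convention:

    R^2    = 1 - SSE/SST   (about the measured mean; NOT squared Pearson r)
    RMSE   = sqrt(mean((y - yhat)^2))          [% GPC]
    RRMSE  = RMSE / mean(y) * 100              [%]

Negative validation R^2 (predictions worse than the measured mean) is
reported as 0 when clamping is enabled; the raw value is retained.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import BayesianRidge
from sklearn.model_selection import KFold
from sklearn.svm import SVR

ALGORITHMS = ("PLSR", "SVMR", "RFR", "BLR")

#: default hyperparameter grids, overridable per call
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "PLSR": {"n_components": list(range(1, 21))},
    "SVMR": {"C": [0.1, 1.0, 10.0, 100.0], "gamma": ["scale", 0.01, 0.1]},
    "RFR": {"n_estimators": [100, 300], "max_depth": [None, 10]},
    "BLR": {},
}


@dataclass
class TrainingDesign:
    """Rows of (n_measured, n_simulated) training-set sizes.

    The canonical design pairs a fixed validation set with training sets of
    50/150/276 measured samples and 276 measured plus 50-997 simulated.
    """

    rows: list[tuple[int, int]]
    repeats: int = 10

    def __post_init__(self) -> None:
        for n_m, n_s in self.rows:
            if n_m < 0 or n_s < 0:
                raise ValueError("design counts must be nonnegative")


#: the published ten-row design (measured, simulated)
TABLE1_DESIGN = TrainingDesign(
    rows=[(50, 0), (150, 0), (276, 0), (276, 50), (276, 100),
          (276, 200), (276, 300), (276, 500), (276, 700), (276, 997)]
)


@dataclass
class EvalMetrics:
    r2: float
    rmse: float
    rrmse: float
    r2_raw: float = field(default=np.nan)

    def as_dict(self) -> dict[str, float]:
        return {"r2": self.r2, "rmse": self.rmse, "rrmse": self.rrmse}


@dataclass
class FittedModel:
    algorithm: str
    estimator: object
    hyperparameters: dict
    cv_mse: float
    feature_labels: Optional[list[str]] = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(np.asarray(X, dtype=float))).ravel()


def _make_estimator(algorithm: str, params: dict, seed: int):
    if algorithm == "PLSR":
        return PLSRegression(scale=True, **params)
    if algorithm == "SVMR":
        return SVR(kernel="rbf", **params)
    if algorithm == "RFR":
        return RandomForestRegressor(random_state=seed, **params)
    if algorithm == "BLR":
        return BayesianRidge(**params)
    raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")


def fit_regression(
    X: np.ndarray,
    y: np.ndarray,
    algorithm: str = "PLSR",
    cv: int = 5,
    seed: int = 0,
    grid: Optional[dict[str, list]] = None,
    feature_labels: Optional[list[str]] = None,
) -> FittedModel:
    """Grid-searched fit of one algorithm; final refit on all data."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")
    if X.shape[0] < cv:
        raise ValueError(f"need at least cv={cv} samples")
    if np.ptp(y) == 0:
        raise ValueError("degenerate response: y is constant")
    grid = DEFAULT_GRIDS[algorithm] if grid is None else grid

    # shared fold assignment across the whole grid
    folds = list(KFold(n_splits=cv, shuffle=True, random_state=seed).split(X))

    names = sorted(grid)
    combos = [dict(zip(names, vals))
              for vals in itertools.product(*(grid[n] for n in names))] or [{}]
    best: tuple[float, dict] | None = None
    for params in combos:
        p = dict(params)
        if algorithm == "PLSR":
            # components cannot exceed rank of the smallest training fold
            max_nc = min(min(len(tr) for tr, _ in folds) - 1, X.shape[1])
            if p["n_components"] > max_nc:
                continue
        errs = []
        for tr, te in folds:
            est = _make_estimator(algorithm, p, seed)
            est.fit(X[tr], y[tr])
            pred = np.asarray(est.predict(X[te])).ravel()
            errs.append(float(np.mean((y[te] - pred) ** 2)))
        mse = float(np.mean(errs))
        if best is None or mse < best[0]:
            best = (mse, p)
    assert best is not None, "no admissible grid point"
    est = _make_estimator(algorithm, best[1], seed)
    est.fit(X, y)
    return FittedModel(algorithm, est, best[1], best[0], feature_labels)


def evaluate(
    predicted: np.ndarray,
    measured: np.ndarray,
    clamp_negative_r2: bool = True,
) -> EvalMetrics:
    """R^2 / RMSE / RRMSE of predictions against measured values."""
    yhat = np.asarray(predicted, dtype=float).ravel()
    y = np.asarray(measured, dtype=float).ravel()
    if yhat.shape != y.shape:
        raise ValueError("predicted and measured lengths differ")
    if y.size < 2:
        raise ValueError("need at least 2 samples")
    ybar = y.mean()
    if ybar == 0:
        raise ValueError("mean of measured values is zero; RRMSE undefined")
    sse = float(np.sum((y - yhat) ** 2))
    sst = float(np.sum((y - ybar) ** 2))
    if sst == 0:
        raise ValueError("measured values are constant; R^2 undefined")
    r2_raw = 1.0 - sse / sst
    rmse = float(np.sqrt(sse / y.size))
    rrmse = rmse / ybar * 100.0
    r2 = max(0.0, r2_raw) if clamp_negative_r2 else r2_raw
    return EvalMetrics(r2=r2, rmse=rmse, rrmse=rrmse, r2_raw=r2_raw)


def assemble_training_sets(
    measured_X: np.ndarray,
    measured_y: np.ndarray,
    simulated_X: np.ndarray,
    simulated_y: np.ndarray,
    design: TrainingDesign,
    seed: int = 0,
) -> list[list[tuple[np.ndarray, np.ndarray]]]:
    """Per design row, draw ``repeats`` training sets.

    Measured samples are drawn without replacement; simulated samples are
    drawn without replacement from the simulated pool and appended.  Returns
    ``rows x repeats`` (X, y) pairs; reproducible under the seed.
    """
    measured_X = np.asarray(measured_X, dtype=float)
    simulated_X = np.asarray(simulated_X, dtype=float)
    measured_y = np.asarray(measured_y, dtype=float)
    simulated_y = np.asarray(simulated_y, dtype=float)
    rng = np.random.default_rng(seed)
    out = []
    for row_idx, (n_m, n_s) in enumerate(design.rows):
        if n_m > measured_X.shape[0]:
            raise ValueError(
                f"design row {row_idx}: {n_m} measured requested, "
                f"{measured_X.shape[0]} available"
            )
        if n_s > simulated_X.shape[0]:
            raise ValueError(
                f"design row {row_idx}: {n_s} simulated requested, "
                f"{simulated_X.shape[0]} available"
            )
        reps = []
        for _ in range(design.repeats):
            mi = rng.choice(measured_X.shape[0], size=n_m, replace=False)
            parts_X, parts_y = [measured_X[mi]], [measured_y[mi]]
            if n_s:
                si = rng.choice(simulated_X.shape[0], size=n_s, replace=False)
                parts_X.append(simulated_X[si])
                parts_y.append(simulated_y[si])
            reps.append((np.vstack(parts_X), np.concatenate(parts_y)))
        out.append(reps)
    return out


def augmentation_curve(
    measured_X: np.ndarray,
    measured_y: np.ndarray,
    simulated_X: np.ndarray,
    simulated_y: np.ndarray,
    val_X: np.ndarray,
    val_y: np.ndarray,
    design: TrainingDesign,
    algorithm: str = "PLSR",
    seed: int = 0,
    grid: Optional[dict[str, list]] = None,
) -> pd.DataFrame:
    """Mean validation metrics per design row (the data-augmentation curve).

    Every row x repeat assembles a training set, fits the algorithm and
    evaluates on the fixed validation set; per-row means are reported in
    design order.
    """
    sets = assemble_training_sets(
        measured_X, measured_y, simulated_X, simulated_y, design, seed
    )
    records = []
    for (n_m, n_s), reps in zip(design.rows, sets):
        train_metrics, val_metrics = [], []
        for rep_idx, (Xt, yt) in enumerate(reps):
            model = fit_regression(Xt, yt, algorithm, seed=seed + rep_idx, grid=grid)
            train_metrics.append(evaluate(model.predict(Xt), yt))
            val_metrics.append(evaluate(model.predict(val_X), val_y))
        records.append({
            "n_measured": n_m,
            "n_simulated": n_s,
            "train_r2": np.mean([m.r2 for m in train_metrics]),
            "train_rrmse": np.mean([m.rrmse for m in train_metrics]),
            "val_r2": np.mean([m.r2 for m in val_metrics]),
            "val_rmse": np.mean([m.rmse for m in val_metrics]),
            "val_rrmse": np.mean([m.rrmse for m in val_metrics]),
        })
    return pd.DataFrame.from_records(records)
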