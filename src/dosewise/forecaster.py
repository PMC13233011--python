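"""Supervised glucose forecasting at 30/60-minute horizons.

The forecasting arm mirrors the dosing agent's comparison methodology: a
model predicts glucose ``horizon_min`` ahead from the leakage-safe
engineered features, is fit on the training weeks only, and is scored on
the held-out week with MAE/RMSE and the time-in-range of its predictions,
always next to a persistence reference (predict the last observed
glucose) — the floor any learned forecaster must beat on structured data.

The model slot accepts any scikit-learn-style regressor (``fit(X, y)`` /
``predict(X)``); the default is a ridge regression on the feature table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge

from .features import DEFAULT_LAGS_MIN, DEFAULT_WINDOWS_MIN, featurize
from .metrics import mae as _mae, range_metrics, rmse as _rmse
from .ohio_io import STEP_MIN, PatientTimeline


@dataclass
class ForecastSpec:
    horizon_min: int = 30
    model: object = field(default_factory=lambda: Ridge(alpha=1.0))
    lags_min: Sequence[int] = DEFAULT_LAGS_MIN
    windows_min: Sequence[int] = DEFAULT_WINDOWS_MIN

    def __post_init__(self) -> None:
        if self.horizon_min <= 0 or self.horizon_min % STEP_MIN != 0:
            raise ValueError("horizon must be a positive multiple of 5 min")
        for attr in ("fit", "predict"):
            if not callable(getattr(self.model, attr, None)):
                raise TypeError("model must implement fit(X, y) and predict(X)")


class PersistenceRegressor:
    """The persistence reference expressed through the regressor contract."""

    def fit(self, X: pd.DataFrame, y) -> "PersistenceRegressor":
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return np.asarray(X["glucose_now"], dtype=float)


def make_supervised(timeline: PatientTimeline, features: pd.DataFrame,
                    horizon_min: int) -> tuple[pd.DataFrame, pd.Series]:
    """Pair features at t with glucose at t + horizon.

    The current glucose is prepended as the ``glucose_now`` column. Rows
    whose future target is missing are dropped; feature gaps are left to
    the fitting step.
    """
    if horizon_min <= 0 or horizon_min % STEP_MIN != 0:
        raise ValueError("horizon must be a positive multiple of 5 min")
    shift = horizon_min // STEP_MIN
    if shift >= len(timeline):
        raise ValueError(f"horizon {horizon_min} min exceeds the data extent")
    g = timeline.df["glucose"].where(~timeline.df["flag_gap_excluded"])
    X = features.copy()
    X.insert(0, "glucose_now", g)
    y = g.shift(-shift).rename("glucose_future")
    keep = y.notna()
    return X.loc[keep], y.loc[keep]


def persistence_baseline(glucose: pd.Series, horizon_min: int) -> pd.Series:
    """Predict glucose at each time as the reading ``horizon_min`` earlier."""
    if horizon_min <= 0 or horizon_min % STEP_MIN != 0:
        raise ValueError("horizon must be a positive multiple of 5 min")
    return glucose.shift(horizon_min // STEP_MIN).rename("persistence_pred")


def _score(pred: np.ndarray, actual: np.ndarray, low: float, high: float) -> dict:
    tir_pred, _, _ = range_metrics(pred, low, high)
    return {"mae": _mae(pred, actual), "rmse": _rmse(pred, actual),
            "tir_of_predictions": tir_pred, "n": int(np.sum(~np.isnan(pred * actual)))}


def fit_and_score(
    spec: ForecastSpec,
    splits: tuple[PatientTimeline, PatientTimeline, PatientTimeline],
    low: float = 70.0,
    high: float = 180.0,
) -> pd.DataFrame:
    """Fit on the training split, score on validation and test.

    Splits must be strictly ordered in time (as produced by
    ``time_blocked_split``); shuffled splits are refused. Returns one row
    per (split, model) with the persistence reference scored alongside.
    """
    train, val, test = splits
    bounds = [(t.df.index.min(), t.df.index.max()) for t in (train, val, test) if len(t)]
    for (lo_a, hi_a), (lo_b, _hi_b) in zip(bounds, bounds[1:]):
        if not hi_a < lo_b:
            raise ValueError("splits must be non-overlapping and ordered train < val < test")
    for t in (train, val, test):
        if not t.df.index.is_monotonic_increasing:
            raise ValueError("shuffled (non-temporal) splits are refused")

    def prepared(tl: PatientTimeline) -> tuple[pd.DataFrame, pd.Series]:
        feats = featurize(tl, spec.lags_min, spec.windows_min)
        X, y = make_supervised(tl, feats, spec.horizon_min)
        keep = X.notna().all(axis=1)
        return X.loc[keep], y.loc[keep]

    X_train, y_train = prepared(train)
    spec.model.fit(X_train, y_train)

    rows = []
    for name, tl in (("validation", val), ("test", test)):
        X, y = prepared(tl)
        if len(X) == 0:
            continue
        pred = np.asarray(spec.model.predict(X), dtype=float)
        rows.append({"split": name, "model": type(spec.model).__name__,
                     "horizon_min": spec.horizon_min, **_score(pred, y.to_numpy(), low, high)})
        persist = X["glucose_now"].to_numpy()
        rows.append({"split": name, "model": "persistence",
                     "horizon_min": spec.horizon_min, **_score(persist, y.to_numpy(), low, high)})
    return pd.DataFrame(rows)
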