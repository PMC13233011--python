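"""Temporally aware feature engineering for CGM series.

Builds the state-representation features: lagged glucose (30-60 min
prior), trailing rolling means and standard deviations (30/60-min
windows), clock features (hour of day), and elapsed time since the last
meal and last insulin dose. All features at row t are functions of rows
<= t only, so they are safe for forecasting without target leakage.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ohio_io import STEP_MIN, PatientTimeline

DEFAULT_LAGS_MIN: tuple[int, ...] = (30, 45, 60)
DEFAULT_WINDOWS_MIN: tuple[int, ...] = (30, 60)
ELAPSED_CAP_MIN = 720.0


def _check_multiples(values: Iterable[int], what: str) -> list[int]:
    out = sorted(set(int(v) for v in values))
    for v in out:
        if v <= 0 or v % STEP_MIN != 0:
            raise ValueError(f"{what} must be positive multiples of {STEP_MIN} min, got {v}")
    return out


def lag_features(glucose: pd.Series, lags_min: Sequence[int] = DEFAULT_LAGS_MIN) -> pd.DataFrame:
    """One column per lag: glucose shifted by lag/5 bins (missing at the head)."""
    lags = _check_multiples(lags_min, "lags")
    return pd.DataFrame(
        {f"lag_glucose_{k}": glucose.shift(k // STEP_MIN) for k in lags},
        index=glucose.index,
    )


def rolling_features(glucose: pd.Series, windows_min: Sequence[int] = DEFAULT_WINDOWS_MIN) -> pd.DataFrame:
    """Trailing rolling mean and sample SD per window, current bin included.

    Undefined (NaN) until the window is fully populated; any missing value
    inside the window propagates to the feature.
    """
    windows = _check_multiples(windows_min, "windows")
    cols = {}
    for w in windows:
        size = w // STEP_MIN
        roll = glucose.rolling(window=size, min_periods=size)
        cols[f"roll_mean_{w}"] = roll.mean()
        cols[f"roll_sd_{w}"] = roll.std(ddof=1)
    return pd.DataFrame(cols, index=glucose.index)


def time_features(timestamps: pd.DatetimeIndex | pd.Series) -> pd.Series:
    """Integer hour of day (0-23) per timestamp."""
    idx = pd.DatetimeIndex(timestamps)
    return pd.Series(idx.hour, index=idx, name="hour_of_day")


def elapsed_features(timeline: PatientTimeline, cap_min: float = ELAPSED_CAP_MIN) -> pd.DataFrame:
    """Minutes since the most recent meal and bolus at or before each bin.

    Before any event the elapsed time is the cap (default 720 min), which
    also bounds the feature for normalization.
    """
    df = timeline.df

    def since(mask: np.ndarray) -> np.ndarray:
        idx = np.arange(len(mask))
        last = np.where(mask, idx, -1)
        last = np.maximum.accumulate(last)
        mins = (idx - last) * STEP_MIN
        mins = np.where(last < 0, cap_min, mins).astype(float)
        return np.minimum(mins, cap_min)

    return pd.DataFrame(
        {
            "time_since_last_meal": since(df["carbs"].to_numpy() > 0),
            "time_since_last_dose": since(df["bolus_units"].to_numpy() > 0),
        },
        index=df.index,
    )


def featurize(
    timeline: PatientTimeline,
    lags_min: Sequence[int] = DEFAULT_LAGS_MIN,
    windows_min: Sequence[int] = DEFAULT_WINDOWS_MIN,
) -> pd.DataFrame:
    """Full feature table: lags, rolling stats, clock, elapsed times.

    Glucose in rows flagged ``gap_excluded`` is treated as missing, so
    features depending on those bins are missing too.
    """
    g = timeline.df["glucose"].where(~timeline.df["flag_gap_excluded"])
    parts = [
        lag_features(g, lags_min),
        rolling_features(g, windows_min),
        time_features(timeline.df.index).to_frame(),
        elapsed_features(timeline),
    ]
    out = pd.concat(parts, axis=1)
    out.index = timeline.df.index
    return out
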