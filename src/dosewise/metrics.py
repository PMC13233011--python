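"""Error and glycemic-range metrics, and small-sample summary statistics.

Forecast accuracy is scored with mean absolute error (MAE) and root mean
square error (RMSE), both in mg/dL. Glycemic control is scored as the
percentage of readings in, below, and above a target range (TIR/TBR/TAR);
the conventional clinical range is 70-180 mg/dL, closed on both ends.
Cross-model comparisons are summarised as mean (sample SD) with a two-sided
Student-t confidence interval, which is the appropriate interval at the
very small n (often n=2) these comparisons involve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class Metrics:
    """Paired forecast-error and range metrics for one evaluation.

    Percentages always sum to 100 over the non-missing readings.
    """

    mae: float
    rmse: float
    tir: float
    tbr: float
    tar: float
    mean_reward: float
    n: int

    def __post_init__(self) -> None:
        if self.n > 0:
            if self.rmse + 1e-12 < self.mae:
                raise ValueError("RMSE cannot be smaller than MAE")
            total = self.tir + self.tbr + self.tar
            if abs(total - 100.0) > 1e-9:
                raise ValueError(f"TIR+TBR+TAR must be 100, got {total}")


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    n: int


def _paired(predicted, actual) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {a.shape}")
    keep = ~(np.isnan(p) | np.isnan(a))
    p, a = p[keep], a[keep]
    if p.size == 0:
        raise ValueError("no non-missing pairs to score")
    return p, a


def mae(predicted, actual) -> float:
    """Mean absolute error over pairwise non-missing readings, mg/dL."""
    p, a = _paired(predicted, actual)
    return float(np.mean(np.abs(p - a)))


def rmse(predicted, actual) -> float:
    """Root mean square error over pairwise non-missing readings, mg/dL."""
    p, a = _paired(predicted, actual)
    return float(np.sqrt(np.mean((p - a) ** 2)))


def range_metrics(glucose, low: float = 70.0, high: float = 180.0) -> tuple[float, float, float]:
    """Percent of readings in/below/above [low, high], closed interval.

    Missing (NaN) readings are excluded from both numerator and denominator.
    Returns ``(tir, tbr, tar)``; the three always sum to exactly 100.
    """
    g = np.asarray(glucose, dtype=float)
    g = g[~np.isnan(g)]
    if g.size == 0:
        raise ValueError("no non-missing readings")
    n = g.size
    tbr = np.count_nonzero(g < low)
    tar = np.count_nonzero(g > high)
    tir = n - tbr - tar
    return 100.0 * tir / n, 100.0 * tbr / n, 100.0 * tar / n


def mean_sd_ci(values, conf: float = 0.95) -> SummaryStats:
    """Mean, sample SD (n-1 denominator) and two-sided Student-t CI.

    With n=2 the t quantile is large (t_{0.975,1} = 12.706), producing the
    very wide intervals characteristic of two-model comparisons.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty value list")
    m = float(np.mean(v))
    if v.size == 1:
        raise ValueError("CI undefined for a single value (need n >= 2)")
    sd = float(np.std(v, ddof=1))
    if conf == 0.0:
        return SummaryStats(mean=m, sd=sd, ci_low=m, ci_high=m, n=int(v.size))
    t = float(stats.t.ppf((1.0 + conf) / 2.0, df=v.size - 1))
    half = t * sd / np.sqrt(v.size)
    return SummaryStats(mean=m, sd=sd, ci_low=m - half, ci_high=m + half, n=int(v.size))


def evaluate_series(predicted, actual, rewards=None, low: float = 70.0, high: float = 180.0) -> Metrics:
    """Bundle MAE/RMSE on the pairs and range metrics on the actual series."""
    p, a = _paired(predicted, actual)
    tir, tbr, tar = range_metrics(a, low, high)
    mean_reward = float(np.mean(rewards)) if rewards is not None and len(rewards) else float("nan")
    return Metrics(
        mae=float(np.mean(np.abs(p - a))),
        rmse=float(np.sqrt(np.mean((p - a) ** 2))),
        tir=tir,
        tbr=tbr,
        tar=tar,
        mean_reward=mean_reward,
        n=int(p.size),
    )
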