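"""Safety-aware reward family for glucose control.

The agent earns a fixed bonus (+10) whenever glucose sits inside the target
range [L, H] (default 70-180 mg/dL) and an adaptive penalty outside it that
grows linearly with the distance to the nearer range boundary, at one point
per 10 mg/dL. Excursions past the extreme thresholds (<70 or >250 mg/dL)
are doubled, and the penalty is floored at -2x the bonus so Q-value scales
stay bounded during training. Optional components:

* ``asymmetric`` -- hypoglycemia penalties scaled by a factor lambda >= 1,
  encoding that lows are clinically more dangerous than highs;
* ``stability`` -- a penalty on |dG/dt| above a threshold rate, discouraging
  rapid glucose swings;
* ``iob`` -- a penalty on insulin-on-board above a cap, discouraging
  insulin stacking;
* ``full`` -- all of the above.

``sensitivity_grid`` sweeps reward variants against alternative glycemic
threshold sets (70-180, 80-160, 70-140 mg/dL) and tabulates control and
error metrics per cell.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .metrics import mae as _mae, range_metrics, rmse as _rmse

VARIANTS = ("baseline", "asymmetric", "stability", "iob", "full")


@dataclass(frozen=True)
class RewardConfig:
    target_low: float = 70.0
    target_high: float = 180.0
    extreme_low: float = 70.0
    extreme_high: float = 250.0
    in_range_bonus: float = 10.0
    penalty_per_10mgdl: float = 1.0
    extreme_multiplier: float = 2.0
    hypo_asymmetry: float = 2.0
    stability_weight: float = 1.0
    stability_threshold: float = 2.0  # mg/dL per min
    iob_weight: float = 1.0
    iob_cap: float = 3.0  # U
    variant: str = "baseline"

    def __post_init__(self) -> None:
        if not self.target_low < self.target_high:
            raise ValueError("target_low must be < target_high")
        if self.extreme_high <= self.target_high:
            raise ValueError("extreme_high must exceed target_high")
        if self.hypo_asymmetry < 1.0:
            raise ValueError("hypo_asymmetry must be >= 1")
        for name in ("penalty_per_10mgdl", "extreme_multiplier", "stability_weight", "iob_weight"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; one of {VARIANTS}")

    def with_range(self, low: float, high: float) -> "RewardConfig":
        return replace(self, target_low=low, target_high=high)


def _penalty_floor(cfg: RewardConfig) -> float:
    return -2.0 * cfg.in_range_bonus


def reward_base(glucose: float, cfg: RewardConfig | None = None) -> float:
    """In-range bonus or severity-scaled out-of-range penalty.

    ``glucose`` must already be clipped to the sensor band [40, 400].
    """
    cfg = cfg or RewardConfig()
    if not 40.0 <= glucose <= 400.0:
        raise ValueError(f"glucose {glucose} outside [40, 400]; upstream clipping failed")
    if cfg.target_low <= glucose <= cfg.target_high:
        return cfg.in_range_bonus
    if glucose < cfg.target_low:
        dist = cfg.target_low - glucose
        extreme = glucose < cfg.extreme_low
    else:
        dist = glucose - cfg.target_high
        extreme = glucose > cfg.extreme_high
    pen = -(dist / 10.0) * cfg.penalty_per_10mgdl
    if extreme:
        pen *= cfg.extreme_multiplier
    return max(pen, _penalty_floor(cfg))


def reward_asymmetric(glucose: float, cfg: RewardConfig | None = None) -> float:
    """As ``reward_base`` with hypo-side penalties scaled by lambda."""
    cfg = cfg or RewardConfig()
    r = reward_base(glucose, cfg)
    if glucose < cfg.target_low and r < 0:
        r = max(r * cfg.hypo_asymmetry, _penalty_floor(cfg))
    return r


def stability_term(dg_dt: float, cfg: RewardConfig | None = None) -> float:
    """Penalty on the absolute glucose rate beyond the dead-zone threshold."""
    cfg = cfg or RewardConfig()
    if not np.isfinite(dg_dt):
        raise ValueError("dG/dt must be finite")
    return -cfg.stability_weight * max(0.0, abs(dg_dt) - cfg.stability_threshold)


def iob_term(iob: float, cfg: RewardConfig | None = None) -> float:
    """Penalty on insulin-on-board above the stacking cap."""
    cfg = cfg or RewardConfig()
    if iob < 0:
        raise ValueError("IOB must be >= 0")
    return -cfg.iob_weight * max(0.0, iob - cfg.iob_cap)


def total_reward(prev_glucose: float, next_glucose: float, iob: float,
                 cfg: RewardConfig | None = None) -> float:
    """Variant-selected sum of the reward components.

    The glucose rate is taken over one native 5-min step:
    dG/dt = (next - prev) / 5 in mg/dL per min.
    """
    cfg = cfg or RewardConfig()
    dg_dt = (next_glucose - prev_glucose) / 5.0
    if cfg.variant == "baseline":
        return reward_base(next_glucose, cfg)
    if cfg.variant == "asymmetric":
        return reward_asymmetric(next_glucose, cfg)
    if cfg.variant == "stability":
        return reward_base(next_glucose, cfg) + stability_term(dg_dt, cfg)
    if cfg.variant == "iob":
        return reward_base(next_glucose, cfg) + iob_term(iob, cfg)
    if cfg.variant == "full":
        return (reward_asymmetric(next_glucose, cfg)
                + stability_term(dg_dt, cfg)
                + iob_term(iob, cfg))
    raise ValueError(f"unknown variant {cfg.variant!r}")


DEFAULT_THRESHOLD_SETS: tuple[tuple[float, float], ...] = ((70, 180), (80, 160), (70, 140))


def _rollout(env, policy: Callable[[np.ndarray], int]) -> dict[str, np.ndarray]:
    obs = env.reset()
    glucose, rewards, iobs = [], [], []
    done = False
    while not done:
        action = policy(obs)
        obs, reward, done, info = env.step(action)
        glucose.append(info["glucose"])
        iobs.append(info["iob"])
        rewards.append(reward)
    return {
        "glucose": np.asarray(glucose),
        "rewards": np.asarray(rewards),
        "iob": np.asarray(iobs),
    }


def sensitivity_grid(
    policy: Callable[[np.ndarray], int] | Mapping[str, Callable[[np.ndarray], int]],
    env_factory: Callable[..., object],
    threshold_sets: Sequence[tuple[float, float]] = DEFAULT_THRESHOLD_SETS,
    variants: Sequence[str] = ("baseline", "asymmetric", "stability", "iob"),
    n_episodes: int = 5,
    seeds: Sequence[int] = (1, 2, 3, 4, 5),
    reward_cfg: RewardConfig | None = None,
) -> pd.DataFrame:
    """Threshold x variant sensitivity table over paired-seed rollouts.

    ``policy`` is either a single callable (state vector -> action index),
    used in every cell, or a mapping from variant name to callable, e.g.
    policies trained under each reward variant. ``env_factory(seed=...,
    reward_cfg=...)`` must build a fresh environment; seeds are shared
    across cells so comparisons between rows are paired.

    Each row carries TIR/TBR/TAR (under that row's thresholds), MAE and
    RMSE of the one-step-ahead persistence of glucose (a trajectory
    smoothness measure), and mean per-episode cumulative reward, each as
    ``mean`` and ``sd`` over seeds.
    """
    if not variants:
        raise ValueError("variants must be non-empty")
    base = reward_cfg or RewardConfig()
    rows = []
    for (low, high), variant in itertools.product(threshold_sets, variants):
        cfg = replace(base, target_low=low, target_high=high, variant=variant)
        pol = policy[variant] if isinstance(policy, Mapping) else policy
        per_seed: dict[str, list[float]] = {k: [] for k in ("tir", "tbr", "tar", "mae", "rmse", "mean_reward")}
        for seed in seeds:
            g_all, ret = [], []
            for ep in range(n_episodes):
                env = env_factory(seed=int(seed) * 10_000 + ep, reward_cfg=cfg)
                tr = _rollout(env, pol)
                g_all.append(tr["glucose"])
                ret.append(float(tr["rewards"].sum()))
            g = np.concatenate(g_all)
            tir, tbr, tar = range_metrics(g, low, high)
            per_seed["tir"].append(tir)
            per_seed["tbr"].append(tbr)
            per_seed["tar"].append(tar)
            per_seed["mae"].append(_mae(g[:-1], g[1:]))
            per_seed["rmse"].append(_rmse(g[:-1], g[1:]))
            per_seed["mean_reward"].append(float(np.mean(ret)))
        row = {"low": low, "high": high, "variant": variant}
        for key, vals in per_seed.items():
            row[f"{key}_mean"] = float(np.mean(vals))
            row[f"{key}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
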