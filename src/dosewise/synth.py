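"""Synthetic T1D cohort generator in the OhioT1DM event-stream layout.

The real dataset is restricted by a data-use agreement, so this module
produces structurally faithful stand-ins: per-patient 8-week logs on a
5-minute CGM grid with user-entered meals and boluses, exercise bouts, a
held basal rate, band heart rate, sensor dropout gaps (including one long
gap per week), and occasional non-physiologic spikes. Glucose itself is
produced by the simulator dynamics in :mod:`dosewise.environment`, driven
by the sampled behavior, so every channel carries the correlations the
downstream models rely on (boluses track meal carbs through a noisy carb
ratio; exercise lowers glucose and raises heart rate).

All sampling is driven by a single seed; the same seed reproduces the
same patient bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
from lxml import etree

from .environment import (
    EnvConfig,
    GlucoseSim,
    MealExerciseSchedule,
    _triangle_cum,
)
from .ohio_io import STEP_MIN, TS_FORMAT, EventStream, RawEvent
from .rewards import RewardConfig

BINS_PER_DAY = 24 * 60 // STEP_MIN  # 288
MEAL_ANCHORS_H = (8.0, 13.0, 19.0)


@dataclass(frozen=True)
class BehaviorConfig:
    """Distributions describing patient behavior and sensor corruption."""

    meals_per_day: float = 3.0
    meal_time_jitter_sd_min: float = 45.0
    carbs_mean_g: float = 50.0
    carbs_sd_g: float = 20.0
    carb_ratio: float = 0.1          # U per g
    bolus_noise_sd: float = 0.15     # multiplicative
    bolus_omission_prob: float = 0.05
    exercise_bouts_per_week: float = 4.0
    exercise_duration_range_min: tuple[float, float] = (20.0, 60.0)
    sensor_noise_sd: float = 2.0     # mg/dL, added to the true trace
    gap_dropout_prob: float = 0.005  # per bin
    long_gaps_per_week: float = 1.0  # each > 15 min
    spike_prob: float = 0.001        # per bin, value pushed above 400

    def __post_init__(self) -> None:
        for name in ("bolus_omission_prob", "gap_dropout_prob", "spike_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if self.carbs_mean_g < 0:
            raise ValueError("carbs must be >= 0")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def sample_schedule(behavior: BehaviorConfig, rng: np.random.Generator,
                    days: float) -> MealExerciseSchedule:
    """Sample meal times/carbs and exercise bouts for ``days`` of behavior."""
    mu, sigma = _lognormal_params(behavior.carbs_mean_g, behavior.carbs_sd_g)
    n_days = int(np.ceil(days))
    per_anchor = behavior.meals_per_day / len(MEAL_ANCHORS_H)
    meal_min, meal_carbs = [], []
    for d in range(n_days):
        for anchor in MEAL_ANCHORS_H:
            if rng.random() >= min(1.0, per_anchor):
                continue
            t = d * 1440.0 + anchor * 60.0 + rng.normal(0.0, behavior.meal_time_jitter_sd_min)
            t = float(np.clip(t, d * 1440.0, (d + 1) * 1440.0 - STEP_MIN))
            meal_min.append(t)
            meal_carbs.append(float(rng.lognormal(mu, sigma)))

    n_bouts = rng.poisson(behavior.exercise_bouts_per_week * days / 7.0)
    lo, hi = behavior.exercise_duration_range_min
    ex_start = np.sort(rng.uniform(7 * 60.0, 21 * 60.0, n_bouts)
                       + rng.integers(0, max(1, n_days), n_bouts) * 1440.0)
    ex_dur = rng.uniform(lo, hi, n_bouts)
    ex_int = rng.integers(1, 6, n_bouts).astype(float)
    return MealExerciseSchedule(
        meal_minutes=np.asarray(meal_min, dtype=float),
        meal_carbs=np.asarray(meal_carbs, dtype=float),
        exercise_start_min=ex_start,
        exercise_duration_min=ex_dur,
        exercise_intensity=ex_int,
    )


def _bolus_plan(schedule: MealExerciseSchedule, behavior: BehaviorConfig,
                rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Bolus (minute, units) pairs from meals via a noisy carb ratio."""
    times, doses = [], []
    for t, carbs in zip(schedule.meal_minutes, schedule.meal_carbs):
        if rng.random() < behavior.bolus_omission_prob:
            continue
        dose = carbs * behavior.carb_ratio * max(0.0, 1.0 + rng.normal(0.0, behavior.bolus_noise_sd))
        times.append(t)
        doses.append(round(dose, 1))
    return np.asarray(times, dtype=float), np.asarray(doses, dtype=float)


def _profile_kernel(cum_peak: float, cum_end: float, n_bins: int) -> np.ndarray:
    """Per-bin delivered fractions; index j covers ages [(j-1)*5, j*5)."""
    edges = np.arange(n_bins + 1) * STEP_MIN
    cum = np.array([_triangle_cum(e, cum_peak, cum_end) for e in edges])
    return np.diff(cum)


def _simulate_glucose(env_cfg: EnvConfig, schedule: MealExerciseSchedule,
                      bolus_min: np.ndarray, bolus_units: np.ndarray,
                      n_bins: int, rng: np.random.Generator) -> np.ndarray:
    """Run the simulator dynamics over ``n_bins`` with behavior inputs."""
    act_kernel = _profile_kernel(0.4 * env_cfg.dia_min, float(env_cfg.dia_min),
                                 int(np.ceil(env_cfg.dia_min / STEP_MIN)) + 1)
    carb_kernel = _profile_kernel(20.0, 60.0, 60 // STEP_MIN + 1)

    dose_impulse = np.zeros(n_bins)
    for t, u in zip(bolus_min, bolus_units):
        b = int(t // STEP_MIN)
        if 0 <= b < n_bins:
            dose_impulse[b] += u
    carb_impulse = np.zeros(n_bins)
    for t, g in zip(schedule.meal_minutes, schedule.meal_carbs):
        b = int(t // STEP_MIN)
        if 0 <= b < n_bins:
            carb_impulse[b] += g
    # events in bin s begin acting the following bin (kernel index j >= 1)
    activity = np.convolve(dose_impulse, np.concatenate([[0.0], act_kernel]))[:n_bins]
    absorbed = np.convolve(carb_impulse, np.concatenate([[0.0], carb_kernel]))[:n_bins]

    intensity = np.zeros(n_bins)
    for start, dur, inten in zip(schedule.exercise_start_min,
                                 schedule.exercise_duration_min,
                                 schedule.exercise_intensity):
        b0, b1 = int(start // STEP_MIN), int(np.ceil((start + dur) / STEP_MIN))
        intensity[max(0, b0):min(n_bins, b1)] = inten

    noise = rng.normal(0.0, env_cfg.noise_sd, n_bins)
    g = np.empty(n_bins)
    cur = env_cfg.basal_glucose
    k = env_cfg.reversion_rate * env_cfg.step_min
    for i in range(n_bins):
        cur = (cur - k * (cur - env_cfg.basal_glucose)
               + env_cfg.carb_gain * absorbed[i]
               - env_cfg.insulin_sensitivity * activity[i]
               - env_cfg.exercise_effect * intensity[i] * env_cfg.step_min
               + noise[i])
        cur = float(np.clip(cur, env_cfg.glucose_lo, env_cfg.glucose_hi))
        g[i] = cur
    return g


def generate_patient(
    env_cfg: EnvConfig | None = None,
    behavior: BehaviorConfig | None = None,
    weeks: int = 8,
    seed: int = 0,
    patient_id: str = "synth-000",
    cohort: str = "2018",
    start_time: datetime = datetime(2021, 7, 1, 0, 0),
) -> EventStream:
    """Generate one patient's event stream: truth, then sensor corruption."""
    if weeks < 1:
        raise ValueError("weeks must be >= 1")
    env_cfg = env_cfg or EnvConfig()
    behavior = behavior or BehaviorConfig()
    rng = np.random.default_rng(seed)
    n_bins = weeks * 7 * BINS_PER_DAY

    schedule = sample_schedule(behavior, rng, days=weeks * 7)
    bolus_min, bolus_units = _bolus_plan(schedule, behavior, rng)
    true_g = _simulate_glucose(env_cfg, schedule, bolus_min, bolus_units, n_bins, rng)

    measured = true_g + rng.normal(0.0, behavior.sensor_noise_sd, n_bins)
    measured = np.clip(measured, env_cfg.glucose_lo, env_cfg.glucose_hi)

    # corruption: dropout, one long gap per week, occasional spikes
    drop = rng.random(n_bins) < behavior.gap_dropout_prob
    for w in range(int(round(behavior.long_gaps_per_week * weeks))):
        gap_bins = int(rng.integers(5, 25))  # 25-120 min, always > 15 min
        start = int(rng.integers(w * 7 * BINS_PER_DAY,
                                 min(n_bins, (w + 1) * 7 * BINS_PER_DAY) - gap_bins))
        drop[start:start + gap_bins] = True
    spike = (rng.random(n_bins) < behavior.spike_prob) & ~drop
    measured[spike] = rng.uniform(410.0, 500.0, int(spike.sum()))

    events: list[RawEvent] = []
    for i in range(n_bins):
        if drop[i]:
            continue
        ts = start_time + timedelta(minutes=i * STEP_MIN)
        events.append(RawEvent("glucose", ts, round(float(measured[i]), 1)))

    for t, carbs in zip(schedule.meal_minutes, schedule.meal_carbs):
        ts = start_time + timedelta(minutes=round(t))
        events.append(RawEvent("meal", ts, round(float(carbs), 1),
                               {"meal_type": "meal"}))
    for t, u in zip(bolus_min, bolus_units):
        if u <= 0:
            continue
        square = rng.random() < 0.05
        dur = float(rng.integers(6, 13) * STEP_MIN) if square else 0.0
        events.append(RawEvent(
            "bolus", start_time + timedelta(minutes=round(t)), float(u),
            {"bolus_type": "square" if square else "normal", "duration_min": dur}))
    for s, d, inten in zip(schedule.exercise_start_min,
                           schedule.exercise_duration_min,
                           schedule.exercise_intensity):
        events.append(RawEvent("exercise", start_time + timedelta(minutes=round(float(s))),
                               float(inten), {"duration_min": round(float(d))}))

    # held basal rate, re-announced daily with small drift
    rate = 1.0
    for d in range(weeks * 7):
        rate = float(np.clip(rate * (1.0 + rng.normal(0.0, 0.05)), 0.5, 2.0))
        events.append(RawEvent("basal", start_time + timedelta(days=d), round(rate, 2)))

    # band heart rate at the grid cadence: resting + exercise elevation
    intensity = np.zeros(n_bins)
    for s, d, inten in zip(schedule.exercise_start_min,
                           schedule.exercise_duration_min,
                           schedule.exercise_intensity):
        b0, b1 = int(s // STEP_MIN), int(np.ceil((s + d) / STEP_MIN))
        intensity[max(0, b0):min(n_bins, b1)] = inten
    hr = 62.0 + 14.0 * intensity + rng.normal(0.0, 3.0, n_bins)
    for i in range(0, n_bins, 3):  # 15-min cadence keeps files light
        ts = start_time + timedelta(minutes=i * STEP_MIN)
        events.append(RawEvent("heart_rate", ts, round(float(hr[i]), 1)))

    return EventStream(patient_id=patient_id, cohort=cohort, events=events)


def generate_cohort(
    n: int = 12,
    base_seed: int = 0,
    env_cfg: EnvConfig | None = None,
    behavior: BehaviorConfig | None = None,
    weeks: int = 8,
) -> list[EventStream]:
    """Generate ``n`` patients with per-patient physiological jitter.

    Insulin sensitivity is jittered +/-25% and basal glucose +/-15 mg/dL
    around the base configuration; patients split evenly across the 2018
    and 2020 cohort labels.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    env_cfg = env_cfg or EnvConfig()
    behavior = behavior or BehaviorConfig()
    master = np.random.default_rng(base_seed)
    streams = []
    for i in range(n):
        jit = np.random.default_rng(master.integers(0, 2**31))
        cfg_i = replace(
            env_cfg,
            insulin_sensitivity=env_cfg.insulin_sensitivity * float(jit.uniform(0.75, 1.25)),
            basal_glucose=env_cfg.basal_glucose + float(jit.uniform(-15.0, 15.0)),
        )
        streams.append(generate_patient(
            cfg_i, behavior, weeks=weeks, seed=int(jit.integers(0, 2**31)),
            patient_id=f"synth-{i:03d}", cohort="2018" if i < (n + 1) // 2 else "2020",
        ))
    return streams


# ---------------------------------------------------------------------------
# XML serialization
# ---------------------------------------------------------------------------

def write_ohio_xml(stream: EventStream, path: str | Path) -> None:
    """Serialize a stream in the OhioT1DM XML layout (round-trip safe)."""
    root = etree.Element("patient", id=stream.patient_id, cohort=stream.cohort)
    sections: dict[str, etree._Element] = {}
    section_order = ["glucose_level", "basal", "bolus", "meal", "exercise",
                     "basis_heart_rate", "basis_gsr", "basis_skin_temperature",
                     "basis_steps", "basis_sleep"]
    for name in section_order:
        sections[name] = etree.SubElement(root, name)

    element_of = {
        "glucose": ("glucose_level", "value"),
        "bolus": ("bolus", "dose"),
        "basal": ("basal", "value"),
        "meal": ("meal", "carbs"),
        "exercise": ("exercise", "intensity"),
        "heart_rate": ("basis_heart_rate", "value"),
        "gsr": ("basis_gsr", "value"),
        "skin_temp": ("basis_skin_temperature", "value"),
        "steps": ("basis_steps", "value"),
        "sleep": ("basis_sleep", "quality"),
    }
    for e in stream.events:
        section, value_attr = element_of[e.kind]
        ts = e.timestamp.strftime(TS_FORMAT)
        attrs = {value_attr: repr(e.value)}
        if e.kind == "bolus":
            end = e.timestamp + timedelta(minutes=e.extra.get("duration_min", 0.0))
            attrs = {"ts_begin": ts, "ts_end": end.strftime(TS_FORMAT),
                     "type": e.extra.get("bolus_type", "normal"), value_attr: repr(e.value)}
        else:
            attrs["ts"] = ts
            if e.kind == "meal" and "meal_type" in e.extra:
                attrs["type"] = e.extra["meal_type"]
            if e.kind == "exercise" and "duration_min" in e.extra:
                attrs["duration"] = repr(float(e.extra["duration_min"]))
        etree.SubElement(sections[section], "event", **attrs)

    tree = etree.ElementTree(root)
    tree.write(str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8")


def make_env_factory(
    env_cfg: EnvConfig | None = None,
    behavior: BehaviorConfig | None = None,
    reward_cfg: RewardConfig | None = None,
):
    """Factory of fresh simulators with behavior sampled per seed.

    The returned callable has signature ``factory(seed, reward_cfg=None)``,
    as expected by the training loop and the sensitivity grid; a schedule
    covering the episode is drawn from ``behavior`` using the seed.
    """
    env_cfg = env_cfg or EnvConfig()
    behavior = behavior or BehaviorConfig()
    base_reward = reward_cfg or RewardConfig()

    def factory(seed: int, reward_cfg: RewardConfig | None = None) -> GlucoseSim:
        rng = np.random.default_rng(int(seed))
        days = env_cfg.episode_len * STEP_MIN / 1440.0 + 1
        schedule = sample_schedule(behavior, rng, days=days)
        return GlucoseSim(env_cfg, seed=int(seed), schedule=schedule,
                          reward_cfg=reward_cfg or base_reward)

    return factory
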