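"""Seedable glucose-insulin simulation environment for dosing agents.

The simulator is a minimal mean-reverting model of interstitial glucose on
a 5-minute grid with additive meal, insulin, and exercise effects:

    G_{t+1} = clip( G_t - p1 * dt * (G_t - G_b)
                    + k_c * carbs_absorbed_t
                    - S_I * insulin_activity_t
                    - k_e * intensity_t * dt
                    + eps_t ,  40, 400 )

where ``p1`` (per minute) pulls glucose back to the basal level ``G_b``,
``S_I`` is insulin sensitivity (mg/dL drop per unit of insulin activity),
``k_c`` converts absorbed carbohydrate grams to a glucose rise, ``k_e``
scales the exercise effect, and ``eps_t ~ N(0, noise_sd^2)``. Insulin
activity follows a triangular profile peaking at 0.4 x DIA (96 min for the
default 240-min DIA, inside the 90-120-min peak-action band of
rapid-acting insulin) and integrating exactly to the delivered dose; meal
carbohydrate appears over 60 min with a 20-min peak. A dose taken at the
start of a bin begins acting the following bin, so there is no same-bin
instantaneous insulin effect.

The agent observes a 2-hour (24-bin) sliding window of glucose, insulin
doses, carbs and exercise intensity, plus elapsed-time and clock features
and insulin-on-board, and chooses among discrete bolus doses. The
environment follows the conventional RL contract:
``reset() -> observation``, ``step(action) -> (observation, reward,
done, info)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np

from .rewards import RewardConfig, total_reward

STEP_MIN = 5
WINDOW_BINS = 24  # 2-hour window on the 5-min grid
ELAPSED_CAP_MIN = 720.0

# encode_state normalization constants
_GLUCOSE_SCALE = 400.0
_INSULIN_SCALE = 5.0
_CARB_SCALE = 100.0
_EXERCISE_SCALE = 5.0
_ELAPSED_SCALE = ELAPSED_CAP_MIN
_HOUR_SCALE = 24.0
_IOB_SCALE = 10.0

STATE_DIM = 4 * WINDOW_BINS + 4  # windows + 2 elapsed + hour + iob


@dataclass(frozen=True)
class EnvConfig:
    """Simulator parameters; defaults define the study conditions."""

    step_min: int = STEP_MIN
    window_min: int = 120
    basal_glucose: float = 120.0     # G_b, mg/dL
    reversion_rate: float = 0.01     # p1, per min
    insulin_sensitivity: float = 40.0  # S_I, mg/dL per U of activity
    carb_gain: float = 3.5           # k_c, mg/dL per g absorbed
    exercise_effect: float = 0.1     # k_e, mg/dL per intensity-min
    noise_sd: float = 2.0            # mg/dL per step
    action_doses: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5)
    episode_len: int = 1500          # steps; the per-episode transition budget
    dia_min: int = 240
    glucose_lo: float = 40.0
    glucose_hi: float = 400.0

    def __post_init__(self) -> None:
        if 0.0 not in self.action_doses:
            raise ValueError("action_doses must include 0 (a 'no dose' action)")
        for name in ("reversion_rate", "insulin_sensitivity", "carb_gain",
                     "exercise_effect", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.window_min % self.step_min != 0:
            raise ValueError("window_min must be a multiple of step_min")


@dataclass(frozen=True)
class MealExerciseSchedule:
    """Scheduled behavior events driving an episode, in episode minutes."""

    meal_minutes: np.ndarray = field(default_factory=lambda: np.empty(0))
    meal_carbs: np.ndarray = field(default_factory=lambda: np.empty(0))
    exercise_start_min: np.ndarray = field(default_factory=lambda: np.empty(0))
    exercise_duration_min: np.ndarray = field(default_factory=lambda: np.empty(0))
    exercise_intensity: np.ndarray = field(default_factory=lambda: np.empty(0))

    @staticmethod
    def empty() -> "MealExerciseSchedule":
        return MealExerciseSchedule()


@dataclass
class EnvState:
    """The observable state: 2-hour windows plus elapsed/clock features."""

    glucose_window: np.ndarray
    insulin_window: np.ndarray
    carb_window: np.ndarray
    exercise_window: np.ndarray
    time_since_last_meal: float
    time_since_last_dose: float
    hour_of_day: int
    iob: float


# ---------------------------------------------------------------------------
# Pharmacodynamic profiles
# ---------------------------------------------------------------------------

def _triangle_density(m: float, peak: float, end: float) -> float:
    if m < 0 or m >= end:
        return 0.0
    h = 2.0 / end  # unit area
    if m <= peak:
        return h * m / peak
    return h * (end - m) / (end - peak)


def _triangle_cum(m: float, peak: float, end: float) -> float:
    """Area of the unit triangle from 0 to m (fraction delivered)."""
    if m <= 0:
        return 0.0
    if m >= end:
        return 1.0
    h = 2.0 / end
    if m <= peak:
        return 0.5 * h * m * m / peak
    tail = end - m
    return 1.0 - 0.5 * h * tail * tail / (end - peak)


def insulin_activity(dose: float, minutes_since: float, dia_min: int = 240) -> float:
    """Insulin activity rate (U/min) of a bolus ``minutes_since`` delivery.

    Triangular profile: rises to a peak at 0.4 x DIA and returns to zero at
    DIA; the profile integrates to the full dose.
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    if minutes_since < 0:
        raise ValueError("minutes_since must be >= 0")
    return dose * _triangle_density(minutes_since, 0.4 * dia_min, float(dia_min))


def carb_appearance(carbs: float, minutes_since: float) -> float:
    """Carbohydrate appearance rate (g/min): triangular over 60 min, 20-min peak."""
    if carbs < 0:
        raise ValueError("carbs must be >= 0")
    return carbs * _triangle_density(minutes_since, 20.0, 60.0)


def _bin_fraction(cum, age_end_min: float) -> float:
    """Fraction of a profile delivered within the bin ending at ``age_end_min``."""
    return cum(age_end_min) - cum(age_end_min - STEP_MIN)


# ---------------------------------------------------------------------------
# State encoding
# ---------------------------------------------------------------------------

def encode_state(state: EnvState) -> np.ndarray:
    """Normalized fixed-length vector of length :data:`STATE_DIM`."""
    return np.concatenate([
        np.asarray(state.glucose_window) / _GLUCOSE_SCALE,
        np.asarray(state.insulin_window) / _INSULIN_SCALE,
        np.asarray(state.carb_window) / _CARB_SCALE,
        np.asarray(state.exercise_window) / _EXERCISE_SCALE,
        [state.time_since_last_meal / _ELAPSED_SCALE,
         state.time_since_last_dose / _ELAPSED_SCALE,
         state.hour_of_day / _HOUR_SCALE,
         state.iob / _IOB_SCALE],
    ])


def decode_state(vec: np.ndarray) -> EnvState:
    """Inverse of :func:`encode_state` (exact up to float arithmetic)."""
    v = np.asarray(vec, dtype=float)
    if v.size != STATE_DIM:
        raise ValueError(f"expected vector of length {STATE_DIM}, got {v.size}")
    w = WINDOW_BINS
    return EnvState(
        glucose_window=v[0:w] * _GLUCOSE_SCALE,
        insulin_window=v[w:2 * w] * _INSULIN_SCALE,
        carb_window=v[2 * w:3 * w] * _CARB_SCALE,
        exercise_window=v[3 * w:4 * w] * _EXERCISE_SCALE,
        time_since_last_meal=float(v[4 * w] * _ELAPSED_SCALE),
        time_since_last_dose=float(v[4 * w + 1] * _ELAPSED_SCALE),
        hour_of_day=int(round(v[4 * w + 2] * _HOUR_SCALE)),
        iob=float(v[4 * w + 3] * _IOB_SCALE),
    )


# ---------------------------------------------------------------------------
# Simulator
# ---------------------------------------------------------------------------

_SAFETY_FLOOR_STEPS = 6  # consecutive floor-pinned steps before termination


class GlucoseSim:
    """Closed-loop glucose simulator with discrete insulin dose actions."""

    def __init__(
        self,
        config: EnvConfig | None = None,
        seed: int = 0,
        schedule: MealExerciseSchedule | None = None,
        reward_cfg: RewardConfig | None = None,
        start_time: datetime = datetime(2021, 7, 1, 0, 0),
    ) -> None:
        self.config = config or EnvConfig()
        self.reward_cfg = reward_cfg or RewardConfig()
        self.schedule = schedule or MealExerciseSchedule.empty()
        self.start_time = start_time
        self._seed = int(seed)
        self.state: EnvState | None = None

    @property
    def n_actions(self) -> int:
        return len(self.config.action_doses)

    def reset(self, seed: int | None = None) -> np.ndarray:
        """Start a new episode; returns the encoded observation."""
        if seed is not None:
            self._seed = int(seed)
        self.rng = np.random.default_rng(self._seed)
        cfg = self.config
        warm = cfg.basal_glucose + self.rng.normal(0.0, cfg.noise_sd, WINDOW_BINS)
        warm = np.clip(warm, cfg.glucose_lo, cfg.glucose_hi)
        self.t = 0
        self.glucose = float(warm[-1])
        self._doses: list[tuple[int, float]] = []   # (step delivered, U)
        self._floor_run = 0
        self.state = EnvState(
            glucose_window=warm,
            insulin_window=np.zeros(WINDOW_BINS),
            carb_window=np.zeros(WINDOW_BINS),
            exercise_window=np.zeros(WINDOW_BINS),
            time_since_last_meal=ELAPSED_CAP_MIN,
            time_since_last_dose=ELAPSED_CAP_MIN,
            hour_of_day=self.start_time.hour,
            iob=0.0,
        )
        return encode_state(self.state)

    # -- per-bin physiological inputs ------------------------------------

    def _activity_units(self, t: int) -> float:
        """Insulin activity (U) expended during transition t -> t+1."""
        cfg = self.config
        total = 0.0
        keep = []
        for s, dose in self._doses:
            age_end = (t - s) * STEP_MIN  # dose acts from the bin after delivery
            if age_end - STEP_MIN >= cfg.dia_min:
                continue
            keep.append((s, dose))
            if age_end > 0:
                total += dose * _bin_fraction(
                    lambda m: _triangle_cum(m, 0.4 * cfg.dia_min, float(cfg.dia_min)), age_end)
        self._doses = keep
        return total

    def _carbs_grams(self, t: int) -> float:
        """Grams absorbed during transition t -> t+1."""
        total = 0.0
        for m_min, grams in zip(self.schedule.meal_minutes, self.schedule.meal_carbs):
            s = int(m_min // STEP_MIN)
            age_end = (t - s) * STEP_MIN
            if 0 < age_end <= 60.0 + STEP_MIN:
                total += grams * _bin_fraction(lambda m: _triangle_cum(m, 20.0, 60.0), age_end)
        return total

    def _meal_in_bin(self, t: int) -> float:
        grams = 0.0
        for m_min, g in zip(self.schedule.meal_minutes, self.schedule.meal_carbs):
            if int(m_min // STEP_MIN) == t:
                grams += g
        return grams

    def _exercise_intensity(self, t: int) -> float:
        minute = t * STEP_MIN
        for start, dur, inten in zip(self.schedule.exercise_start_min,
                                     self.schedule.exercise_duration_min,
                                     self.schedule.exercise_intensity):
            if start <= minute < start + dur:
                return float(inten)
        return 0.0

    def _iob(self, t: int) -> float:
        """Linear-decay IOB from action doses at the start of step t."""
        cfg = self.config
        total = 0.0
        for s, dose in self._doses:
            age = (t - s) * STEP_MIN
            if age < cfg.dia_min:
                total += dose * (1.0 - age / cfg.dia_min)
        return total

    # -- transition -------------------------------------------------------

    def step(self, action_index: int) -> tuple[np.ndarray, float, bool, dict]:
        if self.state is None:
            raise RuntimeError("call reset() before step()")
        cfg = self.config
        if not 0 <= action_index < self.n_actions:
            raise ValueError(f"action index {action_index} outside [0, {self.n_actions})")
        dose = cfg.action_doses[action_index]
        if dose > 0:
            self._doses.append((self.t, dose))

        prev_g = self.glucose
        activity = self._activity_units(self.t)
        absorbed = self._carbs_grams(self.t)
        intensity = self._exercise_intensity(self.t)
        noise = self.rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd > 0 else 0.0

        g = (prev_g
             - cfg.reversion_rate * cfg.step_min * (prev_g - cfg.basal_glucose)
             + cfg.carb_gain * absorbed
             - cfg.insulin_sensitivity * activity
             - cfg.exercise_effect * intensity * cfg.step_min
             + noise)
        g = float(np.clip(g, cfg.glucose_lo, cfg.glucose_hi))

        self.t += 1
        self.glucose = g
        iob = self._iob(self.t)
        reward = total_reward(prev_g, g, iob, self.reward_cfg)

        meal_grams = self._meal_in_bin(self.t - 1)
        st = self.state
        new_state = EnvState(
            glucose_window=np.append(st.glucose_window[1:], g),
            insulin_window=np.append(st.insulin_window[1:], dose),
            carb_window=np.append(st.carb_window[1:], meal_grams),
            exercise_window=np.append(st.exercise_window[1:], intensity),
            time_since_last_meal=0.0 if meal_grams > 0 else min(
                st.time_since_last_meal + STEP_MIN, ELAPSED_CAP_MIN),
            time_since_last_dose=0.0 if dose > 0 else min(
                st.time_since_last_dose + STEP_MIN, ELAPSED_CAP_MIN),
            hour_of_day=(self.start_time + timedelta(minutes=self.t * STEP_MIN)).hour,
            iob=iob,
        )
        self.state = new_state

        self._floor_run = self._floor_run + 1 if g <= cfg.glucose_lo else 0
        safety_stop = self._floor_run >= _SAFETY_FLOOR_STEPS
        done = self.t >= cfg.episode_len or safety_stop
        info = {
            "glucose": g,
            "iob": iob,
            "absorbed_carbs": absorbed,
            "activity": activity,
            "safety_stop": safety_stop,
        }
        return encode_state(new_state), reward, done, info
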