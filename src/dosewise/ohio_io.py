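"""OhioT1DM-schema event-stream I/O and CGM preprocessing.

The OhioT1DM datasets log one XML file per patient: interstitial glucose
every 5 minutes plus user-entered bolus/basal insulin, meals with carb
estimates, exercise bouts, and band physiology (heart rate, GSR, skin
temperature, steps). This module parses that layout into an
:class:`EventStream`, fuses every channel onto a uniform 5-minute grid,
imputes short CGM gaps (<= 15 min) while excluding longer ones, clips and
flags sensor outliers (<40 or >400 mg/dL, non-physiologic rate spikes),
resolves insulin events into a continuous insulin-on-board (IOB) trace
under linear decay, and performs the leakage-safe time-blocked
train/validation/test split (weeks 1-6 / 7 / 8).

Timestamps follow the dataset's ``dd-mm-YYYY HH:MM:SS`` convention and are
treated as timezone-naive local clock time. Grid bins are half-open
``[t, t+5min)``: an event on an exact boundary belongs to the bin starting
there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree

logger = logging.getLogger(__name__)

TS_FORMAT = "%d-%m-%Y %H:%M:%S"
STEP_MIN = 5
BINS_PER_WEEK = 7 * 24 * 60 // STEP_MIN  # 2016

EVENT_KINDS = (
    "glucose", "bolus", "basal", "meal", "exercise",
    "heart_rate", "gsr", "skin_temp", "steps", "sleep",
)

# XML element name -> (kind, value attribute)
_ELEMENT_MAP = {
    "glucose_level": ("glucose", "value"),
    "bolus": ("bolus", "dose"),
    "basal": ("basal", "value"),
    "meal": ("meal", "carbs"),
    "exercise": ("exercise", "intensity"),
    "basis_heart_rate": ("heart_rate", "value"),
    "basis_gsr": ("gsr", "value"),
    "basis_skin_temperature": ("skin_temp", "value"),
    "basis_steps": ("steps", "value"),
    "basis_sleep": ("sleep", "quality"),
}

_KIND_TO_ELEMENT = {kind: (el, attr) for el, (kind, attr) in _ELEMENT_MAP.items()}


@dataclass(frozen=True)
class RawEvent:
    """One timestamped record from a patient log."""

    kind: str
    timestamp: datetime
    value: float
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if not np.isfinite(self.value):
            raise ValueError(f"non-finite value for {self.kind} at {self.timestamp}")
        if self.kind in ("bolus", "basal") and self.value < 0:
            raise ValueError(f"negative insulin dose at {self.timestamp}")
        if self.kind == "exercise" and not 1 <= self.value <= 5:
            raise ValueError(f"exercise intensity {self.value} outside [1, 5]")


@dataclass
class EventStream:
    """Time-sorted per-patient event log."""

    patient_id: str
    cohort: str  # "2018" or "2020"
    events: list[RawEvent]

    def __post_init__(self) -> None:
        # kind as secondary key makes the order canonical for ties, so a
        # write/parse round trip reproduces the list exactly
        self.events = sorted(self.events, key=lambda e: (e.timestamp, e.kind))

    def of_kind(self, kind: str) -> list[RawEvent]:
        return [e for e in self.events if e.kind == kind]


TIMELINE_COLUMNS = [
    "glucose", "bolus_units", "bolus_duration_min", "basal_rate", "carbs",
    "exercise_intensity", "exercise_duration", "heart_rate", "gsr",
    "skin_temp", "steps", "iob", "flag_imputed", "flag_clipped",
    "flag_gap_excluded",
]


@dataclass
class PatientTimeline:
    """Uniform 5-minute-grid view of one patient.

    ``df`` is indexed by bin-start timestamps with the channel columns in
    :data:`TIMELINE_COLUMNS`; flag columns are boolean markers written by
    the preprocessing steps.
    """

    patient_id: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.df.index
        if len(idx) > 1:
            deltas = np.diff(idx.values).astype("timedelta64[s]").astype(int)
            if not np.all(deltas == STEP_MIN * 60):
                raise ValueError("timeline grid spacing must be exactly 5 minutes")

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "PatientTimeline":
        return PatientTimeline(self.patient_id, self.df.copy())


# ---------------------------------------------------------------------------
# XML parsing
# ---------------------------------------------------------------------------

def _parse_ts(element, attr: str) -> datetime:
    raw = element.get(attr)
    if raw is None:
        raise ValueError(
            f"missing {attr!r} attribute on <{element.getparent().tag}> event: "
            f"{etree.tostring(element, encoding='unicode').strip()}"
        )
    return datetime.strptime(raw, TS_FORMAT)


def parse_ohio_xml(source: str | Path) -> EventStream:
    """Parse an OhioT1DM-layout XML document into an :class:`EventStream`.

    ``source`` is a path to an XML file or an XML string. Unrecognized
    elements are skipped with a warning; malformed XML raises
    ``lxml.etree.XMLSyntaxError`` (which names the offending line).
    """
    text = None
    if isinstance(source, Path) or (isinstance(source, str) and not source.lstrip().startswith("<")):
        text = Path(source).read_bytes()
    else:
        text = source.encode() if isinstance(source, str) else source
    root = etree.fromstring(text)
    patient_id = root.get("id", "unknown")
    cohort = root.get("cohort", "2018")

    events: list[RawEvent] = []
    for section in root:
        if section.tag is etree.Comment:
            continue
        if section.tag not in _ELEMENT_MAP:
            logger.warning("skipping unrecognized element <%s>", section.tag)
            continue
        kind, value_attr = _ELEMENT_MAP[section.tag]
        for ev in section:
            ts_attr = "ts_begin" if ev.get("ts_begin") is not None else "ts"
            ts = _parse_ts(ev, ts_attr)
            raw_value = ev.get(value_attr)
            if raw_value is None:
                raise ValueError(f"missing {value_attr!r} on <{section.tag}> event at {ts}")
            extra: dict = {}
            if kind == "bolus":
                extra["bolus_type"] = ev.get("type", "normal")
                if ev.get("ts_end") is not None:
                    end = _parse_ts(ev, "ts_end")
                    extra["duration_min"] = (end - ts).total_seconds() / 60.0
            elif kind == "meal" and ev.get("type") is not None:
                extra["meal_type"] = ev.get("type")
            elif kind == "exercise" and ev.get("duration") is not None:
                extra["duration_min"] = float(ev.get("duration"))
            events.append(RawEvent(kind=kind, timestamp=ts, value=float(raw_value), extra=extra))
    return EventStream(patient_id=patient_id, cohort=cohort, events=events)


def write_timeline(timeline: PatientTimeline, path: str | Path) -> None:
    """Export a timeline as a CSV table with ISO-8601 bin timestamps."""
    out = timeline.df.copy()
    out.index.name = "timestamp"
    out.to_csv(path, date_format="%Y-%m-%dT%H:%M:%S")


def read_timeline(path: str | Path, patient_id: str = "unknown") -> PatientTimeline:
    df = pd.read_csv(path, index_col="timestamp", parse_dates=["timestamp"])
    return PatientTimeline(patient_id, df)


# ---------------------------------------------------------------------------
# Grid alignment
# ---------------------------------------------------------------------------

def _bin_of(ts: datetime, origin: pd.Timestamp) -> int:
    return int((pd.Timestamp(ts) - origin).total_seconds() // (STEP_MIN * 60))


def align_5min(stream: EventStream, agg: str = "mean") -> PatientTimeline:
    """Fuse all channels of a stream onto the uniform 5-minute grid.

    Sub-5-minute continuous channels (heart rate, GSR, skin temperature,
    glucose if oversampled) are aggregated within each bin with ``agg``
    (mean or median). Discrete events are assigned to their containing
    half-open bin: boluses and meal carbs sum, steps sum, exercise
    intensity is spread over the bout's duration. Basal rate is a held
    (forward-filled) rate from each basal event onward.
    """
    if agg not in ("mean", "median"):
        raise ValueError("agg must be 'mean' or 'median'")
    if not stream.events:
        raise ValueError(f"cannot align an empty event stream for patient {stream.patient_id}")

    t0 = pd.Timestamp(stream.events[0].timestamp).floor(f"{STEP_MIN}min")
    t1 = pd.Timestamp(stream.events[-1].timestamp).floor(f"{STEP_MIN}min")
    index = pd.date_range(t0, t1, freq=f"{STEP_MIN}min")
    n = len(index)

    df = pd.DataFrame(index=index, columns=TIMELINE_COLUMNS, dtype=float)
    df[["bolus_units", "bolus_duration_min", "carbs", "exercise_intensity",
        "exercise_duration", "steps"]] = 0.0
    for flag in ("flag_imputed", "flag_clipped", "flag_gap_excluded"):
        df[flag] = False
    df["iob"] = 0.0

    agg_fn = np.mean if agg == "mean" else np.median
    continuous: dict[str, dict[int, list[float]]] = {
        "glucose": {}, "heart_rate": {}, "gsr": {}, "skin_temp": {},
    }
    for e in stream.events:
        b = _bin_of(e.timestamp, t0)
        if not 0 <= b < n:
            continue
        if e.kind in continuous:
            continuous[e.kind].setdefault(b, []).append(e.value)
        elif e.kind == "bolus":
            df.iloc[b, df.columns.get_loc("bolus_units")] += e.value
            dur = float(e.extra.get("duration_min", 0.0))
            if e.extra.get("bolus_type", "normal") != "normal" and dur > 0:
                df.iloc[b, df.columns.get_loc("bolus_duration_min")] = max(
                    dur, df.iloc[b, df.columns.get_loc("bolus_duration_min")])
        elif e.kind == "meal":
            df.iloc[b, df.columns.get_loc("carbs")] += e.value
        elif e.kind == "steps":
            df.iloc[b, df.columns.get_loc("steps")] += e.value
        elif e.kind == "basal":
            df.iloc[b, df.columns.get_loc("basal_rate")] = e.value
        elif e.kind == "exercise":
            dur = float(e.extra.get("duration_min", STEP_MIN))
            nbins = max(1, int(np.ceil(dur / STEP_MIN)))
            df.iloc[b:b + nbins, df.columns.get_loc("exercise_intensity")] = e.value
            df.iloc[b, df.columns.get_loc("exercise_duration")] = dur
        # sleep events carried only in the stream; no grid channel by default
    for col, bins in continuous.items():
        loc = df.columns.get_loc(col)
        for b, values in bins.items():
            df.iloc[b, loc] = agg_fn(values)
    df["basal_rate"] = df["basal_rate"].ffill().fillna(0.0)
    return PatientTimeline(stream.patient_id, df)


# ---------------------------------------------------------------------------
# Imputation, clipping, IOB
# ---------------------------------------------------------------------------

def impute_gaps(timeline: PatientTimeline, max_gap_min: int = 15) -> PatientTimeline:
    """Fill CGM gaps up to ``max_gap_min``; flag longer gaps as excluded.

    Interior gaps are forward-filled (no future information); a leading gap
    with no prior reading is backward-filled. Rows filled either way are
    flagged ``imputed``; rows in longer gaps are flagged ``gap_excluded``
    and their glucose stays missing.
    """
    if max_gap_min <= 0 or max_gap_min % STEP_MIN != 0:
        raise ValueError("max_gap_min must be a positive multiple of 5")
    max_bins = max_gap_min // STEP_MIN

    out = timeline.copy()
    g = out.df["glucose"].to_numpy(copy=True)
    imputed = out.df["flag_imputed"].to_numpy(copy=True)
    excluded = out.df["flag_gap_excluded"].to_numpy(copy=True)

    isna = np.isnan(g)
    i, n = 0, len(g)
    while i < n:
        if not isna[i]:
            i += 1
            continue
        j = i
        while j < n and isna[j]:
            j += 1
        gap_len = j - i
        if gap_len <= max_bins:
            if i > 0:  # interior: forward fill from the last reading
                g[i:j] = g[i - 1]
                imputed[i:j] = True
            elif j < n:  # leading: backward fill from the first reading
                g[i:j] = g[j]
                imputed[i:j] = True
            else:  # entire series missing
                excluded[i:j] = True
        else:
            excluded[i:j] = True
        i = j
    out.df["glucose"] = g
    out.df["flag_imputed"] = imputed
    out.df["flag_gap_excluded"] = excluded
    return out


MAX_STEP_DELTA = 50.0  # mg/dL per 5-min bin; ~3x the physiological maximum


def clip_outliers(timeline: PatientTimeline, lo: float = 40.0, hi: float = 400.0) -> PatientTimeline:
    """Clip out-of-band CGM readings and flag non-physiologic rate spikes.

    Readings below ``lo`` / above ``hi`` are clipped to the bound and
    flagged. A within-band jump of more than 50 mg/dL between consecutive
    bins is treated as a sensor spike: the value is replaced by the
    previous reading and flagged.
    """
    if not lo < hi:
        raise ValueError("lo must be < hi")
    out = timeline.copy()
    g = out.df["glucose"].to_numpy(copy=True)
    clipped = out.df["flag_clipped"].to_numpy(copy=True)

    bound = (~np.isnan(g)) & ((g < lo) | (g > hi))
    g = np.clip(g, lo, hi)
    clipped |= bound

    # Spike pass: `prev` tracks the last trusted reading. Bound-clipped and
    # spike-replaced rows are anomalies and never become the reference.
    prev = np.nan
    for i in range(len(g)):
        if np.isnan(g[i]) or bound[i]:
            continue
        if not np.isnan(prev) and abs(g[i] - prev) > MAX_STEP_DELTA:
            g[i] = prev
            clipped[i] = True
            continue
        prev = g[i]
    out.df["glucose"] = g
    out.df["flag_clipped"] = clipped
    return out


def resolve_iob(timeline: PatientTimeline, dia_min: int = 240) -> PatientTimeline:
    """Resolve insulin events to a continuous insulin-on-board trace.

    Each delivered unit decays linearly to zero over the duration of
    insulin action (DIA, default 240 min). Normal boluses deliver in their
    bin; square/dual boluses deliver uniformly over their stated duration;
    basal delivers ``rate x 5/60`` units per bin. IOB at a bin is the
    superposition of the remaining fractions of every prior delivery.
    """
    if dia_min <= 0:
        raise ValueError("dia_min must be positive")
    out = timeline.copy()
    df = out.df
    if (df["bolus_units"] < 0).any() or (df["basal_rate"] < 0).any():
        raise ValueError("negative insulin dose in timeline")

    n = len(df)
    delivered = df["basal_rate"].to_numpy() * (STEP_MIN / 60.0)
    delivered = delivered.copy()
    bolus = df["bolus_units"].to_numpy()
    dur = df["bolus_duration_min"].to_numpy()
    for i in np.nonzero(bolus > 0)[0]:
        if dur[i] > 0:
            nbins = max(1, int(np.ceil(dur[i] / STEP_MIN)))
            hi = min(n, i + nbins)
            delivered[i:hi] += bolus[i] / nbins
        else:
            delivered[i] += bolus[i]

    # iob[t] = sum_s delivered[s] * max(0, 1 - (t-s)*5/dia): a truncated
    # linear-decay kernel applied by direct convolution.
    kernel_len = int(np.ceil(dia_min / STEP_MIN))
    ages = np.arange(kernel_len) * STEP_MIN
    kernel = np.maximum(0.0, 1.0 - ages / dia_min)
    iob = np.convolve(delivered, kernel)[:n]
    df["iob"] = iob
    return out


def preprocess(stream: EventStream, max_gap_min: int = 15, dia_min: int = 240,
               agg: str = "mean") -> PatientTimeline:
    """align -> impute -> clip -> IOB, the standard preprocessing chain."""
    tl = align_5min(stream, agg=agg)
    tl = impute_gaps(tl, max_gap_min=max_gap_min)
    tl = clip_outliers(tl)
    return resolve_iob(tl, dia_min=dia_min)


# ---------------------------------------------------------------------------
# Time-blocked split
# ---------------------------------------------------------------------------

def time_blocked_split(timeline: PatientTimeline) -> tuple[PatientTimeline, PatientTimeline, PatientTimeline]:
    """Split a timeline into contiguous train/validation/test segments.

    Timelines spanning at least 8 weeks are split on calendar boundaries:
    weeks 1-6 for training, week 7 for validation, the remainder for test.
    Shorter timelines are split proportionally 6:1:1 (a warning is logged).
    """
    n = len(timeline)
    if n < 3:
        raise ValueError(f"timeline of {n} bins is too short to split")
    if n >= 8 * BINS_PER_WEEK:
        i_train = 6 * BINS_PER_WEEK
        i_val = 7 * BINS_PER_WEEK
    else:
        logger.warning("timeline spans %d bins (< 8 weeks); splitting proportionally 6:1:1", n)
        i_train = (n * 6) // 8
        i_val = (n * 7) // 8
    df = timeline.df
    parts = (df.iloc[:i_train], df.iloc[i_train:i_val], df.iloc[i_val:])
    return tuple(PatientTimeline(timeline.patient_id, p.copy()) for p in parts)  # type: ignore[return-value]
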