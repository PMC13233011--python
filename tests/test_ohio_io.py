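"""Preprocessing chain: XML parsing, alignment, imputation, clipping, IOB, split."""

from datetime import datetime, timedelta

import numpy as np
import pandas as pd
import pytest
from lxml import etree

import dosewise as dw
from dosewise.ohio_io import BINS_PER_WEEK, STEP_MIN

from conftest import make_glucose_stream

T0 = datetime(2021, 7, 1, 9, 0)


class TestParse:
    def test_two_glucose_events_in_order(self):
        xml = """<patient id="p1" cohort="2018">
          <glucose_level>
            <event ts="01-07-2021 09:00:00" value="100"/>
            <event ts="01-07-2021 09:05:00" value="105"/>
          </glucose_level>
        </patient>"""
        stream = dw.parse_ohio_xml(xml)
        assert [e.value for e in stream.events] == [100.0, 105.0]
        assert stream.events[0].kind == "glucose"
        assert stream.events[0].timestamp == T0

    def test_out_of_order_events_sorted(self):
        xml = """<patient id="p1">
          <glucose_level>
            <event ts="01-07-2021 09:10:00" value="110"/>
            <event ts="01-07-2021 09:00:00" value="100"/>
          </glucose_level>
        </patient>"""
        stream = dw.parse_ohio_xml(xml)
        ts = [e.timestamp for e in stream.events]
        assert ts == sorted(ts)

    def test_malformed_xml_raises_with_line(self):
        with pytest.raises(etree.XMLSyntaxError):
            dw.parse_ohio_xml("<patient><glucose_level></patient>")

    def test_missing_timestamp_names_element(self):
        xml = '<patient id="p"><glucose_level><event value="100"/></glucose_level></patient>'
        with pytest.raises(ValueError, match="ts"):
            dw.parse_ohio_xml(xml)

    def test_unknown_section_skipped(self, caplog):
        xml = """<patient id="p">
          <mystery><event ts="01-07-2021 09:00:00" value="1"/></mystery>
          <glucose_level><event ts="01-07-2021 09:00:00" value="100"/></glucose_level>
        </patient>"""
        stream = dw.parse_ohio_xml(xml)
        assert len(stream.events) == 1


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_xml_round_trip_identity(tmp_path, seed):
    """write_ohio_xml then parse_ohio_xml reproduces the stream field for field."""
    stream = dw.generate_patient(weeks=1, seed=seed)
    path = tmp_path / "p.xml"
    dw.write_ohio_xml(stream, path)
    back = dw.parse_ohio_xml(path)
    assert back.patient_id == stream.patient_id
    assert back.cohort == stream.cohort
    assert len(back.events) == len(stream.events)
    for a, b in zip(stream.events, back.events):
        assert (a.kind, a.timestamp, a.value, a.extra) == (b.kind, b.timestamp, b.value, b.extra)


class TestAlign:
    def test_subminute_channel_aggregated(self):
        extra = [dw.RawEvent("gsr", T0 + timedelta(minutes=i), float(v))
                 for i, v in enumerate([1, 2, 3, 4, 5])]
        stream = make_glucose_stream([100, 101], extra_events=extra)
        tl = dw.align_5min(stream, agg="mean")
        assert tl.df["gsr"].iloc[0] == pytest.approx(3.0)
        tl_med = dw.align_5min(stream, agg="median")
        assert tl_med.df["gsr"].iloc[0] == pytest.approx(3.0)

    def test_boluses_in_same_bin_sum(self):
        extra = [dw.RawEvent("bolus", T0 + timedelta(minutes=1), 1.0,
                             {"bolus_type": "normal", "duration_min": 0.0}),
                 dw.RawEvent("bolus", T0 + timedelta(minutes=3), 0.5,
                             {"bolus_type": "normal", "duration_min": 0.0})]
        stream = make_glucose_stream([100, 101], extra_events=extra)
        tl = dw.align_5min(stream)
        assert tl.df["bolus_units"].iloc[0] == pytest.approx(1.5)

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            dw.align_5min(dw.EventStream("p", "2018", []))

    def test_against_brute_force_binning(self):
        """Randomized stream vs an independent dictionary-binning oracle."""
        rng = np.random.default_rng(4)
        events = []
        for _ in range(200):
            offset = float(rng.uniform(0, 600))
            events.append(dw.RawEvent("heart_rate", T0 + timedelta(minutes=offset),
                                      float(rng.uniform(50, 120))))
        events.append(dw.RawEvent("glucose", T0, 100.0))
        stream = dw.EventStream("p", "2018", events)
        tl = dw.align_5min(stream, agg="mean")

        bins: dict[int, list[float]] = {}
        for e in stream.events:
            if e.kind != "heart_rate":
                continue
            b = int((e.timestamp - T0).total_seconds() // (STEP_MIN * 60))
            bins.setdefault(b, []).append(e.value)
        for b, values in bins.items():
            assert tl.df["heart_rate"].iloc[b] == pytest.approx(np.mean(values))


class TestImpute:
    def test_short_gap_forward_filled_and_flagged(self):
        tl = dw.align_5min(make_glucose_stream([100, None, None, 110]))
        out = dw.impute_gaps(tl)
        assert list(out.df["glucose"]) == [100, 100, 100, 110]
        assert list(out.df["flag_imputed"]) == [False, True, True, False]

    def test_long_gap_excluded(self):
        tl = dw.align_5min(make_glucose_stream([100, None, None, None, None, None, 110]))
        out = dw.impute_gaps(tl)
        assert out.df["glucose"].isna().sum() == 5
        assert out.df["flag_gap_excluded"].sum() == 5

    def test_leading_gap_backward_filled(self):
        tl = dw.align_5min(make_glucose_stream([None, None, 90, 95]))
        # leading Nones produce no events; craft explicitly
        stream = make_glucose_stream([90, None, 95])
        tl = dw.align_5min(stream)
        out = dw.impute_gaps(tl)
        assert not out.df["glucose"].isna().any()

    def test_gapless_identity(self):
        tl = dw.align_5min(make_glucose_stream([100, 105, 110]))
        out = dw.impute_gaps(tl)
        pd.testing.assert_frame_equal(out.df, tl.df)

    def test_bad_max_gap_rejected(self, patient_timeline):
        with pytest.raises(ValueError):
            dw.impute_gaps(patient_timeline, max_gap_min=7)


class TestClip:
    @pytest.mark.parametrize("raw,expect,flagged", [
        (450.0, 400.0, True),
        (39.0, 40.0, True),
        (150.0, 150.0, False),
    ])
    def test_bound_rules(self, raw, expect, flagged):
        tl = dw.align_5min(make_glucose_stream([150.0, raw]))
        out = dw.clip_outliers(tl)
        assert out.df["glucose"].iloc[1] == expect
        assert bool(out.df["flag_clipped"].iloc[1]) is flagged

    def test_rate_spike_replaced_by_previous(self):
        tl = dw.align_5min(make_glucose_stream([120, 200, 122]))
        out = dw.clip_outliers(tl)
        assert out.df["glucose"].iloc[1] == 120
        assert bool(out.df["flag_clipped"].iloc[1])
        assert out.df["glucose"].iloc[2] == 122

    def test_band_invariant_after_impute_and_clip(self):
        stream = dw.generate_patient(weeks=1, seed=5)
        tl = dw.clip_outliers(dw.impute_gaps(dw.align_5min(stream)))
        g = tl.df["glucose"].dropna()
        assert ((g >= 40) & (g <= 400)).all()


class TestIOB:
    def test_linear_decay_half_way(self):
        extra = [dw.RawEvent("bolus", T0, 2.0, {"bolus_type": "normal", "duration_min": 0.0})]
        tl = dw.align_5min(make_glucose_stream([100] * 30, extra_events=extra))
        out = dw.resolve_iob(tl, dia_min=240)
        assert out.df["iob"].iloc[24] == pytest.approx(1.0)  # t + 120 min

    def test_no_insulin_zero_iob(self):
        tl = dw.align_5min(make_glucose_stream([100, 105, 110]))
        out = dw.resolve_iob(tl)
        assert (out.df["iob"] == 0).all()

    def test_superposition_against_per_minute_oracle(self):
        """Random bolus/basal schedules vs direct per-event superposition."""
        rng = np.random.default_rng(11)
        for trial in range(100):
            n = 60
            values = [100.0] * n
            extra = []
            n_bolus = int(rng.integers(1, 6))
            bolus_bins = rng.integers(0, n - 1, n_bolus)
            doses = rng.uniform(0.5, 6.0, n_bolus).round(2)
            durations = np.where(rng.random(n_bolus) < 0.3,
                                 rng.integers(2, 8, n_bolus) * STEP_MIN, 0.0)
            for b, d, dur in zip(bolus_bins, doses, durations):
                extra.append(dw.RawEvent(
                    "bolus", T0 + timedelta(minutes=int(b) * STEP_MIN), float(d),
                    {"bolus_type": "square" if dur > 0 else "normal",
                     "duration_min": float(dur)}))
            tl = dw.align_5min(make_glucose_stream(values, extra_events=extra))
            dia = 240
            out = dw.resolve_iob(tl, dia_min=dia)

            # oracle: expand every delivery to (minute, units), superpose decay
            deliveries: list[tuple[float, float]] = []
            df = tl.df
            for i in range(n):
                u, dur = df["bolus_units"].iloc[i], df["bolus_duration_min"].iloc[i]
                if u <= 0:
                    continue
                if dur > 0:
                    nb = max(1, int(np.ceil(dur / STEP_MIN)))
                    for j in range(nb):
                        if i + j < n:
                            deliveries.append(((i + j) * STEP_MIN, u / nb))
                else:
                    deliveries.append((i * STEP_MIN, u))
            for i in range(n):
                t = i * STEP_MIN
                expect = sum(u * max(0.0, 1.0 - (t - m) / dia)
                             for m, u in deliveries if m <= t)
                assert abs(out.df["iob"].iloc[i] - expect) < 1e-9


class TestSplit:
    def test_eight_week_counts(self):
        stream = dw.generate_patient(weeks=8, seed=2)
        tl = dw.preprocess(stream)
        train, val, test = dw.time_blocked_split(tl)
        assert (len(train), len(val), len(test)) == (6 * BINS_PER_WEEK, BINS_PER_WEEK, BINS_PER_WEEK)

    def test_proportional_split_counts(self):
        stream = dw.generate_patient(weeks=4, seed=2)
        tl = dw.preprocess(stream)
        assert len(tl) == 8064
        train, val, test = dw.time_blocked_split(tl)
        assert (len(train), len(val), len(test)) == (6048, 1008, 1008)

    def test_partition_and_ordering(self, patient_timeline):
        train, val, test = dw.time_blocked_split(patient_timeline)
        rebuilt = pd.concat([train.df, val.df, test.df])
        pd.testing.assert_frame_equal(rebuilt, patient_timeline.df)
        assert train.df.index.max() < val.df.index.min() < val.df.index.max() < test.df.index.min()

    def test_too_short_rejected(self):
        tl = dw.align_5min(make_glucose_stream([100]))
        with pytest.raises(ValueError, match="short"):
            dw.time_blocked_split(tl)
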