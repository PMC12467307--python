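import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aucurve.curves import (
    AUEvent,
    CurveTrack,
    ModulationConfig,
    bspline_eval,
    event_to_control_points,
    event_to_track,
    events_from_prediction,
    export_tracks,
    import_tracks,
    map_to_rig,
    modulate_curve,
)
from aucurve.inventory import load_rig_map

from oracles import deboor_eval


class TestBsplineEval:
    def test_partition_of_unity_constant_curve(self):
        for t in np.linspace(0, 1, 17):
            assert bspline_eval([3.3] * 6, t) == pytest.approx(3.3, abs=1e-12)

    def test_clamped_endpoints(self):
        b = [1.0, 2.0, -1.0, 4.0, 7.0]
        assert bspline_eval(b, 0.0) == pytest.approx(1.0, abs=1e-12)
        assert bspline_eval(b, 1.0) == pytest.approx(7.0, abs=1e-12)

    def test_matches_deboor_oracle(self):
        rng = np.random.default_rng(0)
        ts = np.linspace(0, 1, 100)
        for _ in range(10):
            b = rng.normal(size=6)
            for t in ts:
                assert bspline_eval(b, float(t)) == pytest.approx(
                    deboor_eval(b, float(t)), abs=1e-10)

    def test_short_control_lists_padded(self):
        assert bspline_eval([2.0], 0.5) == pytest.approx(2.0, abs=1e-12)
        assert bspline_eval([0.0, 1.0], 0.0) == pytest.approx(0.0, abs=1e-12)
        assert bspline_eval([0.0, 1.0], 1.0) == pytest.approx(1.0, abs=1e-12)

    def test_empty_control_list_rejected(self):
        with pytest.raises(ValueError):
            bspline_eval([], 0.5)

    def test_out_of_range_time_rejected(self):
        with pytest.raises(ValueError):
            bspline_eval([1.0, 2.0, 3.0, 4.0], 1.5)

    @given(st.lists(st.floats(-5, 5), min_size=4, max_size=9),
           st.floats(0, 1))
    @settings(max_examples=60, deadline=None)
    def test_convex_hull_property(self, control, t):
        val = bspline_eval(control, t)
        assert min(control) - 1e-9 <= val <= max(control) + 1e-9

    def test_c2_continuity_of_dense_samples(self):
        """First and second finite differences of a densely sampled spline
        stay bounded by the discretisation order (no jumps at knots)."""
        b = np.array([0.0, 0.0, 1.0, 0.0, 0.0])
        h = 1e-3
        ts = np.arange(0, 1 + h / 2, h)
        vals = np.array([bspline_eval(b, float(t)) for t in ts])
        d1 = np.diff(vals) / h
        d2 = np.diff(d1) / h
        assert np.abs(np.diff(d1)).max() < 50 * h   # derivative continuous
        assert np.abs(np.diff(d2)).max() < 50 * h   # curvature continuous


class TestEventToControlPoints:
    def test_zero_value_gives_zero_curve(self):
        ev = AUEvent("AU12", 0.0, 0.0, 0.5, 1.0)
        track = event_to_track(ev)
        assert np.abs(track.values()).max() == 0.0

    def test_curve_zero_at_onset_and_offset(self):
        ev = AUEvent("AU12", 0.9, 0.1, 0.3, 0.8)
        track = event_to_track(ev)
        assert track.keys[0] == (pytest.approx(0.1), pytest.approx(0.0, abs=1e-12))
        assert track.keys[-1] == (pytest.approx(0.8), pytest.approx(0.0, abs=1e-12))

    def test_peak_bounded_by_value_and_near_apex(self):
        ev = AUEvent("AU6", 0.7, 0.2, 0.45, 1.2)
        anchors, values = event_to_control_points(ev)
        np.testing.assert_array_equal(values, [0, 0, 0.7, 0, 0])
        ts = np.linspace(ev.onset_s, ev.offset_s, 2001)
        u = np.interp(ts, anchors, [0.0, 0.5, 1.0])
        curve = bspline_eval(values, u)
        assert curve.max() <= ev.value + 1e-12
        t_peak = ts[np.argmax(curve)]
        span = ev.offset_s - ev.onset_s
        assert abs(t_peak - ev.apex_s) <= 0.05 * span

    def test_invalid_event_rejected(self):
        with pytest.raises(ValueError):
            AUEvent("AU1", 0.5, 0.5, 0.5, 1.0)
        with pytest.raises(ValueError):
            AUEvent("AU1", 1.5, 0.0, 0.5, 1.0)


class TestModulateCurve:
    def _track(self, scale=1.0):
        ev = AUEvent("AU12", 1.0, 0.0, 0.5, 1.0)
        tr = event_to_track(ev)
        return CurveTrack(tr.channel, [(t, v * scale) for t, v in tr.keys])

    def test_identity_modulation(self):
        tr = self._track()
        out = modulate_curve(tr, "happiness", ModulationConfig({"happiness": 1.0}, iv=1.0))
        assert out.keys == tr.keys

    def test_substitution_example(self):
        tr = CurveTrack("c", [(0.0, 2.0)])
        out = modulate_curve(tr, "joy", ModulationConfig({"joy": 0.8}, iv=0.5))
        assert out.keys[0][1] == pytest.approx(0.8)

    def test_linearity(self):
        cfg = ModulationConfig({"fear": 0.7}, iv=0.9)
        a = modulate_curve(self._track(3.0), "fear", cfg)
        b = modulate_curve(self._track(1.0), "fear", cfg)
        np.testing.assert_allclose(a.values(), 3.0 * b.values(), atol=1e-12)

    def test_times_unchanged(self):
        tr = self._track()
        out = modulate_curve(tr, "fear", ModulationConfig({"fear": 0.5}, iv=0.3))
        np.testing.assert_array_equal(out.times(), tr.times())

    def test_unknown_emotion_rejected(self):
        with pytest.raises(KeyError):
            modulate_curve(self._track(), "boredom", ModulationConfig({"joy": 1.0}))


class TestMapToRig:
    def test_au12_maps_to_two_corner_pull_channels(self):
        rig = load_rig_map()
        tracks = map_to_rig({"AU12": event_to_track(AUEvent("AU12", 1.0, 0, 0.5, 1))}, rig)
        assert [t.channel for t in tracks] == \
            ["CTRL_L_mouth_cornerPull", "CTRL_R_mouth_cornerPull"]

    def test_au4_maps_to_four_channels(self):
        rig = load_rig_map()
        tracks = map_to_rig({"AU4": event_to_track(AUEvent("AU4", 1.0, 0, 0.5, 1))}, rig)
        assert len(tracks) == 4

    def test_unmapped_au_rejected_by_name(self):
        rig = load_rig_map()
        with pytest.raises(KeyError, match="AU99"):
            map_to_rig({"AU99": event_to_track(AUEvent("AU99", 1.0, 0, 0.5, 1))}, rig)


class TestExport:
    def test_empty_track_list_writes_header_only(self, tmp_path):
        path = tmp_path / "keys.csv"
        export_tracks([], 60.0, path)
        assert path.read_text().strip() == "channel,time_s,frame,value,interp,tangent"

    def test_round_trip_csv_and_json(self, tmp_path):
        ev = AUEvent("AU12", 0.8, 0.0, 0.25, 0.5)
        tracks = [event_to_track(ev, channel="CTRL_test")]
        for fmt in ("csv", "json"):
            path = tmp_path / f"keys.{fmt}"
            export_tracks(tracks, 60.0, path, format=fmt)
            back = import_tracks(path, format=fmt)
            assert back[0].channel == "CTRL_test"
            np.testing.assert_allclose(back[0].times(), tracks[0].times(), atol=0)
            np.testing.assert_allclose(back[0].values(), tracks[0].values(), atol=0)

    def test_frame_index_is_rounded_time_times_fps(self, tmp_path):
        tr = CurveTrack("c", [(0.5, 1.0)])
        path = tmp_path / "keys.csv"
        export_tracks([tr], 60.0, path)
        row = path.read_text().splitlines()[1].split(",")
        assert int(row[2]) == 30

    def test_byte_stable_output(self, tmp_path):
        ev = AUEvent("AU6", 0.4, 0.0, 0.3, 0.9)
        tracks = [event_to_track(ev)]
        export_tracks(tracks, 24.0, tmp_path / "a.csv")
        export_tracks(tracks, 24.0, tmp_path / "b.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_invalid_fps_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            export_tracks([], 0.0, tmp_path / "x.csv")


class TestEventsFromPrediction:
    def test_threshold_filters_aus(self):
        events = events_from_prediction(
            {"AU12": 0.9, "AU6": 0.2}, 0.2, 0.8, n_frames=41, fps=200.0)
        assert [e.au_id for e in events] == ["AU12"]

    def test_span_matches_timestamps(self):
        events = events_from_prediction({"AU12": 1.0}, 0.25, 0.75, n_frames=41, fps=200.0)
        ev = events[0]
        assert ev.onset_s == pytest.approx(0.25 * 40 / 200)
        assert ev.offset_s == pytest.approx(0.75 * 40 / 200)
        assert ev.onset_s < ev.apex_s < ev.offset_s
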