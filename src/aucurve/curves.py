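"""Animation-curve synthesis: AU events -> clamped B-spline tracks -> rig keys.

Each detected AU event (an intensity peak between an onset and an offset
time) becomes a smooth scalar curve: a clamped uniform cubic B-spline over
control values ``(0, 0, v, 0, 0)`` so the curve is exactly zero at both ends
of the event span, stays inside the convex hull of its control values
(never exceeding the peak intensity ``v``), and attains its maximum at the
apex. Time inside the span is warped piecewise-linearly so the spline's
symmetric peak lands on the requested apex second.

Curves are modulated per emotion, ``c'(t) = c(t) * m_e * i_v``, with ``m_e``
an emotion-specific gain (high for joy, low for fear) and ``i_v`` in [0, 1]
an intensity-variation factor, then duplicated onto the rig control
channels mapped to the AU (bilateral left/right channels) and exported as
engine-agnostic keyframe files with cubic interpolation / auto tangent
metadata.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import BSpline

from .inventory import RigMap

__all__ = [
    "AUEvent",
    "CurveTrack",
    "ModulationConfig",
    "bspline_eval",
    "event_to_control_points",
    "event_to_track",
    "modulate_curve",
    "map_to_rig",
    "export_tracks",
    "import_tracks",
    "events_from_prediction",
]


@dataclass(frozen=True)
class AUEvent:
    au_id: str
    value: float          # peak intensity in [0, 1]
    onset_s: float
    apex_s: float
    offset_s: float

    def __post_init__(self):
        if not (0.0 <= self.value <= 1.0):
            raise ValueError(f"event value outside [0,1]: {self.value}")
        if not (self.onset_s < self.apex_s < self.offset_s):
            raise ValueError(
                f"need onset < apex < offset, got ({self.onset_s}, {self.apex_s}, {self.offset_s})")


@dataclass
class CurveTrack:
    channel: str
    keys: list[tuple[float, float]]
    interp: str = "cubic"
    tangent: str = "auto"

    def __post_init__(self):
        times = [t for t, _ in self.keys]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"key times must be strictly increasing on {self.channel}")

    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.keys])

    def values(self) -> np.ndarray:
        return np.array([v for _, v in self.keys])


@dataclass
class ModulationConfig:
    me_by_emotion: dict[str, float] = field(default_factory=dict)
    iv: float = 1.0

    def __post_init__(self):
        for emo, me in self.me_by_emotion.items():
            if me <= 0:
                raise ValueError(f"modulator for {emo} must be > 0, got {me}")
        if not (0.0 <= self.iv <= 1.0):
            raise ValueError(f"iv must lie in [0,1], got {self.iv}")


def _clamped_knots(m: int, degree: int = 3) -> np.ndarray:
    """Clamped uniform knot vector for m control points on [0, 1]."""
    interior = np.linspace(0.0, 1.0, m - degree + 1)
    return np.concatenate([np.zeros(degree), interior, np.ones(degree)])


def bspline_eval(control_points, t) -> np.ndarray | float:
    """Evaluate the clamped uniform cubic B-spline through ``control_points``
    at normalized time(s) ``t`` in [0, 1].

    Fewer than four control points are endpoint-duplicated up to four. The
    basis forms a partition of unity, so the curve lies in the convex hull
    of the control values and interpolates the first and last ones.
    """
    b = np.asarray(control_points, dtype=np.float64)
    if b.ndim != 1 or b.size == 0:
        raise ValueError("control_points must be a non-empty 1-D sequence")
    while b.size < 4:
        b = np.concatenate([[b[0]], b, [b[-1]]])
    spline = BSpline(_clamped_knots(b.size), b, 3, extrapolate=True)
    t_arr = np.asarray(t, dtype=np.float64)
    if (t_arr < 0).any() or (t_arr > 1).any():
        raise ValueError("t must lie in [0,1]")
    out = spline(t_arr)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def event_to_control_points(event: AUEvent) -> tuple[np.ndarray, np.ndarray]:
    """Control scaffolding for an onset-apex-offset event.

    Returns ``(anchor_times, control_values)``: the control values are
    ``(0, 0, v, 0, 0)`` and the anchor times ``(onset_s, apex_s, offset_s)``
    define the piecewise-linear warp from spline parameter ``u`` in [0, 1]
    (peak at u = 0.5) onto seconds.
    """
    values = np.array([0.0, 0.0, event.value, 0.0, 0.0])
    anchors = np.array([event.onset_s, event.apex_s, event.offset_s])
    return anchors, values


def _time_to_u(times: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    onset, apex, offset = anchors
    return np.interp(times, [onset, apex, offset], [0.0, 0.5, 1.0])


def event_to_track(event: AUEvent, channel: str | None = None, n_keys: int = 33) -> CurveTrack:
    """Sample an event's spline into a keyframed track on [onset_s, offset_s]."""
    anchors, values = event_to_control_points(event)
    times = np.unique(np.concatenate([
        np.linspace(event.onset_s, event.offset_s, n_keys), [event.apex_s]]))
    curve = bspline_eval(values, _time_to_u(times, anchors))
    keys = [(float(t), float(v)) for t, v in zip(times, curve)]
    return CurveTrack(channel=channel or event.au_id, keys=keys)


def modulate_curve(track: CurveTrack, emotion: str, config: ModulationConfig) -> CurveTrack:
    """Scale every key value by the emotion modulator times the intensity
    variation; key times are untouched."""
    if emotion not in config.me_by_emotion:
        raise KeyError(f"emotion {emotion!r} missing from modulation config")
    gain = config.me_by_emotion[emotion] * config.iv
    return CurveTrack(channel=track.channel,
                      keys=[(t, v * gain) for t, v in track.keys],
                      interp=track.interp, tangent=track.tangent)


def map_to_rig(au_curves: dict[str, CurveTrack], rig: RigMap) -> list[CurveTrack]:
    """Duplicate each AU's curve onto all of its rig channels (bilateral
    left/right symmetry), preserving the channel order of the map."""
    tracks = []
    for au_id, track in au_curves.items():
        if au_id not in rig:
            raise KeyError(f"AU id {au_id!r} has no rig mapping")
        for channel in rig.channels(au_id):
            tracks.append(CurveTrack(channel=channel, keys=list(track.keys),
                                     interp=track.interp, tangent=track.tangent))
    return tracks


_CSV_COLS = ["channel", "time_s", "frame", "value", "interp", "tangent"]


def export_tracks(tracks: list[CurveTrack], fps: float, path, format: str = "csv") -> None:
    """Write keyframe tracks to a CSV or JSON file (byte-stable)."""
    if fps <= 0:
        raise ValueError(f"fps must be > 0, got {fps}")
    path = Path(path)
    if format == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, lineterminator="\n")
            w.writerow(_CSV_COLS)
            for tr in tracks:
                for t, v in tr.keys:
                    w.writerow([tr.channel, repr(float(t)), int(round(t * fps)),
                                repr(float(v)), tr.interp, tr.tangent])
    elif format == "json":
        payload = {"fps": fps, "tracks": [
            {"channel": tr.channel, "interp": tr.interp, "tangent": tr.tangent,
             "keys": [{"time_s": t, "frame": int(round(t * fps)), "value": v}
                      for t, v in tr.keys]}
            for tr in tracks]}
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise ValueError(f"unknown export format {format!r}")


def import_tracks(path, format: str = "csv") -> list[CurveTrack]:
    """Reload tracks written by :func:`export_tracks`."""
    path = Path(path)
    if format == "csv":
        grouped: dict[str, CurveTrack] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                tr = grouped.setdefault(row["channel"], CurveTrack(
                    channel=row["channel"], keys=[], interp=row["interp"],
                    tangent=row["tangent"]))
                tr.keys.append((float(row["time_s"]), float(row["value"])))
        return list(grouped.values())
    if format == "json":
        payload = json.loads(path.read_text())
        return [CurveTrack(channel=tr["channel"],
                           keys=[(k["time_s"], k["value"]) for k in tr["keys"]],
                           interp=tr["interp"], tangent=tr["tangent"])
                for tr in payload["tracks"]]
    raise ValueError(f"unknown import format {format!r}")


def events_from_prediction(au_values: dict[str, float], y_start: float, y_end: float,
                           n_frames: int, fps: float = 200.0,
                           threshold: float = 0.5,
                           apex_fraction: float = 0.5) -> list[AUEvent]:
    """Turn per-AU intensities plus normalized timestamps into AU events.

    AUs below ``threshold`` are dropped; the apex defaults to the midpoint
    of the predicted span (``apex_fraction = 0.5``), configurable because
    the timestamp head predicts only onset and offset.
    """
    duration = (n_frames - 1) / fps
    onset_s = y_start * duration
    offset_s = y_end * duration
    if offset_s <= onset_s:
        offset_s = onset_s + 1.0 / fps
    apex_s = onset_s + apex_fraction * (offset_s - onset_s)
    return [AUEvent(au_id=au, value=min(float(v), 1.0), onset_s=onset_s,
                    apex_s=apex_s, offset_s=offset_s)
            for au, v in sorted(au_values.items()) if v >= threshold]
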