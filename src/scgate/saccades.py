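"""Saccade detection and guided-trial scoring from 1 kHz eye-position traces.

Detection follows the classic velocity/acceleration-threshold scheme used for
primate eye tracking: candidate intervals where smoothed eye speed exceeds
30 deg/s are kept if they contain an acceleration-magnitude sample above
8000 deg/s^2 and span at least 12 consecutive above-threshold samples.
Samples recorded during lost tracking, or while gaze is outside the display
(50 x 36 deg), are removed before detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: display half-extents in degrees (50 x 36 deg usable field)
DISPLAY_HALF_X = 25.0
DISPLAY_HALF_Y = 18.0

VELOCITY_THRESHOLD = 30.0     # deg/s
ACCEL_THRESHOLD = 8000.0      # deg/s^2
MIN_DURATION_MS = 12          # >= 12 consecutive above-threshold samples
MERGE_GAP_MS = 10             # candidate intervals closer than this are merged


@dataclass
class EyePositionTrace:
    """Uniformly sampled 2D gaze trajectory with a validity mask.

    ``t`` is in ms on a strict 1 ms grid; ``x``/``y`` in degrees; ``valid``
    marks samples with usable tracking.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.t.shape, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.t.shape == self.x.shape == self.y.shape == self.valid.shape):
            raise ValueError("t, x, y, valid must have identical shapes")
        if self.t.size > 1:
            dt = np.diff(self.t)
            if not np.allclose(dt, 1.0):
                raise ValueError("trace must be sampled on a uniform 1 ms grid")

    def __len__(self) -> int:
        return int(self.t.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_ms": self.t, "x_deg": self.x, "y_deg": self.y,
             "valid": self.valid.astype(int)}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EyePositionTrace":
        df = pd.read_csv(path)
        return cls(df["t_ms"].to_numpy(), df["x_deg"].to_numpy(),
                   df["y_deg"].to_numpy(), df["valid"].to_numpy().astype(bool))


@dataclass
class SaccadeEvent:
    """One detected saccade.

    ``offset_ms`` is half-open: the first millisecond after the last
    above-threshold sample, so ``duration_ms`` equals the number of
    above-threshold samples.
    """

    onset_ms: float
    offset_ms: float
    start_xy: tuple
    end_xy: tuple
    amplitude: float
    direction: float       # deg in [0, 360)
    peak_velocity: float   # deg/s
    duration_ms: float


@dataclass
class ResponseField:
    """Response-field vector: preferred saccade direction and eccentricity."""

    direction: float       # deg
    eccentricity: float    # deg, > 0
    center_xy: tuple | None = None

    def __post_init__(self) -> None:
        if self.eccentricity <= 0:
            raise ValueError("eccentricity must be > 0")
        if self.center_xy is None:
            th = math.radians(self.direction)
            self.center_xy = (self.eccentricity * math.cos(th),
                              self.eccentricity * math.sin(th))


def _boxcar(a: np.ndarray, width: int) -> np.ndarray:
    """Boxcar smoothing; NaNs propagate (a NaN contaminates its window)."""
    if width <= 1:
        return a.copy()
    kernel = np.ones(width) / width
    pad = width // 2
    padded = np.pad(a, (pad, width - 1 - pad), mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def compute_kinematics(trace: EyePositionTrace, smooth_samples: int = 5,
                       fs_hz: float = 1000.0):
    """Eye speed (deg/s) and its derivative (deg/s^2) on the trace's grid.

    Positions are smoothed with a ``smooth_samples`` boxcar, differentiated
    with a central difference, and the speed differentiated again for
    acceleration. Invalid samples become NaN and propagate through the
    smoothing window, so gaps never generate spurious velocity spikes.
    """
    n = len(trace)
    speed = np.full(n, np.nan)
    accel = np.full(n, np.nan)
    if n < 3 or trace.valid.sum() < 3:
        return speed, accel

    x = np.where(trace.valid, trace.x, np.nan)
    y = np.where(trace.valid, trace.y, np.nan)
    xs = _boxcar(x, smooth_samples)
    ys = _boxcar(y, smooth_samples)

    dt = 1.0 / fs_hz
    vx = np.full(n, np.nan)
    vy = np.full(n, np.nan)
    vx[1:-1] = (xs[2:] - xs[:-2]) / (2 * dt)
    vy[1:-1] = (ys[2:] - ys[:-2]) / (2 * dt)
    speed = np.hypot(vx, vy)
    accel[1:-1] = (speed[2:] - speed[:-2]) / (2 * dt)
    return speed, accel


def _runs(mask: np.ndarray):
    """Start/stop index pairs (half-open) of True runs in a boolean mask."""
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def detect_saccades(trace: EyePositionTrace,
                    velocity_threshold: float = VELOCITY_THRESHOLD,
                    accel_threshold: float = ACCEL_THRESHOLD,
                    min_duration_ms: float = MIN_DURATION_MS,
                    merge_gap_ms: float = MERGE_GAP_MS,
                    display_half=(DISPLAY_HALF_X, DISPLAY_HALF_Y),
                    smooth_samples: int = 5) -> list[SaccadeEvent]:
    """Detect saccades by velocity/acceleration thresholding.

    Returns time-ordered, non-overlapping :class:`SaccadeEvent`s; empty list
    when nothing qualifies.
    """
    if len(trace) == 0:
        return []
    usable = trace.valid & (np.abs(trace.x) <= display_half[0]) \
        & (np.abs(trace.y) <= display_half[1])
    clean = EyePositionTrace(trace.t, trace.x, trace.y, usable)
    speed, accel = compute_kinematics(clean, smooth_samples=smooth_samples)

    above = np.where(np.isnan(speed), False, speed > velocity_threshold)
    runs = _runs(above)
    if not runs:
        return []

    # merge candidate intervals separated by < merge_gap_ms (one saccade can
    # dip below threshold for a sample or two near its velocity trough)
    merged = [list(runs[0])]
    for start, stop in runs[1:]:
        if start - merged[-1][1] < merge_gap_ms:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])

    events: list[SaccadeEvent] = []
    prev_stop = 0
    for start, stop in merged:
        n_samples = stop - start
        if n_samples < min_duration_ms:
            continue
        seg_accel = accel[start:stop]
        if not np.any(np.abs(seg_accel[~np.isnan(seg_accel)]) > accel_threshold):
            continue
        # refine onset/offset back/forward to the local speed minimum: the
        # threshold crossing lags true movement onset by a few ms
        floor = velocity_threshold / 3.0
        while start > prev_stop and not np.isnan(speed[start - 1]) \
                and floor < speed[start - 1] < speed[start]:
            start -= 1
        n_total = len(speed)
        while stop < n_total and not np.isnan(speed[stop]) \
                and floor < speed[stop] < speed[stop - 1]:
            stop += 1
        prev_stop = stop
        last = stop - 1
        sx, sy = trace.x[start], trace.y[start]
        ex, ey = trace.x[last], trace.y[last]
        amp = math.hypot(ex - sx, ey - sy)
        direction = math.degrees(math.atan2(ey - sy, ex - sx)) % 360.0
        events.append(SaccadeEvent(
            onset_ms=float(trace.t[start]),
            offset_ms=float(trace.t[last] + 1.0),
            start_xy=(float(sx), float(sy)),
            end_xy=(float(ex), float(ey)),
            amplitude=float(amp),
            direction=float(direction),
            peak_velocity=float(np.nanmax(speed[start:stop])),
            duration_ms=float(stop - start),
        ))
    return events


def circular_difference(a_deg: float, b_deg: float):
    """Absolute circular difference between two angles in degrees, in [0, 180]."""
    return np.abs((np.asarray(a_deg) - np.asarray(b_deg) + 180.0) % 360.0 - 180.0)


def classify_in_rf(saccades: list[SaccadeEvent], rf: ResponseField,
                   direction_tol_deg: float = 10.0,
                   amp_lo: float = 0.8, amp_hi: float = 1.5) -> np.ndarray:
    """In-RF flags: direction within ``direction_tol_deg`` (circular, inclusive)
    of the RF direction and amplitude in [amp_lo, amp_hi] x eccentricity."""
    flags = np.zeros(len(saccades), dtype=bool)
    for i, s in enumerate(saccades):
        ok_dir = circular_difference(s.direction, rf.direction) <= direction_tol_deg
        ok_amp = amp_lo * rf.eccentricity <= s.amplitude <= amp_hi * rf.eccentricity
        flags[i] = bool(ok_dir and ok_amp)
    return flags


@dataclass
class ScoredTrial:
    outcome: str                 # "success" | "fail"
    latency_ms: float            # NaN when no qualifying saccade
    saccade: SaccadeEvent | None = None


def score_guided_trial(trace: EyePositionTrace, target_xy,
                       go_cue_ms: float,
                       response_window_ms: float = 1000.0,
                       accept_window_side_deg: float = 3.0,
                       **detect_kwargs) -> ScoredTrial:
    """Score a visually guided saccade trial.

    Success requires a detected saccade initiated within ``response_window_ms``
    after the go cue whose endpoint lands inside the square acceptance window
    (side ``accept_window_side_deg``) centered on the target. The first
    qualifying saccade determines latency.
    """
    if not (trace.t[0] <= go_cue_ms <= trace.t[-1]):
        raise ValueError("go cue must fall inside the trace span")
    half = accept_window_side_deg / 2.0
    tx, ty = target_xy
    for s in detect_saccades(trace, **detect_kwargs):
        if not (go_cue_ms < s.onset_ms <= go_cue_ms + response_window_ms):
            continue
        ex, ey = s.end_xy
        if abs(ex - tx) <= half and abs(ey - ty) <= half:
            return ScoredTrial("success", s.onset_ms - go_cue_ms, s)
    return ScoredTrial("fail", float("nan"), None)


def events_to_frame(events: list[SaccadeEvent],
                    in_rf: np.ndarray | None = None) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "onset_ms": [e.onset_ms for e in events],
            "offset_ms": [e.offset_ms for e in events],
            "amp_deg": [e.amplitude for e in events],
            "dir_deg": [e.direction for e in events],
            "vpeak_dps": [e.peak_velocity for e in events],
        }
    )
    if in_rf is not None:
        df["in_rf"] = np.asarray(in_rf, dtype=bool)
    return df
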