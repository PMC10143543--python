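"""Ankle-IMU pipeline: walking-bout selection, gyroscope gait-event
detection and single-sensor temporal / energy gait features.

Gait events are read off the sagittal (Z) axis of each ankle gyroscope:
the swing of a leg produces one large positive angular-velocity lobe,
flanked by a negative dip at toe off (TO, before the lobe) and a
shallower negative dip at initial contact (IC, after it).  The
mid-swing peak (MS) is found first with a data-adaptive height
threshold

    height >= max(50 dps, 0.3 * max(s_z))

subject to a minimum peak distance of 0.5 s and minimum width of 0.1 s;
TO and IC are then the nearest qualifying dips of the inverted signal
(depth >= 15 dps and >= 5 dps respectively) before and after each MS.

Only features estimable from a single sensor are computed (stance,
swing, cadence, single support via the contralateral swing, energies,
shank motion range); double support and loading response are
deliberately not derived from IMU data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .simulate import ImuRecording


@dataclass
class PeakDetectionParams:
    ms_floor_dps: float = 50.0
    ms_fraction: float = 0.3
    ms_min_distance_s: float = 0.5
    ms_min_width_s: float = 0.1
    to_threshold_dps: float = 15.0
    ic_threshold_dps: float = 5.0
    assign_window_s: float = 0.5   # max TO/IC distance from the MS peak

    def validate(self) -> None:
        vals = (self.ms_floor_dps, self.ms_min_distance_s, self.ms_min_width_s,
                self.to_threshold_dps, self.ic_threshold_dps,
                self.assign_window_s)
        if any(v <= 0 for v in vals):
            raise ValueError("peak-detection parameters must be positive")
        if not 0.0 < self.ms_fraction < 1.0:
            raise ValueError("ms_fraction must lie in (0, 1)")

    def ms_height(self, signal_max: float) -> float:
        """Adaptive mid-swing height threshold."""
        return max(self.ms_floor_dps, self.ms_fraction * signal_max)


@dataclass
class BoutConfig:
    mode: str = "auto"             # auto | manual
    manual_intervals: tuple[tuple[float, float], ...] = ()
    rms_window_s: float = 1.0
    threshold_dps: float = 30.0
    merge_gap_s: float = 1.0
    min_duration_s: float = 3.0


@dataclass(frozen=True)
class Stride:
    t_to: float
    t_ms: float
    t_ic: float

    def validate(self) -> None:
        if not self.t_to < self.t_ms < self.t_ic:
            raise ValueError(f"stride events out of order: {self}")


@dataclass
class ImuFootEvents:
    strides: list[Stride]
    diagnostics: dict = field(default_factory=dict)

    def times(self, which: str) -> np.ndarray:
        return np.asarray([getattr(s, f"t_{which}") for s in self.strides])


@dataclass
class ImuGaitEvents:
    left: ImuFootEvents
    right: ImuFootEvents


# ---------------------------------------------------------------------------
# walking bouts
# ---------------------------------------------------------------------------

def detect_walking_bouts(recording: ImuRecording,
                         config: BoutConfig | None = None
                         ) -> list[tuple[float, float]]:
    """Walking-bout intervals (seconds from session start).

    Manual mode returns the configured intervals verbatim (the source
    protocol annotated bouts from test timing).  Automatic mode
    thresholds the 1 s moving RMS of the gyroscope magnitude, merges
    gaps shorter than ``merge_gap_s`` and drops bouts shorter than
    ``min_duration_s``.
    """
    cfg = config or BoutConfig()
    if cfg.mode == "manual":
        return [tuple(iv) for iv in cfg.manual_intervals]
    t = recording.time_s
    if len(t) < 2:
        return []
    fs = 1.0 / float(np.median(np.diff(t)))
    mag = np.linalg.norm(recording.gyro, axis=1)
    win = max(1, int(round(cfg.rms_window_s * fs)))
    kernel = np.ones(win) / win
    rms = np.sqrt(np.convolve(mag ** 2, kernel, mode="same"))
    active = rms > cfg.threshold_dps
    if not active.any():
        return []
    intervals = []
    i = 0
    n = len(active)
    while i < n:
        if active[i]:
            j = i
            while j + 1 < n and active[j + 1]:
                j += 1
            intervals.append([t[i], t[j]])
            i = j + 1
        else:
            i += 1
    merged = [intervals[0]]
    for a, b in intervals[1:]:
        if a - merged[-1][1] < cfg.merge_gap_s:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged if b - a >= cfg.min_duration_s]


# ---------------------------------------------------------------------------
# event detection
# ---------------------------------------------------------------------------

def detect_imu_gait_events(gyro_z: np.ndarray, time_s: np.ndarray,
                           params: PeakDetectionParams | None = None
                           ) -> ImuFootEvents:
    """Detect (TO, MS, IC) stride triples of one foot from gyro Z.

    Strides missing a qualifying TO or IC dip within the assignment
    window are dropped and counted in diagnostics.
    """
    prm = params or PeakDetectionParams()
    prm.validate()
    if len(time_s) < 2 or not np.any(gyro_z > 0):
        return ImuFootEvents([], {"n_dropped": 0})
    fs = 1.0 / float(np.median(np.diff(time_s)))
    if (time_s[-1] - time_s[0]) < prm.ms_min_distance_s:
        return ImuFootEvents([], {"n_dropped": 0})

    height = prm.ms_height(float(gyro_z.max()))
    ms_idx, _ = find_peaks(gyro_z, height=height,
                           distance=max(1, int(round(prm.ms_min_distance_s * fs))),
                           width=prm.ms_min_width_s * fs)
    to_idx, _ = find_peaks(-gyro_z, height=prm.to_threshold_dps)
    ic_idx, _ = find_peaks(-gyro_z, height=prm.ic_threshold_dps)
    to_times, ic_times = time_s[to_idx], time_s[ic_idx]

    strides, dropped = [], 0
    for i in ms_idx:
        t_ms = time_s[i]
        before = to_times[(to_times < t_ms) & (t_ms - to_times <= prm.assign_window_s)]
        after = ic_times[(ic_times > t_ms) & (ic_times - t_ms <= prm.assign_window_s)]
        if not len(before) or not len(after):
            dropped += 1
            continue
        stride = Stride(t_to=float(before[-1]), t_ms=float(t_ms),
                        t_ic=float(after[0]))
        if strides and stride.t_to < strides[-1].t_ic:
            dropped += 1
            continue
        stride.validate()
        strides.append(stride)
    return ImuFootEvents(strides, {"n_dropped": dropped})


def _events_in_bouts(gyro_z, time_s, bouts, params) -> ImuFootEvents:
    if bouts is None:
        return detect_imu_gait_events(gyro_z, time_s, params)
    strides, dropped = [], 0
    for a, b in bouts:
        m = (time_s >= a) & (time_s <= b)
        ev = detect_imu_gait_events(gyro_z[m], time_s[m], params)
        strides.extend(ev.strides)
        dropped += ev.diagnostics.get("n_dropped", 0)
    return ImuFootEvents(strides, {"n_dropped": dropped})


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

@dataclass
class ImuFeatureVector:
    session: pd.Series
    per_stride: dict[str, pd.DataFrame]
    meta: dict = field(default_factory=dict)


def _asym(left: float, right: float) -> float:
    denom = 0.5 * (abs(left) + abs(right))
    return abs(left - right) / denom if denom > 0 else 0.0


def _foot_cycle_arrays(ev: ImuFootEvents):
    """Cycle, stance and swing durations of one foot.

    cycle_k  = IC_k -> IC_{k+1}
    stance_k = IC_k -> TO_{k+1}
    swing_k  = TO_{k+1} -> IC_{k+1}     (so stance + swing = cycle exactly)
    """
    ic, to = ev.times("ic"), ev.times("to")
    if len(ic) < 2:
        e = np.asarray([])
        return e, e, e
    cycle = np.diff(ic)
    stance = to[1:] - ic[:-1]
    swing = ic[1:] - to[1:]
    return cycle, stance, swing


def _demeaned(a: np.ndarray) -> np.ndarray:
    return a - np.median(a, axis=0, keepdims=True)


def _energy(x: np.ndarray, dt: float) -> float:
    return float(np.sum(x ** 2) * dt)


def compute_imu_features(events: ImuGaitEvents,
                         left_rec: ImuRecording, right_rec: ImuRecording,
                         bouts: list[tuple[float, float]] | None = None,
                         leg_length_factor: float = 1.0 / 90.0
                         ) -> ImuFeatureVector:
    """Temporal and energy/asymmetry gait features from both ankles.

    Cycle-based features need >= 2 strides per foot; with fewer, only
    the step count is reported.  ``normalized_stride_length`` is a
    declared surrogate: the swing angular excursion of the shank (deg)
    scaled by a configurable leg-length factor; the walking-speed proxy
    multiplies it by cadence.
    """
    per_foot: dict[str, dict[str, float]] = {}
    per_stride: dict[str, pd.DataFrame] = {}
    for side, ev, rec in (("left", events.left, left_rec),
                          ("right", events.right, right_rec)):
        t = rec.time_s
        dt = float(np.median(np.diff(t))) if len(t) > 1 else 0.0
        if bouts is None:
            mask = np.ones(len(t), bool)
        else:
            mask = np.zeros(len(t), bool)
            for a, b in bouts:
                mask |= (t >= a) & (t <= b)
        gz = rec.gyro[:, 2]
        acc = _demeaned(rec.accel)
        f: dict[str, float] = {}
        cycle, stance, swing = _foot_cycle_arrays(ev)
        per_stride[side] = pd.DataFrame(
            {"t_to": ev.times("to"), "t_ms": ev.times("ms"),
             "t_ic": ev.times("ic")})
        if len(cycle):
            f["cycle_duration_mean"] = float(cycle.mean())
            f["cycle_duration_std"] = float(cycle.std(ddof=1)) if len(cycle) > 1 else np.nan
            f["stance_mean"] = float(stance.mean())
            f["stance_std"] = float(stance.std(ddof=1)) if len(stance) > 1 else np.nan
            f["stance_pct_mean"] = float((stance / cycle).mean())
            f["swing_mean"] = float(swing.mean())
            f["swing_std"] = float(swing.std(ddof=1)) if len(swing) > 1 else np.nan
            f["cadence"] = 1.0 / f["cycle_duration_mean"]
        f["n_steps"] = float(len(ev.strides))
        f["total_gyro_energy"] = _energy(gz[mask], dt)
        f["cumulative_accel_energy"] = _energy(np.linalg.norm(acc[mask], axis=1), dt)
        stride_acc_energy, ranges = [], []
        for s in ev.strides:
            m = (t >= s.t_to) & (t <= s.t_ic)
            if m.sum() < 2:
                continue
            stride_acc_energy.append(_energy(np.linalg.norm(acc[m], axis=1), dt))
            angle = np.cumsum(gz[m]) * dt   # deg, rectangular integration
            ranges.append(float(angle.max() - angle.min()))
        f["accel_max_energy"] = max(stride_acc_energy) if stride_acc_energy else np.nan
        f["range_of_shank_motion"] = float(np.mean(ranges)) if ranges else np.nan
        f["max_rotation"] = float(np.max(ranges)) if ranges else np.nan
        if ranges and "cadence" in f:
            f["normalized_stride_length"] = f["range_of_shank_motion"] * leg_length_factor
            f["norm_walking_speed"] = f["normalized_stride_length"] * f["cadence"]
        per_foot[side] = f

    out: dict[str, float] = {}
    for side, f in per_foot.items():
        for k, v in f.items():
            out[f"{k}_{side}"] = v
    # single support of one foot = contralateral swing
    for side, other in (("right", "left"), ("left", "right")):
        sw = per_foot[other].get("swing_mean")
        if sw is not None:
            out[f"single_support_{side}_mean"] = sw
            out[f"single_support_{side}_std"] = per_foot[other].get("swing_std", np.nan)
    # leg averages
    for key in ("cycle_duration_mean", "cycle_duration_std", "stance_mean",
                "stance_pct_mean", "swing_mean", "cadence",
                "total_gyro_energy", "cumulative_accel_energy",
                "accel_max_energy", "range_of_shank_motion",
                "normalized_stride_length", "norm_walking_speed"):
        vals = [per_foot[s][key] for s in ("left", "right") if key in per_foot[s]]
        if vals:
            out[key] = float(np.mean(vals))
    # walking cadence follows the insole convention 1/(t02' - t01): the
    # anchor is a right initial contact and the closing event the first
    # left toe-off after the next right initial contact — both visible
    # to the ankle gyroscopes.  Falls back to the leg-averaged cycle
    # rate when one foot's events are missing.
    r_ic = events.right.times("ic")
    l_to = events.left.times("to")
    rates = []
    for k in range(len(r_ic) - 1):
        nxt = l_to[l_to >= r_ic[k + 1] - 1e-9]
        if len(nxt):
            rates.append(1.0 / (nxt[0] - r_ic[k]))
    out["walking_cadence"] = (float(np.mean(rates)) if rates
                              else out.get("cadence", np.nan))
    out["number_of_steps"] = per_foot["left"]["n_steps"] + per_foot["right"]["n_steps"]
    # asymmetry indices
    for key, name in (("cadence", "asym_cadence"),
                      ("stance_mean", "asym_contact_time"),
                      ("norm_walking_speed", "asym_walking_speed"),
                      ("accel_max_energy", "asym_accel_max_energy"),
                      ("total_gyro_energy", "asym_gyro_energy")):
        l, r = per_foot["left"].get(key), per_foot["right"].get(key)
        if l is not None and r is not None and np.isfinite([l, r]).all():
            out[name] = _asym(l, r)
    return ImuFeatureVector(session=pd.Series(out), per_stride=per_stride,
                            meta={"leg_length_factor": leg_length_factor,
                                  "normalized_stride_length": "surrogate: swing "
                                  "shank excursion (deg) x leg_length_factor"})


def extract_imu_features(left_rec: ImuRecording, right_rec: ImuRecording,
                         params: PeakDetectionParams | None = None,
                         bout_config: BoutConfig | None = None,
                         leg_length_factor: float = 1.0 / 90.0
                         ) -> tuple[ImuGaitEvents, ImuFeatureVector]:
    """Full IMU chain: bouts -> per-foot event detection -> features.

    Bouts are detected on each device independently (auto mode by
    default); events and energies are restricted to them.
    """
    cfg = bout_config or BoutConfig()
    bouts_l = detect_walking_bouts(left_rec, cfg) or None
    bouts_r = detect_walking_bouts(right_rec, cfg) or None
    ev = ImuGaitEvents(
        left=_events_in_bouts(left_rec.gyro[:, 2], left_rec.time_s, bouts_l, params),
        right=_events_in_bouts(right_rec.gyro[:, 2], right_rec.time_s, bouts_r, params))
    feats = compute_imu_features(ev, left_rec, right_rec,
                                 bouts=bouts_l, leg_length_factor=leg_length_factor)
    return ev, feats
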