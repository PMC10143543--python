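"""Insole pressure pipeline: preprocessing, gait-event detection and
per-cycle spatiotemporal feature extraction.

Gait events are detected from regional (heel / toe) vertical force with a
four-state per-foot contact machine.  The eight events of a cycle are the
combinations of heel/toe contact per foot:

    heel strike : heel force rises above threshold while toe is unloaded
    toe strike  : toe force rises while heel is loaded (foot flat)
    heel off    : heel force drops while toe is loaded
    toe off     : toe force drops while heel is unloaded (swing begins)

Completed cycles (anchored right heel strike to right heel strike) yield
the time points t01..t08 plus the successor events t01', t02', from which
the spatiotemporal feature set a01..a25 is evaluated:

    a01 right single support   = t05 - t02   (see note below)
    a02 left single support    = t01' - t06
    a03 double support         = a06 + a10
    a04 right side stance      = t06 - t01
    a05 left side stance       = t02' - t05
    a06 right loading response = t02 - t01
    a07 right terminal stance  = t04 - t02
    a08 right pre-swing        = t05 - t04
    a09 right gait cycle       = t01' - t01
    a10 left loading response  = t06 - t05
    a11 left terminal stance   = t07 - t06
    a12 left pre-swing         = t01' - t07
    a13 left gait cycle        = t02' - t02
    a14 walking cadence        = 1 / (t02' - t01)   [cycles/s]
    a15..a25 = the corresponding durations as fractions of a09

Note on a01: printed versions of this feature catalogue circulating in
the literature assign right single support the same formula as left
side stance (t02' - t05).  The default here is the biomechanically
consistent mirror of a02, a01 = t05 - t02 (right single support equals
the left foot's swing); ``printed_formula=True`` reproduces the
catalogued variant instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .simulate import (CycleTruth, EVENT_NAMES, HEEL_CELLS, InsoleRecording,
                       TOE_CELLS, FootChannels)


class NoStepsError(ValueError):
    """Raised when no completed gait cycle is available."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class ForceThresholds:
    """Contact-detection thresholds for regional forces.

    Thresholds default to a fraction of the session's 95th-percentile
    regional force (scale-free, so doubling the signal amplitude leaves
    event times unchanged); absolute-Newton overrides are available.
    De-assertion uses a hysteresis band below the threshold so that
    chatter around the threshold does not produce event bursts.
    """

    heel_fraction: float = 0.05
    toe_fraction: float = 0.05
    heel_newton: float | None = None
    toe_newton: float | None = None
    percentile: float = 95.0
    hysteresis: float = 0.2
    min_event_gap_s: float = 0.05

    def validate(self) -> None:
        if not 0.0 <= self.hysteresis < 0.5:
            raise ValueError("hysteresis must lie in [0, 0.5)")
        if self.min_event_gap_s < 0:
            raise ValueError("min_event_gap_s must be >= 0")
        for v in (self.heel_fraction, self.toe_fraction):
            if v <= 0:
                raise ValueError("threshold fractions must be > 0")

    def resolve(self, heel_force: np.ndarray, toe_force: np.ndarray
                ) -> tuple[float, float]:
        self.validate()
        heel = (self.heel_newton if self.heel_newton is not None else
                self.heel_fraction * np.percentile(heel_force, self.percentile))
        toe = (self.toe_newton if self.toe_newton is not None else
               self.toe_fraction * np.percentile(toe_force, self.percentile))
        return float(heel), float(toe)


@dataclass
class PreprocessConfig:
    lowpass_hz: float = 20.0
    filter_order: int = 4
    baseline_correct: bool = True
    normalization: str = "none"   # none | peak | body_weight
    body_weight_n: float | None = None


@dataclass
class SensorGroups:
    heel: tuple[int, ...] = HEEL_CELLS
    toe: tuple[int, ...] = TOE_CELLS
    cell_area_cm2: float = 10.0

    def validate(self) -> None:
        h, t = set(self.heel), set(self.toe)
        if h & t:
            raise ValueError("heel and toe sensor groups must be disjoint")
        if not all(0 <= i < 16 for i in h | t):
            raise ValueError("sensor indices must lie in 0..15")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess(recording: InsoleRecording,
               config: PreprocessConfig | None = None) -> InsoleRecording:
    """Low-pass filter and baseline-correct the pressure channels.

    Zero-phase Butterworth filtering (no group delay, so event times are
    not shifted); baseline correction subtracts each cell's minimum so
    quiescent segments sit at ~0.  Total force is recomputed from the
    filtered pressures.  Timestamps and non-pressure channels pass
    through unchanged; the choices are recorded in ``meta['preprocess']``.
    """
    cfg = config or PreprocessConfig()
    fs = 1.0 / float(np.median(np.diff(recording.time_s)))
    sos = sps.butter(cfg.filter_order, cfg.lowpass_hz, btype="low",
                     fs=fs, output="sos")

    feet = {}
    for side in ("left", "right"):
        foot: FootChannels = getattr(recording, side)
        p = foot.pressure
        if not p.any():
            warnings.warn(f"all-zero pressure channels on {side} foot; "
                          "recording passed through", stacklevel=2)
            feet[side] = foot
            continue
        p = sps.sosfiltfilt(sos, p, axis=0)
        if cfg.baseline_correct:
            p = p - p.min(axis=0, keepdims=True)
        p = np.clip(p, 0.0, None)
        scale = 1.0
        if cfg.normalization == "peak":
            scale = 1.0 / max(p.max(), 1e-12)
        elif cfg.normalization == "body_weight":
            if not cfg.body_weight_n:
                raise ValueError("body_weight normalization requires body_weight_n")
            scale = 1.0 / cfg.body_weight_n
        p = p * scale
        total = 10.0 * p.sum(axis=1) if cfg.normalization == "none" else p.sum(axis=1)
        feet[side] = FootChannels(pressure=p, accel=foot.accel, gyro=foot.gyro,
                                  cop=foot.cop, total_force=np.clip(total, 0, None))

    meta = dict(recording.meta)
    meta["preprocess"] = {"lowpass_hz": cfg.lowpass_hz,
                          "filter_order": cfg.filter_order,
                          "baseline_correct": cfg.baseline_correct,
                          "normalization": cfg.normalization}
    return InsoleRecording(time_s=recording.time_s, left=feet["left"],
                           right=feet["right"], meta=meta)


def heel_toe_forces(recording: InsoleRecording,
                    groups: SensorGroups | None = None
                    ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Area-weighted heel and toe force series (N) per foot."""
    g = groups or SensorGroups()
    g.validate()
    out = {}
    for side in ("left", "right"):
        p = getattr(recording, side).pressure
        heel = g.cell_area_cm2 * p[:, list(g.heel)].sum(axis=1)
        toe = g.cell_area_cm2 * p[:, list(g.toe)].sum(axis=1)
        out[side] = (heel, toe)
    return out


# ---------------------------------------------------------------------------
# event detection
# ---------------------------------------------------------------------------

@dataclass
class GaitEvent:
    time_s: float
    event: str  # one of EVENT_NAMES


@dataclass
class GaitEventSequence:
    events: list[GaitEvent]
    cycles: list[CycleTruth]
    diagnostics: dict = field(default_factory=dict)

    def times(self, event: str) -> np.ndarray:
        return np.asarray([e.time_s for e in self.events if e.event == event])

    @property
    def n_steps(self) -> int:
        """Heel-strike count over both feet (edge steps included)."""
        return sum(e.event.endswith("heel_strike") for e in self.events)


def _hysteresis_state(x: np.ndarray, thr_on: float, thr_off: float
                      ) -> np.ndarray:
    """Boolean contact state: asserts above thr_on, de-asserts below thr_off."""
    sig = np.where(x > thr_on, 1, np.where(x < thr_off, -1, 0))
    idx = np.arange(len(x))
    last = np.maximum.accumulate(np.where(sig != 0, idx, -1))
    state = np.where(last >= 0, np.where(sig[np.maximum(last, 0)] == 1, 1, 0), 0)
    return state.astype(bool)


def _crossings(t: np.ndarray, x: np.ndarray, state: np.ndarray, level: float,
               rising: bool, min_gap: float) -> np.ndarray:
    """Sub-sample interpolated times of state transitions.

    Transitions come from the hysteretic state machine, but the reported
    time interpolates the crossing of the *nominal* threshold `level`
    (searched in a small neighbourhood of the transition), so hysteresis
    debounces without biasing event times.
    """
    if rising:
        idx = np.where(state[1:] & ~state[:-1])[0] + 1
    else:
        idx = np.where(~state[1:] & state[:-1])[0] + 1
    times = []
    for i in idx:
        ts = t[i]
        for j in range(i, max(i - 5, 0), -1):
            x0, x1 = x[j - 1], x[j]
            crossed = (x0 < level <= x1) if rising else (x0 >= level > x1)
            if crossed and (x1 - x0) != 0:
                frac = (level - x0) / (x1 - x0)
                ts = t[j - 1] + frac * (t[j] - t[j - 1])
                break
        times.append(ts)
    out = []
    for ts in times:
        if not out or ts - out[-1] >= min_gap:
            out.append(ts)
    return np.asarray(out)


def _foot_events(t: np.ndarray, heel: np.ndarray, toe: np.ndarray,
                 heel_thr: float, toe_thr: float, thresholds: ForceThresholds
                 ) -> tuple[list[tuple[float, str]], int]:
    """Classify heel/toe contact transitions of one foot.

    Returns (time, kind) with kind in {heel_strike, toe_strike, heel_off,
    toe_off}, plus the count of transitions that violate the canonical
    stance sequence (e.g. a heel release while the toe is unloaded).
    """
    h = 1.0 - thresholds.hysteresis
    heel_state = _hysteresis_state(heel, heel_thr, h * heel_thr)
    toe_state = _hysteresis_state(toe, toe_thr, h * toe_thr)
    gap = thresholds.min_event_gap_s
    raw = []
    for kind, x, state, level, rising in (
            ("heel_strike", heel, heel_state, heel_thr, True),
            ("heel_off", heel, heel_state, heel_thr, False),
            ("toe_strike", toe, toe_state, toe_thr, True),
            ("toe_off", toe, toe_state, toe_thr, False)):
        for ts in _crossings(t, x, state, level, rising, gap):
            raw.append((ts, kind))
    raw.sort()

    # validate against the other region's state at the transition sample
    def state_at(state, ts):
        i = min(np.searchsorted(t, ts), len(t) - 1)
        return bool(state[i])

    events, abnormal = [], 0
    for ts, kind in raw:
        if kind == "heel_strike" and not state_at(toe_state, ts):
            events.append((ts, kind))
        elif kind == "toe_strike" and state_at(heel_state, ts):
            events.append((ts, kind))
        elif kind == "heel_off" and state_at(toe_state, ts):
            events.append((ts, kind))
        elif kind == "toe_off" and not state_at(heel_state, ts):
            events.append((ts, kind))
        else:
            abnormal += 1
    return events, abnormal


_CYCLE_PATTERN = EVENT_NAMES[1:]  # the seven events between successive RHS


def detect_gait_events(time_s: np.ndarray,
                       forces: dict[str, tuple[np.ndarray, np.ndarray]],
                       thresholds: ForceThresholds | None = None
                       ) -> GaitEventSequence:
    """Detect the eight gait events from per-foot heel/toe force series.

    ``forces`` maps 'left'/'right' to (heel force, toe force) on the
    common time grid.  Partial cycles at the session edges are
    discarded; cycles whose events appear out of order are skipped and
    counted in ``diagnostics``.
    """
    thr = thresholds or ForceThresholds()
    all_events: list[GaitEvent] = []
    abnormal = 0
    for side in ("left", "right"):
        heel, toe = forces[side]
        if heel.max() <= 0 and toe.max() <= 0:
            continue
        heel_thr, toe_thr = thr.resolve(heel, toe)
        if heel.max() <= heel_thr and toe.max() <= toe_thr:
            continue
        evts, bad = _foot_events(time_s, heel, toe, heel_thr, toe_thr, thr)
        abnormal += bad
        for ts, kind in evts:
            all_events.append(GaitEvent(ts, f"{side}_{kind}"))
    all_events.sort(key=lambda e: e.time_s)

    by_type = {name: [e.time_s for e in all_events if e.event == name]
               for name in EVENT_NAMES}
    rhs = by_type["right_heel_strike"]
    cycles, invalid = [], 0
    for t01, t01n in zip(rhs, rhs[1:]):
        inner = []
        ok = True
        for name in _CYCLE_PATTERN:
            inside = [ts for ts in by_type[name] if t01 < ts < t01n]
            if len(inside) != 1:
                ok = False
                break
            inner.append(inside[0])
        if ok:
            seq = [t01] + inner + [t01n]
            ok = all(a < b for a, b in zip(seq, seq[1:]))
        t02n_candidates = [ts for ts in by_type["left_toe_off"] if ts > t01n]
        if ok and t02n_candidates:
            cycles.append(CycleTruth(*seq, t02_next=t02n_candidates[0]))
        else:
            invalid += 1

    return GaitEventSequence(events=all_events, cycles=cycles,
                             diagnostics={"n_invalid_cycles": invalid,
                                          "n_abnormal_transitions": abnormal})


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

_PERCENT_MAP = {"a15": "a01", "a16": "a02", "a17": "a03", "a18": "a04",
                "a19": "a05", "a20": "a06", "a21": "a07", "a22": "a08",
                "a23": "a10", "a24": "a11", "a25": "a12"}

FEATURE_LABELS = {
    "a01": "right single support", "a02": "left single support",
    "a03": "double support", "a04": "right side stance phase",
    "a05": "left side stance phase", "a06": "right loading response",
    "a07": "right terminal stance", "a08": "right pre-swing",
    "a09": "right gait cycle duration", "a10": "left loading response",
    "a11": "left terminal stance", "a12": "left pre-swing",
    "a13": "left gait cycle duration", "a14": "walking cadence",
}


def cycle_features(c: CycleTruth, printed_formula: bool = False) -> dict[str, float]:
    """Evaluate the a01..a25 feature formulas on one cycle's time points."""
    f = {
        "a01": (c.t02_next - c.t05) if printed_formula else (c.t05 - c.t02),
        "a02": c.t01_next - c.t06,
        "a04": c.t06 - c.t01,
        "a05": c.t02_next - c.t05,
        "a06": c.t02 - c.t01,
        "a07": c.t04 - c.t02,
        "a08": c.t05 - c.t04,
        "a09": c.t01_next - c.t01,
        "a10": c.t06 - c.t05,
        "a11": c.t07 - c.t06,
        "a12": c.t01_next - c.t07,
        "a13": c.t02_next - c.t02,
        "a14": 1.0 / (c.t02_next - c.t01),
    }
    f["a03"] = f["a06"] + f["a10"]
    for pct, num in _PERCENT_MAP.items():
        f[pct] = f[num] / f["a09"]
    return {k: f[k] for k in sorted(f)}


@dataclass
class InsoleFeatureVector:
    per_cycle: pd.DataFrame
    session: pd.Series
    number_of_steps: int
    pre_swing_variability: float
    printed_formula: bool = False


def compute_features(seq: GaitEventSequence,
                     printed_formula: bool = False) -> InsoleFeatureVector:
    """Per-cycle a01..a25 features plus session aggregates.

    Session aggregates are the mean and std (ddof=1) of each per-cycle
    feature; ``number_of_steps`` counts every detected heel strike
    (edge steps outside completed cycles included) and
    ``pre_swing_variability`` pools the right and left pre-swing
    durations (a08, a12) into one std.
    """
    if not seq.cycles:
        raise NoStepsError("no steps detected: cannot compute gait features "
                           "without at least one completed cycle")
    per_cycle = pd.DataFrame([cycle_features(c, printed_formula)
                              for c in seq.cycles])
    agg = {}
    for col in per_cycle.columns:
        agg[f"{col}_mean"] = float(per_cycle[col].mean())
        agg[f"{col}_std"] = float(per_cycle[col].std(ddof=1))
    pre_swing = np.concatenate([per_cycle["a08"].to_numpy(),
                                per_cycle["a12"].to_numpy()])
    psv = float(np.std(pre_swing, ddof=1)) if len(pre_swing) > 1 else float("nan")
    agg["pre_swing_variability"] = psv
    agg["number_of_steps"] = float(seq.n_steps)
    agg["n_cycles"] = float(len(seq.cycles))
    return InsoleFeatureVector(per_cycle=per_cycle, session=pd.Series(agg),
                               number_of_steps=seq.n_steps,
                               pre_swing_variability=psv,
                               printed_formula=printed_formula)


def extract_insole_features(recording: InsoleRecording,
                            thresholds: ForceThresholds | None = None,
                            preprocess_config: PreprocessConfig | None = None,
                            groups: SensorGroups | None = None,
                            printed_formula: bool = False
                            ) -> tuple[GaitEventSequence, InsoleFeatureVector]:
    """Full insole chain: preprocess -> regional forces -> events -> features."""
    rec = preprocess(recording, preprocess_config)
    forces = heel_toe_forces(rec, groups)
    seq = detect_gait_events(rec.time_s, forces, thresholds)
    feats = compute_features(seq, printed_formula=printed_formula)
    return seq, feats


def cadence_steps_per_min(cycles_per_s: float) -> float:
    """Convert the cycle-based cadence (1/s) to steps per minute."""
    return 120.0 * cycles_per_s
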