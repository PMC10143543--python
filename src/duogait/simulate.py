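"""Synthetic gait ground truth and sensor renderers.

A single ground-truth timeline of gait events (right/left heel strikes,
toe strikes, heel offs, toe offs) is rendered into two synchronized
sensor modalities:

* a pressure-insole recording (100 Hz, 16 pressure cells + 6-axis IMU +
  center of pressure + total force per foot), and
* a pair of ankle-IMU recordings (59.5 Hz, 3-axis accelerometer,
  gyroscope and magnetometer per ankle).

Because both renderers consume the same timeline, any disagreement
between the downstream insole and IMU pipelines is attributable to the
pipelines themselves, not to the simulated subject.  With noise disabled
every truth event is recoverable from the rendered signals to within one
sample of the respective modality.

The eight events of one gait cycle, anchored at a right heel strike, are
labelled t01..t08 in the order

    t01 right heel strike, t02 left toe off, t03 right toe strike,
    t04 right heel off,    t05 left heel strike, t06 right toe off,
    t07 left toe strike,   t08 left heel off,

followed by t01' (next right heel strike) and t02' (next left toe off).
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SPEED_CLASSES = ("slow", "normal", "fast")
MEDICATION_STATES = ("ON", "OFF")

#: per-cycle event offsets drawn as fractions of the cycle duration
EVENT_OFFSET_NAMES = ("t02", "t03", "t04", "t05", "t06", "t07", "t08")

#: normative gait-phase proportions (fraction of the gait cycle)
DEFAULT_PHASE_FRACTIONS: dict[str, float] = {
    "t02": 0.12,  # left toe off          (ends right loading response)
    "t03": 0.20,  # right toe strike
    "t04": 0.40,  # right heel off
    "t05": 0.50,  # left heel strike      (ends right single support)
    "t06": 0.62,  # right toe off         (ends left loading response)
    "t07": 0.65,  # left toe strike
    "t08": 0.90,  # left heel off
}

#: event name <-> time-point id (canonical order within one cycle)
EVENT_NAMES = (
    "right_heel_strike",
    "left_toe_off",
    "right_toe_strike",
    "right_heel_off",
    "left_heel_strike",
    "right_toe_off",
    "left_toe_strike",
    "left_heel_off",
)

_SPEED_CYCLE_FACTOR = {"slow": 1.2, "normal": 1.0, "fast": 0.85}


# ---------------------------------------------------------------------------
# ground-truth containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CycleTruth:
    """Event times (seconds from session start) of one complete gait cycle."""

    t01: float
    t02: float
    t03: float
    t04: float
    t05: float
    t06: float
    t07: float
    t08: float
    t01_next: float
    t02_next: float

    @property
    def duration(self) -> float:
        return self.t01_next - self.t01

    def as_tuple(self) -> tuple[float, ...]:
        return (self.t01, self.t02, self.t03, self.t04, self.t05,
                self.t06, self.t07, self.t08, self.t01_next, self.t02_next)

    def validate(self) -> None:
        seq = self.as_tuple()
        if not all(np.isfinite(seq)):
            raise ValueError("cycle contains non-finite event times")
        if seq[0] < 0:
            raise ValueError("event times must be non-negative")
        if not all(a < b for a, b in zip(seq, seq[1:])):
            raise ValueError(f"cycle events out of order: {seq}")


@dataclass
class GaitTimeline:
    """Ground-truth event times of one recording session."""

    cycles: tuple[CycleTruth, ...]
    subject_id: str = "S00"
    speed_class: str = "normal"
    impairment_rating: int = 0
    state: str = "ON"

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    @property
    def end_time(self) -> float:
        return self.cycles[-1].t02_next if self.cycles else 0.0

    def validate(self) -> None:
        if self.speed_class not in SPEED_CLASSES:
            raise ValueError(f"unknown speed class {self.speed_class!r}")
        if not 0 <= self.impairment_rating <= 4:
            raise ValueError("impairment rating must be in 0..4")
        for c in self.cycles:
            c.validate()
        for a, b in zip(self.cycles, self.cycles[1:]):
            if not math.isclose(a.t01_next, b.t01, rel_tol=0, abs_tol=1e-9):
                raise ValueError("cycles are not contiguous (t01' of cycle k "
                                 "must equal t01 of cycle k+1)")

    def event_times(self, name: str) -> np.ndarray:
        """All truth times of one event type, successors included."""
        if name not in EVENT_NAMES:
            raise ValueError(f"unknown event {name!r}")
        attr = f"t0{EVENT_NAMES.index(name) + 1}"
        times = [getattr(c, attr) for c in self.cycles]
        if self.cycles:
            if name == "right_heel_strike":
                times.append(self.cycles[-1].t01_next)
            elif name == "left_toe_off":
                times.append(self.cycles[-1].t02_next)
        return np.asarray(times)

    def to_frame(self) -> pd.DataFrame:
        cols = ["t01", "t02", "t03", "t04", "t05", "t06", "t07", "t08",
                "t01_next", "t02_next"]
        return pd.DataFrame([c.as_tuple() for c in self.cycles], columns=cols)


# ---------------------------------------------------------------------------
# simulation specification
# ---------------------------------------------------------------------------

@dataclass
class ImpairmentEffect:
    """How a clinical gait rating (0..4) deforms the generated timeline.

    The rating multiplies the timing jitter of loading-response and
    pre-swing events (std scale = 1 + coefficient * rating), adds
    left/right cadence asymmetry and mildly slows the cycle.  The OFF
    medication state amplifies the whole effect for rated subjects.
    """

    loading_response_std_per_rating: float = 0.75
    pre_swing_std_per_rating: float = 0.5
    cadence_asymmetry_per_rating: float = 0.01
    cycle_slowing_per_rating: float = 0.02
    off_state_factor: float = 1.25


@dataclass
class NoiseSpec:
    """Additive Gaussian sensor noise, one std per channel group."""

    pressure_std: float = 0.05        # N/cm^2
    insole_accel_std: float = 0.02    # g
    insole_gyro_std: float = 1.0      # dps
    cop_std: float = 0.005
    imu_gyro_std: float = 3.0         # dps
    imu_accel_std: float = 0.02       # g
    imu_mag_std: float = 5e-7         # T

    def silent(self) -> "NoiseSpec":
        return NoiseSpec(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class InsoleRenderParams:
    heel_peak_pressure: float = 5.0   # N/cm^2 per heel cell at full load
    toe_peak_pressure: float = 4.0
    mid_peak_pressure: float = 1.0
    ramp_s: float = 0.10              # linear loading/unloading ramp
    threshold_fraction: float = 0.05  # envelope level crossed exactly at event
    cell_area_cm2: float = 10.0
    heel_strike_accel_g: float = 0.8
    amplitude_scale: float = 1.0


@dataclass
class ImuRenderParams:
    ms_amplitude_dps: float = 200.0   # mid-swing gyro-Z lobe
    ms_amplitude_std: float = 10.0
    ms_amplitude_min: float = 120.0
    ms_sigma_s: float = 0.06
    to_depth_dps: float = 60.0        # toe-off dip
    ic_depth_dps: float = 30.0        # initial-contact dip
    dip_sigma_s: float = 0.02
    heel_strike_accel_g: float = 1.5
    accel_sigma_s: float = 0.03
    unix_epoch_s: float = 1_700_000_000.0
    mag_base_t: tuple[float, float, float] = (25e-6, 5e-6, 40e-6)


@dataclass
class SimulationSpec:
    """Study conditions for the synthetic cohort.

    Cohort defaults mirror a typical movement-disorders gait protocol: 19 subjects, two medication
    states (ON/OFF), three instructed speeds, two repetitions per
    condition; gait ratings distributed 0:4, 1:11, 2:2, 3:2 over the 19
    subjects; ~16 strides per walk (10 m out, turn, 10 m back).
    """

    n_subjects: int = 19
    states: tuple[str, ...] = MEDICATION_STATES
    speeds: tuple[str, ...] = SPEED_CLASSES
    repetitions: int = 2
    cycles_per_session: int = 16
    cycles_per_session_std: float = 1.5
    mean_cycle_duration_s: dict[str, float] = field(
        default_factory=lambda: {"slow": 1.3, "normal": 1.1, "fast": 0.9})
    cycle_cv: float = 0.03
    subject_cv: float = 0.05
    phase_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PHASE_FRACTIONS))
    asymmetry: float = 0.02
    base_event_jitter_s: float = 0.004
    impairment: ImpairmentEffect = field(default_factory=ImpairmentEffect)
    rating_counts: tuple[int, ...] = (4, 11, 2, 2, 0)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    insole: InsoleRenderParams = field(default_factory=InsoleRenderParams)
    imu: ImuRenderParams = field(default_factory=ImuRenderParams)
    insole_rate_hz: float = 100.0
    imu_rate_hz: float = 59.5
    lead_in_s: float = 1.0
    lead_out_s: float = 1.0
    max_cycle_retries: int = 100
    seed: int = 0

    def validate(self) -> None:
        fr = self.phase_fractions
        if set(fr) != set(EVENT_OFFSET_NAMES):
            raise ValueError(f"phase_fractions must define {EVENT_OFFSET_NAMES}")
        vals = [fr[n] for n in EVENT_OFFSET_NAMES]
        if not all(0.0 < v < 1.0 for v in vals):
            raise ValueError("phase fractions must lie in (0, 1)")
        if not all(a < b for a, b in zip(vals, vals[1:])):
            raise ValueError("phase fractions must increase in event order")
        if self.cycle_cv < 0:
            raise ValueError("cycle_cv must be >= 0")
        if self.cycles_per_session < 1:
            raise ValueError("cycles_per_session must be >= 1")
        for s in self.speeds:
            if s not in self.mean_cycle_duration_s:
                raise ValueError(f"no mean cycle duration for speed {s!r}")


def _session_rng(spec: SimulationSpec, subject_id: str, state: str,
                 speed_class: str, repetition: int) -> np.random.Generator:
    """Per-session generator streamed from the master seed.

    crc32 of the session key (not Python's randomized hash) keeps
    cohorts reproducible under subsetting and across interpreter runs.
    """
    key = f"{subject_id}|{state}|{speed_class}|{repetition}"
    return np.random.default_rng(
        [int(spec.seed) & 0x7FFFFFFF, zlib.crc32(key.encode())])


# ---------------------------------------------------------------------------
# timeline sampling
# ---------------------------------------------------------------------------

def sample_gait_timeline(spec: SimulationSpec,
                         subject_id: str = "S00",
                         speed_class: str = "normal",
                         impairment_rating: int = 0,
                         state: str = "ON",
                         rng: np.random.Generator | None = None,
                         subject_scale: float = 1.0) -> GaitTimeline:
    """Draw a ground-truth gait timeline for one walking session.

    Cycle durations are drawn around the speed class's mean, event
    offsets at the configured phase fractions of each cycle, perturbed
    by Gaussian jitter whose std is inflated by the impairment rating
    for loading-response (t02, t06) and pre-swing (t04, t07) events.
    Cycles violating the event order after perturbation are redrawn up
    to ``spec.max_cycle_retries`` times.
    """
    spec.validate()
    if not 0 <= impairment_rating <= 4:
        raise ValueError("impairment rating must be in 0..4")
    if speed_class not in spec.speeds and speed_class not in SPEED_CLASSES:
        raise ValueError(f"unknown speed class {speed_class!r}")
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    eff = spec.impairment
    n = spec.cycles_per_session
    state_factor = eff.off_state_factor if (state == "OFF" and impairment_rating > 0) else 1.0
    mean_t = (spec.mean_cycle_duration_s[speed_class] * subject_scale
              * (1.0 + eff.cycle_slowing_per_rating * impairment_rating))
    base = spec.base_event_jitter_s
    lr_sigma = base * (1.0 + eff.loading_response_std_per_rating * impairment_rating) * state_factor
    ps_sigma = base * (1.0 + eff.pre_swing_std_per_rating * impairment_rating) * state_factor
    sigma = {"t02": lr_sigma, "t03": base, "t04": ps_sigma,
             "t05": base, "t06": lr_sigma, "t07": ps_sigma, "t08": base}
    asym = spec.asymmetry + eff.cadence_asymmetry_per_rating * impairment_rating

    durations = mean_t * np.clip(
        1.0 + spec.cycle_cv * rng.standard_normal(n + 1), 0.5, 1.5)
    starts = spec.lead_in_s + np.concatenate([[0.0], np.cumsum(durations)])

    offsets: list[dict[str, float]] = []
    for k in range(n + 1):
        t_k = durations[k]
        for _ in range(spec.max_cycle_retries):
            off = {}
            for name in EVENT_OFFSET_NAMES:
                shift = -0.5 * asym * t_k if name == "t05" else 0.0
                jitter = sigma[name] * rng.standard_normal() if sigma[name] > 0 else 0.0
                off[name] = spec.phase_fractions[name] * t_k + shift + jitter
            vals = [off[m] for m in EVENT_OFFSET_NAMES]
            if vals[0] > 0 and vals[-1] < t_k and all(
                    a < b for a, b in zip(vals, vals[1:])):
                offsets.append(off)
                break
        else:
            raise RuntimeError(
                f"could not draw an ordered event sequence for cycle {k} after "
                f"{spec.max_cycle_retries} retries; jitter or asymmetry too "
                "large for the configured phase fractions")

    cycles = []
    for k in range(n):
        s, o = starts[k], offsets[k]
        cycles.append(CycleTruth(
            t01=s, t02=s + o["t02"], t03=s + o["t03"], t04=s + o["t04"],
            t05=s + o["t05"], t06=s + o["t06"], t07=s + o["t07"],
            t08=s + o["t08"], t01_next=starts[k + 1],
            t02_next=starts[k + 1] + offsets[k + 1]["t02"]))

    timeline = GaitTimeline(tuple(cycles), subject_id=subject_id,
                            speed_class=speed_class,
                            impairment_rating=impairment_rating, state=state)
    timeline.validate()
    return timeline


# ---------------------------------------------------------------------------
# recording containers
# ---------------------------------------------------------------------------

@dataclass
class FootChannels:
    """One foot's insole channels on the shared time grid."""

    pressure: np.ndarray    # (n, 16) N/cm^2
    accel: np.ndarray       # (n, 3) g
    gyro: np.ndarray        # (n, 3) dps
    cop: np.ndarray         # (n, 2) dimensionless in [-0.5, 0.5]
    total_force: np.ndarray  # (n,) N


@dataclass
class InsoleRecording:
    time_s: np.ndarray
    left: FootChannels
    right: FootChannels
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        dt = np.diff(self.time_s)
        if len(self.time_s) and not (dt > 0).all():
            raise ValueError("insole timestamps must strictly increase")
        for foot in (self.left, self.right):
            if (foot.pressure < 0).any() or (foot.total_force < 0).any():
                raise ValueError("pressures and total force must be >= 0")
            if (np.abs(foot.cop) > 0.5 + 1e-9).any():
                raise ValueError("center of pressure must lie in [-0.5, 0.5]")


@dataclass
class ImuRecording:
    unix_time_s: np.ndarray
    accel: np.ndarray   # (n, 3) g
    gyro: np.ndarray    # (n, 3) dps
    mag: np.ndarray     # (n, 3) T
    placement: str = "left_ankle"

    def validate(self) -> None:
        if self.placement not in ("left_ankle", "right_ankle"):
            raise ValueError(f"unknown placement {self.placement!r}")
        if len(self.unix_time_s) and not (np.diff(self.unix_time_s) > 0).all():
            raise ValueError("IMU timestamps must strictly increase")

    @property
    def time_s(self) -> np.ndarray:
        """Seconds from session start."""
        if not len(self.unix_time_s):
            return self.unix_time_s
        return self.unix_time_s - self.unix_time_s[0]


# ---------------------------------------------------------------------------
# insole renderer
# ---------------------------------------------------------------------------

HEEL_CELLS = (0, 1, 2, 3, 4)        # rear five pressure cells
MID_CELLS = (5, 6, 7, 8, 9)
TOE_CELLS = (10, 11, 12, 13, 14, 15)  # front six pressure cells


def _contact_envelope(t: np.ndarray, intervals: list[tuple[float, float]],
                      ramp: float, level: float) -> np.ndarray:
    """Trapezoidal 0..1 envelope crossing `level` exactly at interval edges."""
    env = np.zeros_like(t)
    for a, b in intervals:
        r0 = a - level * ramp
        f1 = b + level * ramp
        if f1 - ramp <= r0 + ramp:  # no plateau; contact too short to render
            continue
        env += np.interp(t, [r0, r0 + ramp, f1 - ramp, f1], [0.0, 1.0, 1.0, 0.0],
                         left=0.0, right=0.0)
    return np.clip(env, 0.0, 1.0)


def _gauss(t: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / sigma) ** 2)


def _contact_intervals(timeline: GaitTimeline):
    """Per-region foot-contact intervals, with virtual edge contacts.

    A virtual left stance before the first cycle and a virtual right
    heel strike (plus trailing toe contact) after the last cycle make
    every generated cycle completable by the event detector.
    """
    cy = timeline.cycles
    first, last = cy[0], cy[-1]
    t0_first, t0 = first.t01, first.duration
    t1_last, tn = last.t01_next, last.duration
    right_heel = [(c.t01, c.t04) for c in cy]
    right_toe = [(c.t03, c.t06) for c in cy]
    left_heel = [(c.t05, c.t08) for c in cy]
    left_toe = [(c.t07, c.t02_next) for c in cy]
    # lead-in left stance: heel [t05-T, t08-T], toe [t07-T, t02 of cycle 0]
    left_heel.insert(0, (first.t05 - t0, first.t08 - t0))
    left_toe.insert(0, (first.t07 - t0, first.t02))
    # lead-out right stance: heel strike at t01', toe held to the end
    end = t1_last + 0.5 * tn
    right_heel.append((t1_last, t1_last + 0.4 * tn))
    right_toe.append((t1_last + 0.2 * tn, end + 1.0))
    return {"right_heel": right_heel, "right_toe": right_toe,
            "left_heel": left_heel, "left_toe": left_toe}


def render_insole(timeline: GaitTimeline, spec: SimulationSpec,
                  rng: np.random.Generator | None = None) -> InsoleRecording:
    """Render a ground-truth timeline into a 100 Hz insole recording.

    Heel-group pressure exceeds the detection level exactly during
    [heel strike, heel off] of each foot, toe-group pressure during
    [toe strike, toe off]; loading ramps are linear and much shorter
    than any gait phase.  Total force is the area-weighted sum of the
    cell pressures; the longitudinal center of pressure advances from
    heel to toe during stance.
    """
    timeline.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    prm, noise = spec.insole, spec.noise
    dt = 1.0 / spec.insole_rate_hz
    end = (timeline.end_time if timeline.n_cycles else spec.lead_in_s) + spec.lead_out_s
    t = np.arange(int(round(end / dt))) * dt

    envs = {k: np.zeros_like(t) for k in
            ("right_heel", "right_toe", "left_heel", "left_toe")}
    if timeline.n_cycles:
        for key, iv in _contact_intervals(timeline).items():
            envs[key] = _contact_envelope(t, iv, prm.ramp_s, prm.threshold_fraction)

    scale = prm.amplitude_scale
    feet = {}
    for side in ("left", "right"):
        heel_env, toe_env = envs[f"{side}_heel"], envs[f"{side}_toe"]
        pressure = np.zeros((len(t), 16))
        pressure[:, HEEL_CELLS] = (scale * prm.heel_peak_pressure * heel_env)[:, None]
        pressure[:, TOE_CELLS] = (scale * prm.toe_peak_pressure * toe_env)[:, None]
        pressure[:, MID_CELLS] = (scale * prm.mid_peak_pressure * heel_env * toe_env)[:, None]
        if noise.pressure_std > 0:
            pressure += rng.normal(0.0, noise.pressure_std, pressure.shape)
        pressure = np.clip(pressure, 0.0, None)
        total_force = prm.cell_area_cm2 * pressure.sum(axis=1)

        support = heel_env + toe_env
        cop_y = np.where(support > 0.05,
                         0.4 * (toe_env - heel_env) / np.maximum(support, 1e-9),
                         0.0)
        cop = np.zeros((len(t), 2))
        cop[:, 1] = cop_y
        if noise.cop_std > 0:
            cop += rng.normal(0.0, noise.cop_std, cop.shape)
        cop = np.clip(cop, -0.5, 0.5)

        accel = np.zeros((len(t), 3))
        accel[:, 2] = 1.0
        strikes = [a for a, _ in (_contact_intervals(timeline)[f"{side}_heel"]
                                  if timeline.n_cycles else [])]
        for ts in strikes:
            accel[:, 2] += prm.heel_strike_accel_g * _gauss(t, ts, 0.02)
        gyro = np.zeros((len(t), 3))
        if noise.insole_accel_std > 0:
            accel += rng.normal(0.0, noise.insole_accel_std, accel.shape)
        if noise.insole_gyro_std > 0:
            gyro += rng.normal(0.0, noise.insole_gyro_std, gyro.shape)

        feet[side] = FootChannels(pressure=pressure, accel=accel, gyro=gyro,
                                  cop=cop, total_force=total_force)

    rec = InsoleRecording(time_s=t, left=feet["left"], right=feet["right"],
                          meta={"subject_id": timeline.subject_id,
                                "speed_class": timeline.speed_class})
    rec.validate()
    return rec


# ---------------------------------------------------------------------------
# IMU renderer
# ---------------------------------------------------------------------------

def _foot_strides(timeline: GaitTimeline, side: str) -> list[tuple[float, float]]:
    """(toe off, next heel strike) swing intervals of one foot."""
    if side == "right":
        return [(c.t06, c.t01_next) for c in timeline.cycles]
    return [(c.t02, c.t05) for c in timeline.cycles]


def render_imu(timeline: GaitTimeline, spec: SimulationSpec,
               rng: np.random.Generator | None = None
               ) -> tuple[ImuRecording, ImuRecording]:
    """Render a timeline into left- and right-ankle 59.5 Hz IMU recordings.

    The gyroscope Z axis shows, per stride, one positive mid-swing lobe
    (~200 dps), a deep negative dip at that foot's toe off and a
    shallower negative dip at its heel strike; the accelerometer
    magnitude spikes at heel strike.
    """
    timeline.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    prm, noise = spec.imu, spec.noise
    dt = 1.0 / spec.imu_rate_hz
    end = (timeline.end_time if timeline.n_cycles else spec.lead_in_s) + spec.lead_out_s
    t = np.arange(int(round(end / dt))) * dt

    out = []
    for side in ("left", "right"):
        strides = _foot_strides(timeline, side)
        gyro = np.zeros((len(t), 3))
        accel = np.zeros((len(t), 3))
        accel[:, 2] = 1.0
        for to, ic in strides:
            ms = 0.5 * (to + ic)
            amp = max(prm.ms_amplitude_min,
                      rng.normal(prm.ms_amplitude_dps, prm.ms_amplitude_std))
            gyro[:, 2] += (amp * _gauss(t, ms, prm.ms_sigma_s)
                           - prm.to_depth_dps * _gauss(t, to, prm.dip_sigma_s)
                           - prm.ic_depth_dps * _gauss(t, ic, prm.dip_sigma_s))
            accel[:, 2] += prm.heel_strike_accel_g * _gauss(t, ic, prm.accel_sigma_s)
        mag = np.tile(np.asarray(prm.mag_base_t), (len(t), 1))
        if noise.imu_gyro_std > 0:
            gyro += rng.normal(0.0, noise.imu_gyro_std, gyro.shape)
        if noise.imu_accel_std > 0:
            accel += rng.normal(0.0, noise.imu_accel_std, accel.shape)
        if noise.imu_mag_std > 0:
            mag += rng.normal(0.0, noise.imu_mag_std, mag.shape)
        rec = ImuRecording(unix_time_s=prm.unix_epoch_s + t, accel=accel,
                           gyro=gyro, mag=mag, placement=f"{side}_ankle")
        rec.validate()
        out.append(rec)
    return out[0], out[1]


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass
class SessionRecord:
    subject_id: str
    state: str
    speed_class: str
    repetition: int
    rating: int
    impaired: bool
    timeline: GaitTimeline
    insole: InsoleRecording
    imu_left: ImuRecording
    imu_right: ImuRecording

    @property
    def session_id(self) -> str:
        return f"{self.subject_id}_{self.state}_{self.speed_class}_r{self.repetition}"


@dataclass
class CohortBundle:
    sessions: list[SessionRecord]
    manifest: pd.DataFrame
    spec: SimulationSpec


def assign_ratings(n_subjects: int, counts: tuple[int, ...],
                   rng: np.random.Generator) -> list[int]:
    """Distribute clinical gait ratings over subjects per a count table."""
    pool = [r for r, c in enumerate(counts) for _ in range(c)]
    if not pool:
        raise ValueError("rating counts are all zero")
    reps = math.ceil(n_subjects / len(pool))
    tiled = np.asarray(pool * reps)
    rng.shuffle(tiled)  # shuffle before truncating so small cohorts mix ratings
    return [int(r) for r in tiled[:n_subjects]]


def generate_cohort(spec: SimulationSpec, out_dir=None) -> CohortBundle:
    """Generate the full synthetic cohort: one timeline, one insole
    recording and one IMU recording pair per subject x state x speed x
    repetition, plus a manifest table linking them.

    If ``out_dir`` is given, all recordings and the manifest are written
    there as delimited text and the manifest gains file-path columns.
    """
    spec.validate()
    if spec.n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    master = np.random.default_rng(spec.seed)
    ratings = assign_ratings(spec.n_subjects, spec.rating_counts, master)
    scales = np.clip(1.0 + spec.subject_cv * master.standard_normal(spec.n_subjects),
                     0.7, 1.3)

    sessions: list[SessionRecord] = []
    for i in range(spec.n_subjects):
        subject = f"S{i:02d}"
        for state in spec.states:
            for speed in spec.speeds:
                for rep in range(1, spec.repetitions + 1):
                    r = _session_rng(spec, subject, state, speed, rep)
                    rng_n, rng_tl, rng_ins, rng_imu = r.spawn(4)
                    n_cycles = max(4, int(round(
                        spec.cycles_per_session * _SPEED_CYCLE_FACTOR[speed]
                        + rng_n.normal(0.0, spec.cycles_per_session_std))))
                    tl = sample_gait_timeline(
                        replace(spec, cycles_per_session=n_cycles),
                        subject_id=subject, speed_class=speed,
                        impairment_rating=ratings[i], state=state,
                        rng=rng_tl, subject_scale=float(scales[i]))
                    insole = render_insole(tl, spec, rng_ins)
                    imu_l, imu_r = render_imu(tl, spec, rng_imu)
                    sessions.append(SessionRecord(
                        subject_id=subject, state=state, speed_class=speed,
                        repetition=rep, rating=ratings[i],
                        impaired=ratings[i] > 0, timeline=tl, insole=insole,
                        imu_left=imu_l, imu_right=imu_r))

    rows = [{"session_id": s.session_id, "subject_id": s.subject_id,
             "state": s.state, "speed": s.speed_class,
             "repetition": s.repetition, "rating": s.rating,
             "impaired": s.impaired} for s in sessions]
    manifest = pd.DataFrame(rows)

    if out_dir is not None:
        from . import io as dio
        manifest = dio.write_cohort(sessions, manifest, out_dir)

    return CohortBundle(sessions=sessions, manifest=manifest, spec=spec)
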