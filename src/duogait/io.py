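"""Readers and writers for the canonical delimited-text layouts.

Dialect: comma-separated, "." decimal, mandatory header row, floats
formatted with six decimals (so write(read(x)) is byte-identical for
canonical files).

* Insole CSV: 51 columns — ``time_s`` then, per foot (left then right):
  ``p01..p16, acc_x, acc_y, acc_z, gyr_x, gyr_y, gyr_z, cop_x, cop_y,
  total_force``.
* IMU CSV: 10 columns — ``unix_time_s, acc_x..z, gyr_x..z, mag_x..z``
  (one file per ankle device).
* Manifest: one row per session with identifiers, rating, label and
  file paths.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import FootChannels, ImuRecording, InsoleRecording

_FOOT_FIELDS = ([f"p{i:02d}" for i in range(1, 17)]
                + ["acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z",
                   "cop_x", "cop_y", "total_force"])

INSOLE_COLUMNS = (["time_s"]
                  + [f"L_{c}" for c in _FOOT_FIELDS]
                  + [f"R_{c}" for c in _FOOT_FIELDS])

IMU_COLUMNS = ["unix_time_s", "acc_x", "acc_y", "acc_z",
               "gyr_x", "gyr_y", "gyr_z", "mag_x", "mag_y", "mag_z"]

FLOAT_FORMAT = "%.6f"


def _foot_frame(foot: FootChannels, prefix: str) -> pd.DataFrame:
    data = np.column_stack([foot.pressure, foot.accel, foot.gyro, foot.cop,
                            foot.total_force])
    return pd.DataFrame(data, columns=[f"{prefix}_{c}" for c in _FOOT_FIELDS])


def write_insole_csv(recording: InsoleRecording, path) -> Path:
    path = Path(path)
    frame = pd.concat([pd.DataFrame({"time_s": recording.time_s}),
                       _foot_frame(recording.left, "L"),
                       _foot_frame(recording.right, "R")], axis=1)
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def _check_numeric(frame: pd.DataFrame, path) -> np.ndarray:
    values = frame.to_numpy(float)
    bad = ~np.isfinite(values)
    if bad.any():
        row = int(np.argwhere(bad)[0, 0])
        raise ValueError(f"{path}: non-finite value at data row {row}")
    return values


def _check_time(time: np.ndarray, path) -> None:
    if len(time) == 0:
        raise ValueError(f"{path}: no samples")
    step = np.diff(time)
    if (step <= 0).any():
        i = int(np.argmax(step <= 0))
        raise ValueError(f"{path}: non-monotone timestamp at line {i + 3} "
                         "(times must strictly increase)")


def read_insole_csv(path) -> InsoleRecording:
    path = Path(path)
    frame = pd.read_csv(path)
    if frame.shape[1] != 51:
        raise ValueError(f"{path}: expected 51 columns "
                         f"(time + 2 x 25 channels), found {frame.shape[1]}")
    if list(frame.columns) != INSOLE_COLUMNS:
        raise ValueError(f"{path}: unexpected column names; canonical order "
                         f"starts {INSOLE_COLUMNS[:3]}...")
    if frame.empty:
        raise ValueError(f"{path}: no samples")
    values = _check_numeric(frame, path)
    time = values[:, 0]
    _check_time(time, path)

    def foot(offset: int) -> FootChannels:
        block = values[:, offset:offset + 25]
        return FootChannels(pressure=block[:, :16], accel=block[:, 16:19],
                            gyro=block[:, 19:22], cop=block[:, 22:24],
                            total_force=block[:, 24])

    return InsoleRecording(time_s=time, left=foot(1), right=foot(26),
                           meta={"source": str(path)})


def write_imu_csv(recording: ImuRecording, path) -> Path:
    path = Path(path)
    frame = pd.DataFrame(
        np.column_stack([recording.unix_time_s, recording.accel,
                         recording.gyro, recording.mag]),
        columns=IMU_COLUMNS)
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def read_imu_csv(path, placement: str = "left_ankle") -> ImuRecording:
    path = Path(path)
    frame = pd.read_csv(path)
    if frame.shape[1] != 10:
        raise ValueError(f"{path}: expected 10 columns (timestamp + 9 signal "
                         f"channels), found {frame.shape[1]}")
    if list(frame.columns) != IMU_COLUMNS:
        raise ValueError(f"{path}: unexpected column names; expected {IMU_COLUMNS}")
    if frame.empty:
        raise ValueError(f"{path}: no samples")
    values = _check_numeric(frame, path)
    _check_time(values[:, 0], path)
    return ImuRecording(unix_time_s=values[:, 0], accel=values[:, 1:4],
                        gyro=values[:, 4:7], mag=values[:, 7:10],
                        placement=placement)


def read_bouts_csv(path) -> list[tuple[float, float]]:
    frame = pd.read_csv(path)
    if list(frame.columns) != ["start_s", "end_s"]:
        raise ValueError(f"{path}: expected columns start_s,end_s")
    return [(float(a), float(b)) for a, b in frame.to_numpy(float)]


def write_manifest(manifest: pd.DataFrame, path) -> Path:
    path = Path(path)
    manifest.to_csv(path, index=False)
    return path


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_feature_table(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def write_cohort(sessions, manifest: pd.DataFrame, out_dir) -> pd.DataFrame:
    """Write every session's recordings; return the manifest with paths."""
    out = Path(out_dir)
    (out / "insole").mkdir(parents=True, exist_ok=True)
    (out / "imu").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    # paths are stored relative to the cohort directory so that a cohort
    # is relocatable and identical runs are byte-identical
    ins_paths, l_paths, r_paths, truth_paths = [], [], [], []
    for s in sessions:
        sid = s.session_id
        write_insole_csv(s.insole, out / "insole" / f"{sid}.csv")
        ins_paths.append(f"insole/{sid}.csv")
        write_imu_csv(s.imu_left, out / "imu" / f"{sid}_left.csv")
        l_paths.append(f"imu/{sid}_left.csv")
        write_imu_csv(s.imu_right, out / "imu" / f"{sid}_right.csv")
        r_paths.append(f"imu/{sid}_right.csv")
        s.timeline.to_frame().to_csv(out / "truth" / f"{sid}.csv", index=False,
                                     float_format=FLOAT_FORMAT)
        truth_paths.append(f"truth/{sid}.csv")
    manifest["insole_path"] = ins_paths
    manifest["imu_left_path"] = l_paths
    manifest["imu_right_path"] = r_paths
    manifest["truth_path"] = truth_paths
    write_manifest(manifest, out / "manifest.csv")
    return manifest
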