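"""Delimited-text I/O for IMU streams, Euler trajectories, events and spikes.

All series are plain CSV so that runs are human-diffable: IMU streams carry
``t,gx,gy,gz,ax,ay,az,mx,my,mz`` (gyro in deg/s), trajectories
``t,yaw,pitch,roll`` (degrees), quaternions ``q0,qT,qV,qH`` and spike trains
one time (seconds) per line.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

IMU_COLUMNS = ["t", "gx", "gy", "gz", "ax", "ay", "az", "mx", "my", "mz"]
EULER_COLUMNS = ["t", "yaw", "pitch", "roll"]


def read_imu(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in IMU_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"IMU file {path} missing columns: {missing}")
    return df[IMU_COLUMNS]


def write_imu(df: pd.DataFrame, path: str | Path) -> None:
    df[IMU_COLUMNS].to_csv(path, index=False)


def read_euler(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in EULER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Euler trajectory file {path} missing columns: {missing}")
    return df


def write_euler(df: pd.DataFrame, path: str | Path) -> None:
    cols = EULER_COLUMNS + [c for c in df.columns if c not in EULER_COLUMNS]
    df[cols].to_csv(path, index=False)


def read_spikes(path: str | Path) -> np.ndarray:
    arr = np.loadtxt(path, ndmin=1)
    return np.sort(arr)


def write_spikes(spikes: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(spikes, dtype=float), fmt="%.6f")


def write_quaternions(q: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(q, columns=["q0", "qT", "qV", "qH"]).to_csv(path, index=False)


def read_quaternions(path: str | Path) -> np.ndarray:
    return pd.read_csv(path)[["q0", "qT", "qV", "qH"]].to_numpy(dtype=float)


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
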