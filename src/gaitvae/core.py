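"""Core data containers shared across the pipeline.

Axis convention (fixed here, used everywhere): in the foot frame at mid-stance,
``x`` points anterior-posterior (direction of progression), ``y`` medio-lateral,
``z`` vertical, with gravity measured as +1 g on ``z`` when the foot is flat.
The sagittal-plane (pitch) angular velocity is therefore the ``y`` gyroscope
channel. Accelerometer units are g, gyroscope units deg/s.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

#: column order of the 6-channel signal matrices
CHANNELS = ("ax_g", "ay_g", "az_g", "gx_dps", "gy_dps", "gz_dps")

#: accelerometer / gyroscope full-scale ranges of the sensor
ACC_RANGE_G = 8.0
GYR_RANGE_DPS = 500.0

#: index of the sagittal (pitch) gyroscope channel within the gyro triplet
SAGITTAL_GYRO_AXIS = 1

#: samples per epoch and the working sampling rate they are cut at
EPOCH_SAMPLES = 512
WORK_FS = 100.0

#: standard gravity used for g -> m/s^2 conversion
GRAVITY = 9.81


def epoch_duration_s(fs: float = WORK_FS) -> float:
    """Duration in seconds of one epoch at sampling rate ``fs``."""
    return EPOCH_SAMPLES / fs


@dataclass
class ImuRecording:
    """One foot's 6-axis time series for a single measurement.

    ``acc`` is (n, 3) in g, ``gyr`` (n, 3) in deg/s, both on the uniform grid
    ``time`` (seconds) at sampling rate ``fs``.
    """

    time: np.ndarray
    acc: np.ndarray
    gyr: np.ndarray
    fs: float
    foot: str = "right"
    subject_id: str = ""
    group: str = ""
    session: str = ""
    uses_aid: bool = False
    measurement_id: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyr = np.asarray(self.gyr, dtype=float)
        if self.acc.shape != (self.time.size, 3) or self.gyr.shape != (self.time.size, 3):
            raise ValueError("acc and gyr must be (n, 3) matching the time grid")
        if self.time.size >= 2:
            dt = np.diff(self.time)
            if np.max(np.abs(dt - 1.0 / self.fs)) > 1e-6:
                raise ValueError("time grid must be uniform at fs")
        if not (np.all(np.isfinite(self.acc)) and np.all(np.isfinite(self.gyr))):
            raise ValueError("non-finite samples in recording")
        if self.foot not in ("left", "right"):
            raise ValueError("foot must be 'left' or 'right'")

    def __len__(self) -> int:
        return self.time.size

    @property
    def duration(self) -> float:
        return len(self) / self.fs

    @property
    def data(self) -> np.ndarray:
        """(n, 6) matrix with columns ax, ay, az, gx, gy, gz."""
        return np.hstack([self.acc, self.gyr])

    def with_signals(self, acc: np.ndarray = None, gyr: np.ndarray = None,
                     time: np.ndarray = None, fs: float = None) -> "ImuRecording":
        """Copy of this recording with some arrays replaced."""
        return replace(
            self,
            acc=self.acc if acc is None else acc,
            gyr=self.gyr if gyr is None else gyr,
            time=self.time if time is None else time,
            fs=self.fs if fs is None else fs,
        )


@dataclass
class GaitEvents:
    """Foot contacts and stance/swing phases of one recording (sample indices)."""

    foot_contacts: np.ndarray
    stance_intervals: np.ndarray  # (m, 2) half-open [start, end)
    swing_intervals: np.ndarray  # (m', 2) half-open
    n_samples: int = 0

    def __post_init__(self) -> None:
        self.foot_contacts = np.asarray(self.foot_contacts, dtype=int)
        self.stance_intervals = np.asarray(self.stance_intervals, dtype=int).reshape(-1, 2)
        self.swing_intervals = np.asarray(self.swing_intervals, dtype=int).reshape(-1, 2)
        if self.foot_contacts.size > 1 and np.any(np.diff(self.foot_contacts) <= 0):
            raise ValueError("foot contacts must be strictly increasing")
        for iv in (self.stance_intervals, self.swing_intervals):
            if iv.size and (np.any(iv[:, 0] >= iv[:, 1]) or np.any(np.diff(iv[:, 0]) <= 0)):
                raise ValueError("intervals must be sorted and non-empty")

    @property
    def n_contacts(self) -> int:
        return int(self.foot_contacts.size)

    def stance_mask(self, n: int = None) -> np.ndarray:
        """Boolean per-sample mask that is True inside stance intervals."""
        n = self.n_samples if n is None else n
        mask = np.zeros(n, dtype=bool)
        for s, e in self.stance_intervals:
            mask[max(s, 0):min(e, n)] = True
        return mask


def stride_count(events: GaitEvents) -> int:
    """Number of contact-to-contact gait cycles (``n_contacts - 1``, floored at 0)."""
    return max(events.n_contacts - 1, 0)


@dataclass
class Epoch:
    """A 512 x 6 segment of a recording, the unit the VAE consumes."""

    data: np.ndarray
    start_index: int
    foot: str
    measurement_id: str
    subject_id: str = ""
    group: str = ""
    session: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (EPOCH_SAMPLES, 6):
            raise ValueError(f"epoch must be {EPOCH_SAMPLES} x 6, got {self.data.shape}")
        if self.normalized and np.max(np.abs(self.data)) > 1.0 + 1e-9:
            raise ValueError("normalized epoch has values outside [-1, 1]")


@dataclass
class EpochStats:
    """Per-dimension mean/SD of one epoch plus dataset-level z-scores of those."""

    mean: np.ndarray
    sd: np.ndarray
    z_mean: np.ndarray
    z_sd: np.ndarray
    outlier: bool


def epochs_to_array(epochs: Sequence[Epoch]) -> np.ndarray:
    """Stack a list of epochs into an (n, 512, 6) array."""
    return np.stack([e.data for e in epochs]) if epochs else np.empty((0, EPOCH_SAMPLES, 6))
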