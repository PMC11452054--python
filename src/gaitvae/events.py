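"""Gait-event detection from a single foot-worn IMU.

Foot-worn sensors are nearly stationary during stance and rotate rapidly in
the sagittal plane during swing, so the detector works entirely on angular
velocity: mid-swings are peaks of the absolute sagittal (pitch) gyroscope
channel above an adaptive threshold, the foot contact after each mid-swing is
the first sample where the gyroscope magnitude stays quiet for a minimum
dwell, and stance lasts until the magnitude rises again at swing onset. The
adaptive threshold makes detection invariant to an overall rescaling of the
signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .core import GaitEvents, ImuRecording, SAGITTAL_GYRO_AXIS, stride_count  # noqa: F401

__all__ = ["DetectorConfig", "detect_gait_events", "stride_count"]


@dataclass
class DetectorConfig:
    """Tunable thresholds of the event detector (defaults in deg/s and s).

    The quiet/onset thresholds are interpreted at a sagittal signal scale of
    ``reference_p95_dps`` and scale linearly with the recording's own 95th
    percentile, which makes detected contacts invariant to a rescaling of
    the gyroscope signal.
    """

    peak_fraction: float = 0.5  # adaptive mid-swing threshold: fraction of p95
    min_peak_separation_s: float = 0.5
    contact_quiet_dps: float = 20.0  # gyro magnitude below this counts as quiet
    contact_dwell_s: float = 0.05  # quiet must last at least this long
    swing_onset_dps: float = 40.0  # magnitude rising above this ends stance
    reference_p95_dps: float = 200.0  # amplitude at which the dps defaults apply


def detect_gait_events(rec: ImuRecording, config: DetectorConfig | None = None) -> GaitEvents:
    """Detect foot contacts and stance/swing intervals of one recording.

    Requires the 100-Hz, gyro-offset-corrected recording of the preprocessing
    pipeline and at least 4 s of signal. Returns empty events (with a
    warning) when no swing peaks are found, e.g. on a static recording.
    """
    cfg = config or DetectorConfig()
    if rec.duration < 4.0:
        raise ValueError("recording too short for event detection (< 4 s)")
    fs = rec.fs
    sagittal = np.abs(rec.gyr[:, SAGITTAL_GYRO_AXIS])
    mag = np.linalg.norm(rec.gyr, axis=1)
    n = len(rec)

    p95 = np.percentile(sagittal, 95)
    height = cfg.peak_fraction * p95
    if height <= 0:
        height = np.inf
    scale = p95 / cfg.reference_p95_dps if p95 > 0 else 1.0
    quiet_dps = cfg.contact_quiet_dps * scale
    onset_dps = cfg.swing_onset_dps * scale
    peaks, _ = find_peaks(sagittal, height=height,
                          distance=max(int(cfg.min_peak_separation_s * fs), 1))
    if peaks.size == 0:
        warnings.warn("no swing peaks found; returning empty gait events")
        return GaitEvents(np.empty(0, int), np.empty((0, 2), int),
                          np.empty((0, 2), int), n_samples=n)

    quiet = mag < quiet_dps
    dwell = max(int(round(cfg.contact_dwell_s * fs)), 1)
    # quiet_run[i] = True when samples i .. i+dwell-1 are all quiet
    csum = np.concatenate([[0], np.cumsum(quiet)])
    quiet_run = (csum[dwell:] - csum[:-dwell]) == dwell

    contacts = []
    stances = []
    for j, p in enumerate(peaks):
        limit = peaks[j + 1] if j + 1 < peaks.size else quiet_run.size
        idx = np.flatnonzero(quiet_run[p:limit])
        if idx.size == 0:
            continue
        contact = int(p + idx[0])
        # stance ends when the magnitude rises above the swing-onset threshold
        loud = np.flatnonzero(mag[contact:] > onset_dps)
        end = int(contact + loud[0]) if loud.size else n
        if j + 1 < peaks.size:
            end = min(end, int(peaks[j + 1]))
        if end <= contact:
            continue
        if contacts and contact <= contacts[-1]:
            continue
        contacts.append(contact)
        stances.append((contact, end))

    contacts = np.asarray(contacts, dtype=int)
    stances = np.asarray(stances, dtype=int).reshape(-1, 2)
    swings = []
    for k in range(len(stances) - 1):
        swings.append((stances[k, 1], stances[k + 1, 0]))
    swings = np.asarray(swings, dtype=int).reshape(-1, 2)
    swings = swings[swings[:, 0] < swings[:, 1]] if swings.size else swings
    return GaitEvents(contacts, stances, swings, n_samples=n)


def stance_fraction(events: GaitEvents) -> float:
    """Mean fraction of the gait cycle spent in stance (contact-to-contact)."""
    if events.n_contacts < 2:
        raise ValueError("need at least two contacts")
    total_cycle = events.foot_contacts[-1] - events.foot_contacts[0]
    stance = 0
    for (s, e), nxt in zip(events.stance_intervals[:-1], events.foot_contacts[1:]):
        stance += min(e, nxt) - s
    return float(stance / total_cycle)
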