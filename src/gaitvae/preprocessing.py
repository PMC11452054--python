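"""From raw recordings to normalized 512 x 6 epochs.

The pipeline order is fixed: resample to 100 Hz -> gyroscope offset
correction -> gait-event detection -> segmentation into 512-sample epochs
starting in stance with ~50% overlap -> first-order Butterworth band-pass
(0.01-10 Hz) -> zero the epoch start -> dataset-level outlier removal
(|z| > 5 on per-dimension epoch means/SDs) -> symmetric min-max
normalization by the sensor ranges (acc / 8 g, gyro / 500 deg/s).

The band-pass is applied per epoch on the 512-sample window by default
(matching the step order above); ``filter_recording`` filters the whole
recording instead for callers who prefer that. Both a causal (default) and a
zero-phase filter variant are available.
"""

from __future__ import annotations

import warnings
from dataclasses import replace
from typing import List, Sequence, Tuple

import numpy as np
from scipy.signal import butter, filtfilt, lfilter

from .core import (ACC_RANGE_G, EPOCH_SAMPLES, GYR_RANGE_DPS, WORK_FS,
                   Epoch, EpochStats, GaitEvents, ImuRecording)
from .events import DetectorConfig, detect_gait_events, stride_count

OUTLIER_Z = 5.0


def resample_to_100hz(rec: ImuRecording) -> ImuRecording:
    """Linearly interpolate the recording onto a uniform 100 Hz grid."""
    if rec.fs < 100.0:
        raise ValueError("cannot resample: recording fs is below 100 Hz")
    if rec.fs == WORK_FS:
        return rec
    n_out = int(np.floor(rec.duration * WORK_FS))
    t_new = np.arange(n_out) / WORK_FS
    acc = np.column_stack([np.interp(t_new, rec.time, rec.acc[:, i]) for i in range(3)])
    gyr = np.column_stack([np.interp(t_new, rec.time, rec.gyr[:, i]) for i in range(3)])
    return rec.with_signals(acc=acc, gyr=gyr, time=t_new, fs=WORK_FS)


def correct_gyro_offset(rec: ImuRecording, offset: Sequence[float]) -> ImuRecording:
    """Subtract a constant per-axis gyroscope offset (deg/s)."""
    offset = np.asarray(offset, dtype=float)
    if offset.shape != (3,) or not np.all(np.isfinite(offset)):
        raise ValueError("offset must be 3 finite values")
    return rec.with_signals(gyr=rec.gyr - offset)


def estimate_gyro_offset(rec: ImuRecording, static_end_s: float = 0.5) -> np.ndarray:
    """Estimate the gyroscope offset as the mean over an initial static segment.

    The simulated protocol (and the clinical one it mimics) starts with the
    subject standing still, so the first ``static_end_s`` seconds serve as
    the static measurement.
    """
    n = int(static_end_s * rec.fs)
    if n < 2:
        raise ValueError("static segment too short")
    return rec.gyr[:n].mean(axis=0)


def _butter_band(fs: float):
    return butter(1, [0.01, 10.0], btype="bandpass", fs=fs)


def bandpass(data: np.ndarray, fs: float = WORK_FS, zero_phase: bool = False) -> np.ndarray:
    """First-order Butterworth band-pass, 0.01-10 Hz, applied per column."""
    b, a = _butter_band(fs)
    filt = filtfilt if zero_phase else lfilter
    return np.asarray(filt(b, a, data, axis=0))


def filter_recording(rec: ImuRecording, zero_phase: bool = False) -> ImuRecording:
    """Band-pass the whole recording (alternative to per-epoch filtering)."""
    out = bandpass(rec.data, rec.fs, zero_phase)
    return rec.with_signals(acc=out[:, :3], gyr=out[:, 3:])


def segment_epochs(rec: ImuRecording, events: GaitEvents,
                   overlap_step: int = EPOCH_SAMPLES // 2) -> List[Epoch]:
    """Cut 512-sample epochs starting in stance with ~50% overlap.

    Candidate starts advance by a nominal ``overlap_step`` samples and snap
    to the nearest sample inside a stance interval. The first epoch starts at
    the stance of the second stride and no epoch extends beyond the end of
    the second-to-last stride (nor past the signal end). Returns an empty
    list (with a warning) when fewer than four strides are available.
    """
    n = len(rec)
    if stride_count(events) < 4:
        warnings.warn("fewer than four strides; no epochs segmented")
        return []
    first_start = int(events.foot_contacts[1])
    limit = min(n, int(events.foot_contacts[-1]))

    stance_samples = np.flatnonzero(events.stance_mask(n))
    epochs: List[Epoch] = []
    start = first_start
    data = rec.data
    while start + EPOCH_SAMPLES <= limit:
        epochs.append(Epoch(data=data[start:start + EPOCH_SAMPLES].copy(),
                            start_index=start, foot=rec.foot,
                            measurement_id=rec.measurement_id,
                            subject_id=rec.subject_id, group=rec.group,
                            session=rec.session))
        nominal = start + overlap_step
        if nominal + EPOCH_SAMPLES > limit:
            break
        j = np.searchsorted(stance_samples, nominal)
        candidates = stance_samples[max(j - 1, 0):j + 1]
        candidates = candidates[candidates > start]
        if candidates.size == 0:
            later = stance_samples[stance_samples > nominal]
            if later.size == 0:
                break
            snapped = int(later[0])
        else:
            snapped = int(candidates[np.argmin(np.abs(candidates - nominal))])
        start = snapped
    return epochs


def filter_epoch(epoch: Epoch, zero_phase: bool = False) -> Epoch:
    """Band-pass one epoch on its own 512-sample window."""
    return replace(epoch, data=bandpass(epoch.data, WORK_FS, zero_phase))


def zero_start(epoch: Epoch) -> Epoch:
    """Subtract the first value per dimension so each epoch starts at zero."""
    return replace(epoch, data=epoch.data - epoch.data[0])


def flag_outliers(epochs: Sequence[Epoch],
                  z_threshold: float = OUTLIER_Z
                  ) -> Tuple[List[Epoch], List[Epoch], List[EpochStats]]:
    """Remove epochs whose per-dimension mean or SD is a dataset-level outlier.

    Each epoch's six means and six SDs are z-scored against the distribution
    of those statistics over the whole epoch set; an epoch is removed when
    any |z| exceeds ``z_threshold``. A statistic with zero spread across the
    dataset contributes z = 0 (never triggers removal).
    """
    if len(epochs) < 2:
        raise ValueError("need at least two epochs to compute dataset z-scores")
    means = np.stack([e.data.mean(axis=0) for e in epochs])  # (n, 6)
    sds = np.stack([e.data.std(axis=0, ddof=0) for e in epochs])

    def z(x):
        mu, sd = x.mean(axis=0), x.std(axis=0, ddof=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = (x - mu) / sd
        out[:, sd == 0] = 0.0
        return out

    z_mean, z_sd = z(means), z(sds)
    flags = (np.abs(z_mean) > z_threshold).any(axis=1) | (np.abs(z_sd) > z_threshold).any(axis=1)
    stats = [EpochStats(mean=means[i], sd=sds[i], z_mean=z_mean[i], z_sd=z_sd[i],
                        outlier=bool(flags[i])) for i in range(len(epochs))]
    kept = [e for e, f in zip(epochs, flags) if not f]
    removed = [e for e, f in zip(epochs, flags) if f]
    return kept, removed, stats


_SCALE = np.array([ACC_RANGE_G] * 3 + [GYR_RANGE_DPS] * 3)


def normalize(epoch: Epoch) -> Epoch:
    """Symmetric min-max normalization by the sensor ranges, into [-1, 1]."""
    data = np.clip(epoch.data / _SCALE, -1.0, 1.0)
    return replace(epoch, data=data, normalized=True)


def denormalize(data: np.ndarray) -> np.ndarray:
    """Map normalized epoch data back to physical units (g, deg/s)."""
    return np.asarray(data) * _SCALE


def preprocess_recording(rec: ImuRecording,
                         detector: DetectorConfig | None = None,
                         zero_phase: bool = False,
                         filter_scope: str = "epoch",
                         static_end_s: float = 0.5):
    """Run the full per-recording chain up to (pre-outlier) zeroed epochs.

    Outlier flagging and normalization are dataset-level operations and are
    applied afterwards across all measurements (see :func:`finalize_epochs`).
    Returns ``(epochs, events, rec100)``.
    """
    if filter_scope not in ("epoch", "recording"):
        raise ValueError("filter_scope must be 'epoch' or 'recording'")
    rec100 = resample_to_100hz(rec)
    rec100 = correct_gyro_offset(rec100, estimate_gyro_offset(rec100, static_end_s))
    events = detect_gait_events(rec100, detector)
    if filter_scope == "recording":
        filtered = filter_recording(rec100, zero_phase)
        epochs = segment_epochs(filtered, events)
    else:
        epochs = segment_epochs(rec100, events)
        epochs = [filter_epoch(e, zero_phase) for e in epochs]
    epochs = [zero_start(e) for e in epochs]
    return epochs, events, rec100


def finalize_epochs(epochs: Sequence[Epoch], z_threshold: float = OUTLIER_Z):
    """Dataset-level outlier removal followed by normalization.

    Returns ``(normalized_kept, removed, stats)``.
    """
    kept, removed, stats = flag_outliers(epochs, z_threshold)
    return [normalize(e) for e in kept], removed, stats
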