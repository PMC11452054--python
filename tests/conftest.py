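"""Shared fixtures: a reference synthetic walk and a session-scoped trained
reduced VAE on a two-dominant-factor cohort (reused by several test modules
because training is the expensive step)."""

from __future__ import annotations

import numpy as np
import pytest

from gaitvae.core import epochs_to_array
from gaitvae.events import detect_gait_events
from gaitvae.preprocessing import (correct_gyro_offset, estimate_gyro_offset,
                                   finalize_epochs, preprocess_recording,
                                   resample_to_100hz)
from gaitvae.synthetic import (CohortSpec, SubjectParams, simulate_cohort,
                               simulate_walk, two_factor_cohort_spec)
from gaitvae.vae import VaeConfig, build_model, train

REFERENCE_PARAMS = SubjectParams(
    subject_id="REF", group="stroke", mean_speed=0.8, stride_time=1.2,
    stride_time_cv=0.06, swing_fraction=0.35, asymmetry=0.12,
    swing_peak_gyro=250.0, noise_acc_sd=0.02, noise_gyro_sd=1.0,
    gyro_offset=(0.5, -0.8, 1.2))

#: reduced VAE used for the training-based checks: half filters, short budget
REDUCED_VAE = dict(filters=(16, 32, 64), max_epochs=30, early_stop_patience=10,
                   batch_size=64, seed=7)


@pytest.fixture(scope="session")
def reference_walk():
    """One 120-s stroke-like walk with ground truth (both feet)."""
    left, right, truth = simulate_walk(REFERENCE_PARAMS, 120.0, 104.0, seed=42)
    return left, right, truth


@pytest.fixture(scope="session")
def rec100_events(reference_walk):
    """The right-foot recording resampled/offset-corrected, with events."""
    _, right, truth = reference_walk
    rec = resample_to_100hz(right)
    rec = correct_gyro_offset(rec, estimate_gyro_offset(rec))
    return rec, detect_gait_events(rec), truth


def build_two_factor_dataset(seed: int = 11, n_stroke: int = 32, n_healthy: int = 8):
    """Simulate + preprocess the two-dominant-factor cohort.

    Returns normalized stroke/healthy epoch arrays, per-epoch factor values
    (stride_time, swing_peak_gyro) and measurement ids, plus the raw counts.
    """
    spec = two_factor_cohort_spec(n_stroke=n_stroke, n_healthy=n_healthy, seed=seed)
    records, _ = simulate_cohort(spec)
    all_epochs, factors = [], {}
    for r in records:
        factors[r["measurement_id"]] = (r["params"].stride_time,
                                        r["params"].swing_peak_gyro)
        for foot in ("left", "right"):
            eps, _, _ = preprocess_recording(r[foot])
            all_epochs += eps
    kept, removed, _ = finalize_epochs(all_epochs)
    stroke = [e for e in kept if e.group == "stroke"]
    healthy = [e for e in kept if e.group == "healthy"]
    return dict(stroke=stroke, healthy=healthy, factors=factors,
                n_total=len(all_epochs), n_removed=len(removed))


@pytest.fixture(scope="session")
def trained_vae():
    """Reduced VAE trained on >= 2000 stroke-like epochs of the two-factor cohort."""
    data = build_two_factor_dataset()
    stroke = data["stroke"]
    subjects = sorted({e.subject_id for e in stroke})
    rng = np.random.default_rng(5)
    test_subjects = set(list(rng.permutation(subjects))[:6])
    train_eps = [e for e in stroke if e.subject_id not in test_subjects]
    test_eps = [e for e in stroke if e.subject_id in test_subjects]
    x_train = epochs_to_array(train_eps)
    x_test = epochs_to_array(test_eps)
    assert x_train.shape[0] >= 2000
    cfg = VaeConfig(**REDUCED_VAE)
    model = build_model(cfg)
    model, report = train(model, x_train, x_test, cfg)
    return dict(model=model, report=report, config=cfg,
                x_train=x_train, x_test=x_test,
                train_epochs=train_eps, test_epochs=test_eps,
                healthy_epochs=data["healthy"], factors=data["factors"],
                n_total=data["n_total"], n_removed=data["n_removed"])
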