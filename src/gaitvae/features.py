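"""Measurement-level features: averaged latent scores joined with gait speed.

A two-minute walk yields ~40 epochs per foot; the measurement-level latent
feature is the arithmetic mean of each of the 12 posterior-mean dimensions
over the measurement's non-outlier epochs, per foot. Downstream statistics
use the right foot's averages by convention (configurable).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

LATENT_COLUMNS = [f"L{i}" for i in range(12)]
META_COLUMNS = ["measurement_id", "subject_id", "group", "session", "uses_aid", "foot"]


def scores_table(epochs, codes_mu: np.ndarray) -> pd.DataFrame:
    """Assemble the epoch-score table from epochs and their posterior means."""
    codes_mu = np.asarray(codes_mu)
    if codes_mu.shape[0] != len(epochs):
        raise ValueError("one latent code per epoch required")
    cols = [f"L{i}" for i in range(codes_mu.shape[1])]
    rows = pd.DataFrame({
        "measurement_id": [e.measurement_id for e in epochs],
        "subject_id": [e.subject_id for e in epochs],
        "group": [e.group for e in epochs],
        "session": [e.session for e in epochs],
        "foot": [e.foot for e in epochs],
        "start_index": [e.start_index for e in epochs],
    })
    return pd.concat([rows, pd.DataFrame(codes_mu, columns=cols)], axis=1)


def aggregate(scores: pd.DataFrame) -> pd.DataFrame:
    """Average the latent scores per measurement and foot.

    Input: epoch-score table with metadata columns and latent columns L0..;
    output: one row per (measurement_id, foot) with the latent means and
    ``n_epochs_used``. Aggregation is order-invariant and idempotent.
    """
    latent = [c for c in scores.columns if c.startswith("L") and c[1:].isdigit()]
    if not latent:
        raise ValueError("no latent columns found")
    meta = [c for c in ["subject_id", "group", "session", "uses_aid"] if c in scores.columns]
    grouped = scores.groupby(["measurement_id", "foot"], sort=True)
    out = grouped[latent].mean()
    out["n_epochs_used"] = grouped.size()
    for c in meta:
        out[c] = grouped[c].first()
    return out.reset_index()


def attach_gait_speed(features: pd.DataFrame, speeds: pd.DataFrame) -> pd.DataFrame:
    """Join per-measurement gait speed (columns measurement_id, foot, gait_speed_mps)."""
    return features.merge(speeds, on=["measurement_id", "foot"], how="left")


def select_foot(features: pd.DataFrame, foot: str = "right") -> pd.DataFrame:
    """Restrict the feature table to one foot (analysis convention: right)."""
    if foot not in ("left", "right"):
        raise ValueError("foot must be 'left' or 'right'")
    return features[features["foot"] == foot].reset_index(drop=True)


def znormalize_features(table: pd.DataFrame, columns: Sequence[str],
                        reference: str = "stroke") -> pd.DataFrame:
    """Z-normalize feature columns against a reference group's mean/SD.

    ``reference`` is a group label ("stroke", "healthy") or "all". Used for
    plotting/comparison only; raises on zero-variance features.
    """
    out = table.copy()
    ref = table if reference == "all" else table[table["group"] == reference]
    if ref.empty:
        raise ValueError(f"no rows in reference group '{reference}'")
    for c in columns:
        sd = ref[c].std(ddof=0)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"zero variance in feature '{c}'")
        out[c] = (table[c] - ref[c].mean()) / sd
    return out
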