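"""File formats of the pipeline artifacts.

Recordings are plain CSV (``time_s,ax_g,ay_g,az_g,gx_dps,gy_dps,gz_dps``)
with a JSON sidecar for metadata; ground truth is one JSON per measurement;
epochs are stored in a single HDF5 container plus a manifest CSV; feature
and statistics tables are CSV throughout. Floats are written with a fixed
"%.10g" format so identical runs produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import h5py
import numpy as np
import pandas as pd

from .core import CHANNELS, Epoch, ImuRecording
from .synthetic import GroundTruth

FLOAT_FMT = "%.10g"


def recording_basename(rec: ImuRecording) -> str:
    return f"{rec.measurement_id}_{rec.foot}"


def write_recording(rec: ImuRecording, directory: Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    base = directory / recording_basename(rec)
    df = pd.DataFrame(np.column_stack([rec.time, rec.acc, rec.gyr]),
                      columns=["time_s", *CHANNELS])
    df.to_csv(base.with_suffix(".csv"), index=False, float_format=FLOAT_FMT)
    meta = dict(subject_id=rec.subject_id, group=rec.group, session=rec.session,
                foot=rec.foot, fs=rec.fs, uses_aid=rec.uses_aid,
                measurement_id=rec.measurement_id)
    base.with_suffix(".json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    return base.with_suffix(".csv")


def read_recording(csv_path: Path) -> ImuRecording:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    return ImuRecording(time=df["time_s"].to_numpy(),
                        acc=df[list(CHANNELS[:3])].to_numpy(),
                        gyr=df[list(CHANNELS[3:])].to_numpy(),
                        fs=float(meta["fs"]), foot=meta["foot"],
                        subject_id=meta["subject_id"], group=meta["group"],
                        session=meta["session"], uses_aid=bool(meta["uses_aid"]),
                        measurement_id=meta["measurement_id"])


def write_truth(truth: GroundTruth, measurement_id: str, directory: Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    payload = {
        "true_distance": truth.true_distance,
        "true_mean_speed": truth.true_mean_speed,
        "generative_factors": truth.generative_factors,
        "start_offset_samples": truth.start_offset_samples,
        "true_contacts": {f: v.tolist() for f, v in truth.true_contacts.items()},
        "true_stance_intervals": {f: v.tolist() for f, v in truth.true_stance_intervals.items()},
        "turn_intervals": {f: np.asarray(v).tolist() for f, v in truth.turn_intervals.items()},
    }
    path = directory / f"{measurement_id}_truth.json"
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path


def read_truth(path: Path) -> Dict:
    return json.loads(Path(path).read_text())


def write_events_csv(rows: List[Dict], path: Path) -> None:
    pd.DataFrame(rows, columns=["measurement_id", "foot", "contact_index",
                                "stance_start", "stance_end"]).to_csv(
        path, index=False, float_format=FLOAT_FMT)


def write_epochs(epochs: Sequence[Epoch], h5_path: Path, manifest_path: Path) -> None:
    """Persist epochs as one HDF5 array plus a manifest CSV."""
    data = np.stack([e.data for e in epochs]).astype(np.float32) if epochs else \
        np.empty((0, 512, 6), dtype=np.float32)
    with h5py.File(h5_path, "w") as f:
        f.create_dataset("epochs", data=data, compression="gzip", compression_opts=4)
    pd.DataFrame({
        "epoch_id": np.arange(len(epochs)),
        "measurement_id": [e.measurement_id for e in epochs],
        "subject_id": [e.subject_id for e in epochs],
        "group": [e.group for e in epochs],
        "session": [e.session for e in epochs],
        "foot": [e.foot for e in epochs],
        "start_index": [e.start_index for e in epochs],
        "normalized": [e.normalized for e in epochs],
    }).to_csv(manifest_path, index=False)


def read_epochs(h5_path: Path, manifest_path: Path) -> Tuple[np.ndarray, pd.DataFrame]:
    with h5py.File(h5_path, "r") as f:
        data = f["epochs"][...]
    manifest = pd.read_csv(manifest_path)
    return data, manifest


def write_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def file_sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
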