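"""File formats: recording containers, configs and performance reports.

Each trial lives in one HDF5 file with datasets ``emg`` (N x 6, float) and
``position`` (M x 3, float, cm) plus attributes for task, speed, trial,
seed and the two sample rates; ``cycle_bounds`` is stored as an integer
dataset of (start, end) position-sample indices. Experiment and pipeline
configuration is plain YAML. Reports are CSV (one row per fold) plus a JSON
summary.
"""

from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import yaml

from .synthetic import ExperimentConfig, Recording

log = logging.getLogger("emg2kin")

__all__ = [
    "SchemaError",
    "write_recording",
    "read_recording",
    "read_experiment_dir",
    "load_experiment_config",
    "save_experiment_config",
]


class SchemaError(ValueError):
    """A recording container is missing required datasets or attributes."""


def write_recording(rec: Recording, path) -> Path:
    """Write one trial container; returns the path written."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("emg", data=rec.emg)
        f.create_dataset("position", data=rec.position)
        f.create_dataset(
            "cycle_bounds", data=np.asarray(rec.cycle_bounds, dtype=np.int64)
        )
        f.attrs.update(
            {
                "task_id": rec.task_id,
                "speed": rec.speed,
                "trial_index": rec.trial_index,
                "seed": rec.seed,
                "t0": rec.t0,
                "fs_emg": rec.fs_emg,
                "fs_pos": rec.fs_pos,
            }
        )
    return path


def read_recording(path) -> Recording:
    """Read one trial container back, validating the schema."""
    with h5py.File(path, "r") as f:
        for key in ("emg", "position", "cycle_bounds"):
            if key not in f:
                raise SchemaError(f"{path}: missing dataset {key!r}")
        for key in ("task_id", "speed", "trial_index", "fs_emg", "fs_pos"):
            if key not in f.attrs:
                raise SchemaError(f"{path}: missing attribute {key!r}")
        return Recording(
            emg=f["emg"][()],
            position=f["position"][()],
            cycle_bounds=[tuple(b) for b in f["cycle_bounds"][()]],
            task_id=str(f.attrs["task_id"]),
            speed=str(f.attrs["speed"]),
            trial_index=int(f.attrs["trial_index"]),
            seed=int(f.attrs.get("seed", 0)),
            t0=float(f.attrs.get("t0", 0.0)),
            fs_emg=float(f.attrs["fs_emg"]),
            fs_pos=float(f.attrs["fs_pos"]),
        )


def read_experiment_dir(directory) -> list[Recording]:
    """Read every ``*.h5`` trial container in a directory, sorted by name."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"no such input directory: {directory}")
    paths = sorted(directory.glob("*.h5"))
    if not paths:
        raise SchemaError(f"no recording containers in {directory}")
    return [read_recording(p) for p in paths]


def load_experiment_config(path) -> ExperimentConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = ExperimentConfig().__dataclass_fields__
    unknown = set(raw) - set(known)
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    for key in ("tasks", "speeds"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return ExperimentConfig(**raw)


def save_experiment_config(config: ExperimentConfig, path) -> Path:
    path = Path(path)
    d = asdict(config)
    d["tasks"] = list(d["tasks"])
    d["speeds"] = list(d["speeds"])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
    return path


def recording_filename(rec: Recording) -> str:
    return f"{rec.task_id}_{rec.speed}_trial{rec.trial_index:02d}.h5"
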