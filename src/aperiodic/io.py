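"""On-disk formats: TSV tables, epoch bundles, YAML configs.

All tabular outputs are tab-separated text; epochs are stored as a
directory of ``.npy`` arrays (one per participant x session x period) with
a JSON sidecar describing sampling rate, window and channel names, plus the
trial table as TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import InputError
from .synth import EpochSet

__all__ = [
    "write_table",
    "read_table",
    "write_epochs",
    "read_epochs",
    "write_yaml",
    "read_yaml",
]


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_epochs(epochs: EpochSet, directory, name: str,
                 channel_names: list[str] | None = None) -> Path:
    """Write one EpochSet as <name>.npy + <name>.json + <name>_trials.tsv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.save(directory / f"{name}.npy", epochs.data)
    sidecar = {
        "srate": epochs.srate,
        "window_label": epochs.window_label,
        "t0_offset_ms": epochs.t0_offset_ms,
        "n_trials": int(epochs.n_trials),
        "n_electrodes": int(epochs.n_electrodes),
        "n_samples": int(epochs.n_samples),
        "channel_names": channel_names
        or [f"E{i + 1:02d}" for i in range(epochs.n_electrodes)],
    }
    (directory / f"{name}.json").write_text(json.dumps(sidecar, indent=2))
    epochs.metadata.to_csv(directory / f"{name}_trials.tsv", sep="\t",
                           index=False)
    return directory / f"{name}.npy"


def read_epochs(directory, name: str) -> tuple[EpochSet, list[str]]:
    directory = Path(directory)
    npy = directory / f"{name}.npy"
    sidecar_path = directory / f"{name}.json"
    if not npy.exists() or not sidecar_path.exists():
        raise InputError(f"epoch bundle {name!r} not found in {directory}")
    sidecar = json.loads(sidecar_path.read_text())
    data = np.load(npy)
    meta = pd.read_csv(directory / f"{name}_trials.tsv", sep="\t")
    es = EpochSet(data=data, srate=sidecar["srate"],
                  window_label=sidecar["window_label"],
                  t0_offset_ms=sidecar["t0_offset_ms"], metadata=meta)
    return es, sidecar["channel_names"]


def write_yaml(obj: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(obj, sort_keys=False))
    return path


def read_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
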