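"""Reading and writing trial sets, feature tables, and model archives.

Trials travel as delimited numeric matrices (rows = channels, columns =
samples) listed in a manifest CSV with ``path,label`` columns, or as EDF
recordings (one trial per file) read through ``mne`` when it is installed.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from lmdcsp.dataset import EEGTrialSet
from lmdcsp.preprocess import RawTrial


def read_matrix(path: str | Path) -> np.ndarray:
    """Channels x samples matrix from a delimited text file (comma or
    whitespace separated)."""
    path = Path(path)
    try:
        return np.loadtxt(path, delimiter=",", ndmin=2)
    except ValueError:
        return np.loadtxt(path, ndmin=2)


def write_matrix(path: str | Path, data: np.ndarray) -> None:
    np.savetxt(path, np.asarray(data), delimiter=",", fmt="%.10g")


def read_edf_trial(path: str | Path, label: str) -> RawTrial:
    """One EDF recording as a single trial (requires the ``mne`` extra)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return RawTrial(
        data=raw.get_data() * 1e6,  # volts -> microvolts
        sampling_rate=float(raw.info["sfreq"]),
        label=label,
        channel_names=tuple(raw.ch_names),
    )


def read_manifest(path: str | Path, sampling_rate: float = 128.0) -> EEGTrialSet:
    """Trial set from a manifest CSV (columns ``path,label``; matrix paths
    are resolved relative to the manifest; ``.edf`` files go through mne)."""
    path = Path(path)
    trials: list[RawTrial] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            trial_path = path.parent / row["path"]
            if trial_path.suffix.lower() == ".edf":
                trials.append(read_edf_trial(trial_path, row["label"]))
            else:
                trials.append(
                    RawTrial(
                        data=read_matrix(trial_path),
                        sampling_rate=sampling_rate,
                        label=row["label"],
                    )
                )
    class_names = tuple(sorted({t.label for t in trials}))
    return EEGTrialSet(trials=tuple(trials), class_names=class_names)


def write_trial_set(dataset: EEGTrialSet, out_dir: str | Path) -> Path:
    """Write one matrix CSV per trial plus the manifest; returns its path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, trial in enumerate(dataset.trials):
        name = f"trial_{i:03d}.csv"
        write_matrix(out_dir / name, trial.data)
        rows.append({"path": name, "label": trial.label})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def write_features(path: str | Path, features: np.ndarray, labels: Sequence[str]) -> None:
    """Feature table CSV: trial id, label, f_1..f_g."""
    features = np.asarray(features)
    df = pd.DataFrame(features, columns=[f"f{j + 1}" for j in range(features.shape[1])])
    df.insert(0, "label", list(labels))
    df.insert(0, "trial", np.arange(len(df)))
    df.to_csv(path, index=False)


def read_features(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    feat_cols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    return df[feat_cols].to_numpy(dtype=float), df["label"].to_numpy()
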