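"""Labelled collections of EEG trials."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from lmdcsp.preprocess import RawTrial


@dataclass(frozen=True)
class EEGTrialSet:
    """All trials of one subject, with consistent geometry and labels."""

    trials: tuple[RawTrial, ...]
    class_names: tuple[str, ...]
    subject: str = "subject"

    def __post_init__(self) -> None:
        if not self.trials:
            raise ValueError("trial set is empty")
        ch = {t.n_channels for t in self.trials}
        fs = {t.sampling_rate for t in self.trials}
        if len(ch) != 1 or len(fs) != 1:
            raise ValueError("trials disagree on channel count or sampling rate")
        labels = {t.label for t in self.trials}
        if not labels <= set(self.class_names):
            raise ValueError(f"labels {labels - set(self.class_names)} missing from class_names")

    @property
    def n_channels(self) -> int:
        return self.trials[0].n_channels

    @property
    def sampling_rate(self) -> float:
        return self.trials[0].sampling_rate

    @property
    def labels(self) -> np.ndarray:
        return np.array([t.label for t in self.trials])

    def by_class(self) -> dict[str, list[RawTrial]]:
        out: dict[str, list[RawTrial]] = {c: [] for c in self.class_names}
        for t in self.trials:
            out[t.label].append(t)
        return out
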