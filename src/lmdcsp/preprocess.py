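"""Band-pass filtering, common average referencing, and mirror extension.

Raw motor-imagery EEG is prepared for local mean decomposition in three
steps: a zero-phase Butterworth band-pass (8-30 Hz by default, covering the
mu and beta sensorimotor rhythms), common average referencing (CAR), and a
mirror extension that pads each channel with its own reflection so the
decomposition's end effects fall outside the segment of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import signal as sps


@dataclass(frozen=True)
class RawTrial:
    """One labelled EEG trial: a channels x samples matrix in microvolts."""

    data: np.ndarray
    sampling_rate: float
    label: str
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
            raise ValueError("trial data must be a channels x samples matrix with >= 2 of each")
        if not np.isfinite(data).all():
            raise ValueError("trial data contains non-finite values")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        object.__setattr__(self, "data", data)
        if not self.channel_names:
            object.__setattr__(
                self, "channel_names", tuple(f"ch{i + 1}" for i in range(data.shape[0]))
            )
        elif len(self.channel_names) != data.shape[0]:
            raise ValueError("channel_names length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class PreprocessedTrial:
    """A trial after filtering/referencing, with provenance of both steps."""

    data: np.ndarray
    sampling_rate: float
    label: str
    channel_names: tuple[str, ...] = ()
    band: tuple[float, float] | None = None
    car: bool = False

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class ExtendedSignal:
    """A single-channel signal padded to triple length by mirror reflection."""

    values: np.ndarray
    origin_length: int

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or len(values) != 3 * self.origin_length:
            raise ValueError("extended signal must have length exactly 3 x origin_length")
        object.__setattr__(self, "values", values)


# Artifact removal is delegated to external tooling; the hook defaults to a
# pass-through so the stage order (filter -> artifacts -> CAR -> extension)
# stays explicit in pipeline code.
ArtifactHook = Callable[[PreprocessedTrial], PreprocessedTrial]


def no_artifact_removal(trial: PreprocessedTrial) -> PreprocessedTrial:
    return trial


def bandpass_filter(
    trial: RawTrial | PreprocessedTrial,
    low: float = 8.0,
    high: float = 30.0,
    order: int = 5,
) -> PreprocessedTrial:
    """Zero-phase Butterworth band-pass applied independently per channel.

    Forward-backward filtering (``sosfiltfilt``) doubles the effective order
    and cancels the group delay, so oscillatory features keep their latency.

    Parameters
    ----------
    trial
        Input trial; every channel is filtered with the same coefficients.
    low, high
        Band edges in Hz; must satisfy ``0 < low < high < sampling_rate / 2``.
    order
        Order of the underlying one-pass Butterworth design.
    """
    fs = trial.sampling_rate
    if not (0.0 < low < high < fs / 2.0):
        raise ValueError(f"band ({low}, {high}) Hz must lie inside (0, {fs / 2}) Hz")
    if order < 1:
        raise ValueError("filter order must be >= 1")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, trial.data, axis=1)
    return PreprocessedTrial(
        data=filtered,
        sampling_rate=fs,
        label=trial.label,
        channel_names=trial.channel_names,
        band=(low, high),
        car=getattr(trial, "car", False),
    )


def common_average_reference(trial: PreprocessedTrial | RawTrial) -> PreprocessedTrial:
    """Subtract the instantaneous mean of all channels from every channel."""
    if trial.data.shape[0] < 2:
        raise ValueError("CAR requires at least two channels")
    referenced = trial.data - trial.data.mean(axis=0, keepdims=True)
    return PreprocessedTrial(
        data=referenced,
        sampling_rate=trial.sampling_rate,
        label=trial.label,
        channel_names=trial.channel_names,
        band=getattr(trial, "band", None),
        car=True,
    )


def mirror_extend(signal: Sequence[float] | np.ndarray) -> ExtendedSignal:
    """Pad a signal with full reflections on both sides.

    ``[s(n)..s(1), s(1)..s(n), s(n)..s(1)]`` — the original occupies the
    middle third, so decomposition boundary artefacts land in the copies.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("signal must be a non-empty 1-D vector")
    values = np.concatenate([x[::-1], x, x[::-1]])
    return ExtendedSignal(values=values, origin_length=x.size)


def crop_to_original(extended_result: np.ndarray, n: int) -> np.ndarray:
    """Recover the middle third of a mirror-extended result (the undo of
    :func:`mirror_extend` applied to anything derived from it)."""
    y = np.asarray(extended_result, dtype=float)
    if y.ndim != 1 or n < 1 or y.size != 3 * n:
        raise ValueError(f"expected a 1-D vector of length 3 x {n}, got shape {y.shape}")
    return y[n : 2 * n].copy()


def preprocess_trial(
    trial: RawTrial,
    low: float = 8.0,
    high: float = 30.0,
    order: int = 5,
    car: bool = True,
    artifact_hook: ArtifactHook = no_artifact_removal,
    crop_seconds: tuple[float, float] | None = None,
) -> PreprocessedTrial:
    """Full preprocessing chain: band-pass -> artifact hook -> CAR (-> crop).

    ``crop_seconds`` optionally restricts the trial to a ``[t_start, t_end)``
    window (seconds) after referencing, for datasets where only part of the
    recorded epoch holds imagery.
    """
    out = bandpass_filter(trial, low=low, high=high, order=order)
    out = artifact_hook(out)
    if car:
        out = common_average_reference(out)
    if crop_seconds is not None:
        t0, t1 = crop_seconds
        i0 = int(round(t0 * out.sampling_rate))
        i1 = int(round(t1 * out.sampling_rate))
        if not (0 <= i0 < i1 <= out.data.shape[1]):
            raise ValueError(f"crop window {crop_seconds} s outside trial duration")
        out = PreprocessedTrial(
            data=out.data[:, i0:i1],
            sampling_rate=out.sampling_rate,
            label=out.label,
            channel_names=out.channel_names,
            band=out.band,
            car=out.car,
        )
    return out
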