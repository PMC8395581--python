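"""Local mean decomposition (LMD) of single-channel signals.

LMD iteratively peels a signal into *product functions* (PFs): each PF is an
envelope-modulated oscillation obtained by sifting, i.e. repeatedly
subtracting a smoothed local-mean curve and dividing by a smoothed local
envelope until the envelope flattens to ~1.  The first PF carries the
highest characteristic frequency; what remains after the last PF is a
low-frequency residual.  By construction the PFs and the residual add back
to the input exactly.

The local mean and envelope are built from successive extrema: for each pair
of adjacent extrema the mean is their midpoint and the envelope half their
absolute difference, held piecewise-constant and then smoothed by a repeated
centered moving average.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from lmdcsp.preprocess import ExtendedSignal


class InsufficientExtremaError(ValueError):
    """Raised when a signal has fewer than three local extrema (monotone or
    near-monotone residual: nothing left to sift)."""


@dataclass(frozen=True)
class LMDConfig:
    """Sifting controls.

    Parameters
    ----------
    max_pfs
        Upper bound on extracted product functions; EEG sampled at 128 Hz
        rarely yields more than six meaningful ones.
    max_sift_iterations
        Cap on inner sifting passes per PF.
    envelope_convergence_tol
        Sifting stops once ``max |envelope - 1| < tol``: the demodulated
        signal is then a pure frequency-modulated oscillation.
    smoothing_window
        Odd moving-average window; ``None`` derives it per pass as half the
        mean extrema spacing (odd-forced, minimum 3).
    max_smoothing_passes
        The moving average is reapplied until no two adjacent smoothed
        values are equal, capped at this count.
    """

    max_pfs: int = 8
    max_sift_iterations: int = 30
    envelope_convergence_tol: float = 1e-3
    smoothing_window: int | None = None
    max_smoothing_passes: int = 20

    def __post_init__(self) -> None:
        if self.max_pfs < 1:
            raise ValueError("max_pfs must be >= 1")
        if self.envelope_convergence_tol <= 0:
            raise ValueError("envelope_convergence_tol must be positive")
        if self.smoothing_window is not None and (
            self.smoothing_window < 3 or self.smoothing_window % 2 == 0
        ):
            raise ValueError("smoothing_window must be odd and >= 3")


@dataclass(frozen=True)
class PFDecomposition:
    """Ordered product functions plus residual for one channel signal."""

    pfs: tuple[np.ndarray, ...]
    residual: np.ndarray
    n_iterations: tuple[int, ...] = ()

    @property
    def n_pfs(self) -> int:
        return len(self.pfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for pf in self.pfs:
            out = out + pf
        return out


def _extrema_indices(x: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima and minima, flat runs collapsed to
    their first sample."""
    # collapse equal-valued runs so plateaus count once, at their first index
    keep = np.empty(len(x), dtype=bool)
    keep[0] = True
    keep[1:] = x[1:] != x[:-1]
    idx = np.flatnonzero(keep)
    xv = x[idx]
    if len(xv) < 3:
        return np.empty(0, dtype=int)
    d = np.sign(np.diff(xv))
    turn = np.flatnonzero(d[1:] != d[:-1]) + 1
    return idx[turn]


def _smooth(y: np.ndarray, window: int, max_passes: int) -> np.ndarray:
    """Centered moving average with edge replication, repeated until no two
    adjacent values are equal (plateaus fully dissolved) or the pass cap."""
    half = window // 2
    out = y
    for _ in range(max_passes):
        padded = np.empty(len(out) + 2 * half)
        padded[:half] = out[0]
        padded[half:-half] = out
        padded[-half:] = out[-1]
        csum = np.cumsum(padded)
        out = np.empty_like(out)
        out[0] = csum[window - 1]
        out[1:] = csum[window:] - csum[:-window]
        out /= window
        if not np.any(out[1:] == out[:-1]):
            break
    return out


def local_mean_and_envelope(
    signal: np.ndarray, config: LMDConfig = LMDConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed local-mean and local-envelope curves of one sifting pass.

    Raises
    ------
    InsufficientExtremaError
        If the signal has fewer than three local extrema.
    """
    x = np.asarray(signal, dtype=float)
    ext = _extrema_indices(x)
    if len(ext) < 3:
        raise InsufficientExtremaError(f"only {len(ext)} extrema; need >= 3")
    vals = x[ext]
    mids = 0.5 * (vals[1:] + vals[:-1])
    amps = 0.5 * np.abs(vals[1:] - vals[:-1])

    n = len(x)
    # hold each segment value from one extremum to the next; extend the
    # first/last segment to the signal boundaries
    bounds = np.concatenate([[0], ext[1:-1], [n]])
    seg_len = np.diff(bounds)
    mean_step = np.repeat(mids, seg_len)
    env_step = np.repeat(amps, seg_len)

    if config.smoothing_window is not None:
        window = config.smoothing_window
    else:
        spacing = np.mean(np.diff(ext))
        window = max(3, int(round(spacing / 2.0)))
        if window % 2 == 0:
            window += 1
    mean_curve = _smooth(mean_step, window, config.max_smoothing_passes)
    env_curve = _smooth(env_step, window, config.max_smoothing_passes)
    # the envelope divides the signal during sifting: keep it strictly positive
    floor = max(1e-12, 1e-10 * float(np.max(env_curve, initial=0.0)))
    env_curve = np.maximum(env_curve, floor)
    return mean_curve, env_curve


def _sift_pf(resid: np.ndarray, config: LMDConfig) -> tuple[np.ndarray, int] | None:
    """Extract one product function from ``resid``; ``None`` when the
    residual is monotone (fewer than three extrema)."""
    s = resid
    envelope_product = np.ones_like(resid)
    iterations = 0
    for it in range(config.max_sift_iterations):
        try:
            mean_curve, env_curve = local_mean_and_envelope(s, config)
        except InsufficientExtremaError:
            if it == 0:
                return None
            break
        if it > 0 and np.max(np.abs(env_curve - 1.0)) < config.envelope_convergence_tol:
            break
        s = (s - mean_curve) / env_curve
        envelope_product = envelope_product * env_curve
        iterations = it + 1
    return envelope_product * s, iterations


def decompose(signal: ExtendedSignal | np.ndarray, config: LMDConfig = LMDConfig()) -> PFDecomposition:
    """Decompose a signal into product functions and a residual.

    Accepts a mirror-:class:`~lmdcsp.preprocess.ExtendedSignal` (the normal
    pipeline input; crop each PF back afterwards) or a plain vector.  A
    signal with fewer than three extrema comes back untouched as the
    residual with zero PFs.
    """
    x = signal.values if isinstance(signal, ExtendedSignal) else np.asarray(signal, dtype=float)
    if x.ndim != 1 or len(x) < 5:
        raise ValueError("signal must be a 1-D vector of length >= 5")
    if not np.isfinite(x).all():
        raise ValueError("signal contains non-finite values")

    resid = x.copy()
    pfs: list[np.ndarray] = []
    iters: list[int] = []
    for _ in range(config.max_pfs):
        result = _sift_pf(resid, config)
        if result is None:
            break
        pf, n_it = result
        pfs.append(pf)
        iters.append(n_it)
        resid = resid - pf
        if len(_extrema_indices(resid)) < 3:
            break
    return PFDecomposition(pfs=tuple(pfs), residual=resid, n_iterations=tuple(iters))
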