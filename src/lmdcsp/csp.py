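"""One-versus-one common spatial patterns and log-variance features.

CSP finds spatial filters that maximize the variance of one class while
minimizing the other's, by simultaneously diagonalizing the two
trace-normalized class covariance matrices.  For the three-class problem the
three pairwise filters (A/E, A/F, E/F) are stacked vertically into one
global filter; projecting a trial through it and taking normalized
log-variances of the projected rows yields the feature vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import linalg as sla


@dataclass(frozen=True)
class ClassCovariance:
    """Average trace-normalized covariance of one class."""

    matrix: np.ndarray
    class_label: str = ""
    n_trials: int = 1


@dataclass(frozen=True)
class SpatialFilterBank:
    """Pairwise CSP filters and their vertical concatenation."""

    pairwise: dict[tuple[str, str], np.ndarray]
    global_matrix: np.ndarray
    m: int

    @property
    def n_features(self) -> int:
        return self.global_matrix.shape[0]


def normalized_covariance(X: np.ndarray) -> np.ndarray:
    """Trace-normalized spatial covariance ``X X^T / trace(X X^T)``."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("trial must be a channels x samples matrix")
    cov = X @ X.T
    tr = np.trace(cov)
    if tr <= 0:
        raise ZeroDivisionError("all-zero trial: trace of covariance is zero")
    return cov / tr


def class_covariance(trials: Sequence[np.ndarray], label: str = "") -> ClassCovariance:
    """Arithmetic mean of per-trial normalized covariances."""
    if len(trials) == 0:
        raise ValueError("need at least one trial")
    mats = [normalized_covariance(X) for X in trials]
    return ClassCovariance(matrix=np.mean(mats, axis=0), class_label=label, n_trials=len(mats))


def _sign_fix(W: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude entry of each row positive (determinism
    across linear-algebra backends)."""
    idx = np.argmax(np.abs(W), axis=1)
    signs = np.sign(W[np.arange(W.shape[0]), idx])
    signs[signs == 0] = 1.0
    return W * signs[:, None]


def fit_pairwise_filter(
    class1_trials: Sequence[np.ndarray],
    class2_trials: Sequence[np.ndarray],
    m: int = 4,
) -> np.ndarray:
    """CSP filter (2m x M) between two classes via whiten-then-rotate.

    The composite covariance ``Rc = R1 + R2`` is whitened; the whitened R1
    is eigendecomposed; the returned rows are the ``m`` eigenvector
    directions with the largest eigenvalues (maximal class-1 variance
    share) followed by the ``m`` with the smallest (maximal class-2 share),
    mapped back through the whitening transform.  Each row ``w`` satisfies
    ``w^T Rc w = 1``.
    """
    R1 = class_covariance(class1_trials).matrix
    R2 = class_covariance(class2_trials).matrix
    M = R1.shape[0]
    if m < 1 or 2 * m > M:
        raise ValueError(f"m={m} filter pairs do not fit into {M} channels")
    Rc = R1 + R2
    evals_c, evecs_c = sla.eigh(Rc)
    if evals_c[0] < 1e-12:
        eps = 1e-10 * np.trace(Rc) / M
        warnings.warn(
            f"composite covariance is rank-deficient (min eigenvalue {evals_c[0]:.3e}); "
            f"regularizing with {eps:.3e} * I",
            RuntimeWarning,
            stacklevel=2,
        )
        Rc = Rc + eps * np.eye(M)
        evals_c, evecs_c = sla.eigh(Rc)
    whitener = evecs_c / np.sqrt(evals_c)  # columns scaled: P^T Rc P = I
    S1 = whitener.T @ R1 @ whitener
    evals, evecs = sla.eigh(S1)  # ascending
    pick = np.concatenate([np.arange(M - 1, M - 1 - m, -1), np.arange(0, m)])
    W = (whitener @ evecs[:, pick]).T
    return _sign_fix(W)


def global_filter(
    W_AE: np.ndarray, W_AF: np.ndarray, W_EF: np.ndarray, pair_names: tuple | None = None
) -> SpatialFilterBank:
    """Stack the three pairwise filters vertically: ``W = [W_AE; W_AF; W_EF]``."""
    mats = [np.atleast_2d(np.asarray(W, dtype=float)) for W in (W_AE, W_AF, W_EF)]
    widths = {Wm.shape[1] for Wm in mats}
    if len(widths) != 1:
        raise ValueError(f"pairwise filters have mismatched channel counts: {sorted(widths)}")
    if pair_names is None:
        pair_names = (("A", "E"), ("A", "F"), ("E", "F"))
    return SpatialFilterBank(
        pairwise=dict(zip(pair_names, mats)),
        global_matrix=np.vstack(mats),
        m=mats[0].shape[0] // 2,
    )


def extract_features(X: np.ndarray, bank: SpatialFilterBank | np.ndarray) -> np.ndarray:
    """Normalized log-variance features of the projected trial.

    ``f_p = log(var(Z_p) / sum_k var(Z_k))`` with ``Z = W X``; the
    normalization forces ``sum_p exp(f_p) = 1`` and cancels any global
    amplitude scale of the trial.
    """
    W = bank.global_matrix if isinstance(bank, SpatialFilterBank) else np.asarray(bank, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("trial must have at least 2 samples")
    Z = W @ X
    v = Z.var(axis=1)
    floor = np.finfo(float).tiny
    if np.any(v <= floor):
        warnings.warn("zero-variance projected row; flooring before log", RuntimeWarning, stacklevel=2)
        v = np.maximum(v, floor)
    return np.log(v / v.sum())


def channel_weight_scores(pairwise_filter: np.ndarray, min_max: bool = False) -> np.ndarray:
    """Per-channel discriminability scores of one pairwise CSP filter.

    The raw score of channel ``c`` is the 2-norm of the filter's ``c``-th
    column divided by the Frobenius norm of the whole filter, so the squared
    raw scores sum to one.  With ``min_max=True`` the scores are min-max
    rescaled into [0, 1] (apply after cross-subject averaging).
    """
    W = np.asarray(pairwise_filter, dtype=float)
    total = np.linalg.norm(W)
    if total == 0:
        raise ValueError("zero filter has no channel weights")
    scores = np.linalg.norm(W, axis=0) / total
    if min_max:
        scores = minmax_scores(scores)
    return scores


def minmax_scores(scores: np.ndarray) -> np.ndarray:
    """Min-max rescale scores into [0, 1]; constant input maps to zeros."""
    scores = np.asarray(scores, dtype=float)
    lo, hi = scores.min(), scores.max()
    if hi == lo:
        return np.zeros_like(scores)
    return (scores - lo) / (hi - lo)


def fit_ovo_bank(
    trials_by_class: Mapping[str, Sequence[np.ndarray]], m: int = 4
) -> SpatialFilterBank:
    """Fit all three pairwise filters of a 3-class problem and stack them.

    Class pairs are taken in sorted-label order, matching the (A/E, A/F,
    E/F) convention when labels sort as abduction < extension < flexion.
    """
    labels = sorted(trials_by_class)
    if len(labels) != 3:
        raise ValueError(f"one-versus-one bank expects 3 classes, got {labels}")
    pairs = [(labels[0], labels[1]), (labels[0], labels[2]), (labels[1], labels[2])]
    mats = [fit_pairwise_filter(trials_by_class[a], trials_by_class[b], m=m) for a, b in pairs]
    return global_filter(*mats, pair_names=tuple(pairs))
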