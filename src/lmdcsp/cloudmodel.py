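"""Cloud-model digital characteristics and product-function selection.

The cloud model summarizes a sample by three *digital characteristics*:
expectation ``Ex`` (central value), entropy ``En`` (randomness; for Gaussian
data a consistent estimator of the standard deviation, since
``E|x - mu| = sigma * sqrt(2/pi)``) and super-entropy ``He`` (dispersion of
the entropy itself).  Genuine EEG-derived product functions are more complex
than sifting artefacts, so their En and He are larger; the characteristics
therefore rank PFs as *effective* vs *false*.  In practice the first product
function of band-limited motor-imagery EEG is the effective one, and the
default selection rule hard-codes exactly that choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from lmdcsp.lmd import PFDecomposition
from lmdcsp.preprocess import crop_to_original


@dataclass(frozen=True)
class CloudDescriptor:
    """(Ex, En, He) characteristics of one signal of ``n`` cloud droplets."""

    ex: float
    en: float
    he: float
    n: int


def describe(signal: np.ndarray) -> CloudDescriptor:
    """Backward cloud transform: estimate (Ex, En, He) from a sample.

    ``Ex`` is the arithmetic mean, ``En = sqrt(pi/2) * mean|x - Ex|``, and
    ``He = sqrt(S - En^2)`` with ``S`` the second central moment (1/n
    normalization).  Finite samples can make ``S - En^2`` slightly negative;
    He is a dispersion and is clamped at zero.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("signal must be a 1-D vector of length >= 2")
    if not np.isfinite(x).all():
        raise ValueError("signal contains non-finite values")
    ex = float(np.mean(x))
    en = float(np.sqrt(np.pi / 2.0) * np.mean(np.abs(x - ex)))
    s = float(np.mean((x - ex) ** 2))
    he = float(np.sqrt(max(0.0, s - en**2)))
    return CloudDescriptor(ex=ex, en=en, he=he, n=x.size)


def _parse_rule(rule: str) -> tuple[str, int]:
    kind, _, arg = rule.partition(":")
    kind = kind.strip().lower()
    if kind not in ("fixed", "top"):
        raise ValueError(f"unknown selection rule {rule!r}; use 'fixed:<i>' or 'top:<m>'")
    try:
        value = int(arg)
    except ValueError as err:
        raise ValueError(f"selection rule {rule!r} needs an integer argument") from err
    if value < 1:
        raise ValueError("selection rule argument must be >= 1")
    return kind, value


def select_effective_pfs(
    decompositions: Sequence[PFDecomposition] | Sequence[Sequence[PFDecomposition]],
    rule: str = "fixed:1",
) -> tuple[int, ...]:
    """Choose which PF indices (1-based, PF1 first) count as effective.

    ``fixed:i`` returns ``{i}`` unconditionally — the standard choice for
    band-limited motor-imagery EEG is ``fixed:1``.  ``top:m`` ranks PF
    indices by their (En, He) descending lexicographic order, averaged over
    all supplied decompositions (run it on training data only), and keeps
    the best ``m``.  Selection is global so every channel contributes the
    same indices and the reconstructed matrix stays rectangular.
    """
    flat: list[PFDecomposition] = []
    for item in decompositions:
        if isinstance(item, PFDecomposition):
            flat.append(item)
        else:
            flat.extend(item)
    if not flat:
        raise ValueError("no decompositions supplied")
    n_common = min(d.n_pfs for d in flat)
    if n_common < 1:
        raise ValueError("every channel must have at least one PF")
    kind, value = _parse_rule(rule)
    if kind == "fixed":
        if value > n_common:
            raise ValueError(f"PF{value} requested but only {n_common} PFs are common to all channels")
        return (value,)
    if value > n_common:
        raise ValueError(f"top:{value} requested but only {n_common} PFs are common to all channels")
    mean_en = np.zeros(n_common)
    mean_he = np.zeros(n_common)
    for d in flat:
        for j in range(n_common):
            desc = describe(d.pfs[j])
            mean_en[j] += desc.en
            mean_he[j] += desc.he
    mean_en /= len(flat)
    mean_he /= len(flat)
    order = sorted(range(n_common), key=lambda j: (-mean_en[j], -mean_he[j], j))
    return tuple(sorted(j + 1 for j in order[:value]))


def reconstruct_matrix(
    decompositions: Sequence[PFDecomposition],
    selected: Sequence[int],
    n: int,
) -> np.ndarray:
    """Stack the selected, cropped PFs of each channel into a trial matrix.

    Rows are ordered channel-major: (ch1-PF_a, ch1-PF_b, ..., ch2-PF_a, ...),
    giving an ``(channels * len(selected)) x n`` matrix ready for CSP.
    ``selected`` uses 1-based PF indices and ``n`` is the pre-extension
    trial length.
    """
    selected = tuple(selected)
    if not selected:
        raise ValueError("selected PF index set must be non-empty")
    rows: list[np.ndarray] = []
    for ch, d in enumerate(decompositions):
        for idx in selected:
            if idx < 1 or idx > d.n_pfs:
                raise ValueError(f"channel {ch}: PF{idx} requested but only {d.n_pfs} available")
            pf = d.pfs[idx - 1]
            if pf.size != 3 * n:
                raise ValueError(
                    f"channel {ch}: PF length {pf.size} inconsistent with original length {n}"
                )
            rows.append(crop_to_original(pf, n))
    return np.vstack(rows)


def descriptor_table(
    decompositions: Mapping[int, Sequence[PFDecomposition]] | Sequence[Sequence[PFDecomposition]],
):
    """Long-format table of (trial, channel, pf_index, Ex, En, He) rows."""
    import pandas as pd

    if isinstance(decompositions, Mapping):
        items = decompositions.items()
    else:
        items = enumerate(decompositions)
    records = []
    for trial_id, per_channel in items:
        for ch, d in enumerate(per_channel):
            for j, pf in enumerate(d.pfs):
                desc = describe(pf)
                records.append(
                    {
                        "trial": trial_id,
                        "channel": ch,
                        "pf_index": j + 1,
                        "Ex": desc.ex,
                        "En": desc.en,
                        "He": desc.he,
                    }
                )
    return pd.DataFrame.from_records(records)
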