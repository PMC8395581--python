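"""Multi-objective grey wolf optimizer (MOGWO) for TWSVM hyperparameters.

The optimizer searches (c1, c2, lambda) to jointly maximize four
objectives: the mean recognition accuracy and the three per-class
recognition rates, all estimated by stratified cross-validation of the
one-versus-one twin-SVM.  Non-dominated solutions live in an external
archive pruned by objective-space grid crowding; alpha, beta and delta
leaders are drawn from the least crowded grid cells by roulette and steer
the pack with the classic encircling equations, whose exploration
coefficient ``a`` decays linearly from 2 to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from lmdcsp.twsvm import KernelConfig, ovo_predict, train_ovo

DEFAULT_BOUNDS = np.array([[0.01, 8.0], [0.01, 8.0], [0.001, 8.0]])


@dataclass(frozen=True)
class MOGWOConfig:
    n_wolves: int = 12
    max_iterations: int = 100
    archive_size: int = 10
    grid_inflation: float = 0.1
    leader_selection_pressure: float = 4.0
    grids_per_dim: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_wolves, self.max_iterations, self.grids_per_dim) < 1:
            raise ValueError("n_wolves, max_iterations and grids_per_dim must be positive")
        if self.archive_size < 3:
            raise ValueError("archive_size must be >= 3 (alpha, beta, delta leaders)")


@dataclass(frozen=True)
class ObjectiveVector:
    """Mean accuracy plus per-class recognition rates with their counts."""

    accuracy: float
    cr: tuple[float, ...]
    nc: tuple[int, ...] = ()
    ne: tuple[int, ...] = ()

    @classmethod
    def from_counts(cls, nc: Sequence[int], ne: Sequence[int]) -> "ObjectiveVector":
        nc = tuple(int(v) for v in nc)
        ne = tuple(int(v) for v in ne)
        totals = [c + e for c, e in zip(nc, ne)]
        if any(t == 0 for t in totals):
            raise ValueError("every class needs at least one evaluated sample")
        cr = tuple(c / t for c, t in zip(nc, totals))
        accuracy = sum(nc) / (sum(nc) + sum(ne))
        return cls(accuracy=accuracy, cr=cr, nc=nc, ne=ne)

    def as_array(self) -> np.ndarray:
        return np.array([self.accuracy, *self.cr])


@dataclass
class WolfState:
    position: np.ndarray
    objective: ObjectiveVector | None = None


def _to_array(v) -> np.ndarray:
    return v.as_array() if isinstance(v, ObjectiveVector) else np.asarray(v, dtype=float)


def dominates(u, v) -> bool:
    """Pareto dominance with all objectives maximized: ``u`` dominates ``v``
    iff it is nowhere worse and somewhere strictly better."""
    ua, va = _to_array(u), _to_array(v)
    if ua.shape != va.shape:
        raise ValueError("objective vectors have different dimensions")
    return bool(np.all(ua >= va) and np.any(ua > va))


@dataclass
class ArchiveMember:
    position: np.ndarray
    objective: ObjectiveVector | np.ndarray

    @property
    def values(self) -> np.ndarray:
        return _to_array(self.objective)


class ParetoArchive:
    """External archive of mutually non-dominated solutions with grid pruning."""

    def __init__(self, config: MOGWOConfig):
        self.config = config
        self.members: list[ArchiveMember] = []
        self._cells: list[tuple[int, ...]] = []

    def __len__(self) -> int:
        return len(self.members)

    def _rebuild_grid(self) -> None:
        if not self.members:
            self._cells = []
            return
        vals = np.array([m.values for m in self.members])
        lo, hi = vals.min(axis=0), vals.max(axis=0)
        span = hi - lo
        pad = self.config.grid_inflation * np.where(span > 0, span, 1.0) / 2.0
        lo, hi = lo - pad, hi + pad
        edges = [np.linspace(lo[d], hi[d], self.config.grids_per_dim + 1) for d in range(vals.shape[1])]
        cells = []
        for row in vals:
            idx = tuple(
                int(np.clip(np.searchsorted(edges[d], row[d], side="right") - 1, 0, self.config.grids_per_dim - 1))
                for d in range(len(row))
            )
            cells.append(idx)
        self._cells = cells

    def cell_counts(self) -> dict[tuple[int, ...], int]:
        counts: dict[tuple[int, ...], int] = {}
        for c in self._cells:
            counts[c] = counts.get(c, 0) + 1
        return counts

    def update(self, position: np.ndarray, objective: ObjectiveVector | np.ndarray, rng: np.random.Generator) -> bool:
        """Insert a candidate if no member dominates it; drop members it
        dominates; on overflow evict from the most crowded region (roulette
        weighted by cell occupancy).  Returns True if inserted."""
        cand = ArchiveMember(np.asarray(position, dtype=float).copy(), objective)
        cv = cand.values
        for m in self.members:
            if dominates(m.values, cv):
                return False
        self.members = [m for m in self.members if not dominates(cv, m.values)]
        self.members.append(cand)
        self._rebuild_grid()
        if len(self.members) > self.config.archive_size:
            counts = self.cell_counts()
            weights = np.array([counts[c] for c in self._cells], dtype=float)
            pick = rng.choice(len(self.members), p=weights / weights.sum())
            del self.members[pick]
            self._rebuild_grid()
        return True

    def select_leaders(self, rng: np.random.Generator) -> list[ArchiveMember]:
        """Alpha, beta, delta drawn from the least crowded cells: roulette
        over cells with weight ``count ** -pressure``, distinct members when
        the archive holds at least three."""
        if not self.members:
            raise ValueError("cannot select leaders from an empty archive")
        leaders: list[ArchiveMember] = []
        excluded: set[int] = set()
        for _ in range(3):
            avail = [i for i in range(len(self.members)) if i not in excluded]
            if not avail:
                avail = list(range(len(self.members)))
                excluded.clear()
            counts = self.cell_counts()
            w = np.array(
                [counts[self._cells[i]] ** (-self.config.leader_selection_pressure) for i in avail]
            )
            pick = avail[rng.choice(len(avail), p=w / w.sum())]
            leaders.append(self.members[pick])
            excluded.add(pick)
        return leaders


def update_positions(
    positions: np.ndarray,
    leaders: Sequence[np.ndarray],
    t: int,
    config: MOGWOConfig,
    rng: np.random.Generator,
    bounds: np.ndarray = DEFAULT_BOUNDS,
) -> np.ndarray:
    """One encircling step of the pack.

    For each wolf and each leader ``L``: ``D = |C * L - X|`` and candidate
    ``L - A * D`` with ``A = 2 a r1 - a``, ``C = 2 r2`` (fresh uniform
    ``r1``, ``r2`` per wolf/dimension/leader); the new position is the mean
    of the three candidates, clipped to the box.  ``a`` decays linearly
    from 2 (t = 0) to 0 (t = max_iterations)."""
    X = np.atleast_2d(np.asarray(positions, dtype=float))
    bounds = np.asarray(bounds, dtype=float)
    a = 2.0 * (1.0 - t / config.max_iterations)
    new = np.zeros_like(X)
    for leader in leaders:
        L = np.asarray(leader, dtype=float)
        r1 = rng.random(X.shape)
        r2 = rng.random(X.shape)
        A = 2.0 * a * r1 - a
        C = 2.0 * r2
        D = np.abs(C * L - X)
        new += L - A * D
    new /= len(leaders)
    return np.clip(new, bounds[:, 0], bounds[:, 1])


def stratified_fold_indices(y: Sequence, folds: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    from sklearn.model_selection import StratifiedKFold

    y = np.asarray(y)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros((len(y), 1)), y)]


def cv_objective(
    position: np.ndarray,
    X: np.ndarray,
    y: Sequence,
    fold_indices: Sequence[tuple[np.ndarray, np.ndarray]],
    kernel_kind: str = "gaussian",
) -> ObjectiveVector:
    """Cross-validated objectives of one (c1, c2, lambda) triple on a fixed
    feature table: pooled per-class correct/error counts over the folds."""
    c1, c2, lam = (float(v) for v in position)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = sorted(set(y.tolist()))
    nc = {c: 0 for c in classes}
    ne = {c: 0 for c in classes}
    for tr, te in fold_indices:
        by_class = {c: X[tr][y[tr] == c] for c in classes}
        models = train_ovo(by_class, c1, c2, KernelConfig(kind=kernel_kind, lam=lam))
        pred = ovo_predict(models, X[te])
        for true, hat in zip(y[te], pred):
            if hat == true:
                nc[true] += 1
            else:
                ne[true] += 1
    return ObjectiveVector.from_counts([nc[c] for c in classes], [ne[c] for c in classes])


def evaluate_objectives(
    position: np.ndarray,
    X: np.ndarray,
    y: Sequence,
    folds: int = 5,
    seed: int = 0,
    kernel_kind: str = "gaussian",
) -> ObjectiveVector:
    """Stratified k-fold evaluation of the OVO TWSVM at one hyperparameter
    triple (convenience wrapper building its own folds)."""
    return cv_objective(position, X, y, stratified_fold_indices(y, folds, seed), kernel_kind)


def choose_solution(archive: ParetoArchive) -> ArchiveMember:
    """Deterministic pick from the Pareto set: maximal accuracy, ties broken
    by the larger worst-class rate, then the smaller parameter norm."""
    if not archive.members:
        raise ValueError("empty archive")
    return min(
        archive.members,
        key=lambda m: (-m.values[0], -np.min(m.values[1:]) if len(m.values) > 1 else 0.0, np.linalg.norm(m.position)),
    )


def optimize_objective(
    objective_fn: Callable[[np.ndarray], ObjectiveVector | np.ndarray],
    bounds: np.ndarray = DEFAULT_BOUNDS,
    config: MOGWOConfig = MOGWOConfig(),
    cache_decimals: int = 6,
) -> tuple[ParetoArchive, ArchiveMember]:
    """Run the full MOGWO loop against an arbitrary vector objective.

    Evaluations are cached on positions rounded to ``cache_decimals`` so
    revisited points cost nothing; the whole run is deterministic under
    ``config.seed``.
    """
    bounds = np.asarray(bounds, dtype=float)
    rng = np.random.default_rng(config.seed)
    dim = bounds.shape[0]
    cache: dict[tuple, ObjectiveVector | np.ndarray] = {}

    def evaluate(pos: np.ndarray):
        key = tuple(np.round(pos, cache_decimals))
        if key not in cache:
            cache[key] = objective_fn(pos)
        return cache[key]

    positions = bounds[:, 0] + rng.random((config.n_wolves, dim)) * (bounds[:, 1] - bounds[:, 0])
    archive = ParetoArchive(config)
    for i in range(config.n_wolves):
        archive.update(positions[i], evaluate(positions[i]), rng)
    for t in range(config.max_iterations):
        leaders = [m.position for m in archive.select_leaders(rng)]
        positions = update_positions(positions, leaders, t, config, rng, bounds)
        for i in range(config.n_wolves):
            archive.update(positions[i], evaluate(positions[i]), rng)
    return archive, choose_solution(archive)


def optimize(
    X: np.ndarray,
    y: Sequence,
    config: MOGWOConfig = MOGWOConfig(),
    bounds: np.ndarray = DEFAULT_BOUNDS,
    folds: int = 5,
    kernel_kind: str = "gaussian",
) -> tuple[ParetoArchive, ArchiveMember]:
    """Tune (c1, c2, lambda) on a fixed feature table.

    The same fold assignment (seeded from the config) is reused for every
    evaluation so objective comparisons between positions are paired.
    """
    fold_indices = stratified_fold_indices(y, folds, config.seed)
    return optimize_objective(
        lambda p: cv_objective(p, X, y, fold_indices, kernel_kind), bounds, config
    )


def archive_table(archive: ParetoArchive, chosen: ArchiveMember | None = None):
    """Pareto set as a DataFrame: c1, c2, lambda, CR_i, Accuracy, chosen."""
    import pandas as pd

    rows = []
    for m in archive.members:
        vals = m.values
        row = {"c1": m.position[0], "c2": m.position[1], "lambda": m.position[2]}
        for i, cr in enumerate(vals[1:], start=1):
            row[f"CR{i}"] = cr
        row["Accuracy"] = vals[0]
        row["chosen"] = int(chosen is not None and m is chosen)
        rows.append(row)
    return pd.DataFrame(rows)
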