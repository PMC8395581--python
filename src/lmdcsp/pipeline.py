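"""End-to-end orchestration: preprocess -> LMD -> PF selection -> CSP ->
TWSVM -> MOGWO, with stratified cross-validation and evaluation metrics.

Two evaluation protocols are provided.  ``single`` reports the pooled
cross-validation performance of the hyperparameter triple the optimizer
itself selected — the classic tune-and-report protocol, optimistically
biased because the same folds pick and score the winner.  ``nested`` tunes
inside each outer training split and scores on the untouched outer test
fold, giving an unbiased estimate at higher cost.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from lmdcsp import cloudmodel, csp, mogwo
from lmdcsp.dataset import EEGTrialSet
from lmdcsp.lmd import LMDConfig, PFDecomposition, decompose
from lmdcsp.mogwo import DEFAULT_BOUNDS, ArchiveMember, MOGWOConfig, ObjectiveVector, ParetoArchive
from lmdcsp.preprocess import mirror_extend, preprocess_trial
from lmdcsp.twsvm import KernelConfig, ovo_predict, train_ovo

logger = logging.getLogger("lmdcsp.pipeline")


@dataclass(frozen=True)
class PipelineConfig:
    band: tuple[float, float] = (8.0, 30.0)
    filter_order: int = 5
    car: bool = True
    crop_seconds: tuple[float, float] | None = None
    lmd: LMDConfig = field(default_factory=LMDConfig)
    selection_rule: str = "fixed:1"
    csp_m: int = 4
    folds: int = 5
    kernel_kind: str = "gaussian"
    mogwo: MOGWOConfig = field(default_factory=MOGWOConfig)
    bounds: np.ndarray = field(default_factory=lambda: DEFAULT_BOUNDS.copy())
    mode: str = "single"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("single", "nested"):
            raise ValueError("mode must be 'single' or 'nested'")


@dataclass(frozen=True)
class EvaluationReport:
    """Pooled confusion counts and the derived per-class metrics."""

    confusion: np.ndarray  # rows = true class, columns = predicted
    class_names: tuple[str, ...]
    precision: np.ndarray
    recall: np.ndarray
    accuracy: float
    fold_assignments: np.ndarray | None = None
    chosen_parameters: tuple[float, float, float] | None = None

    @property
    def macro_precision(self) -> float:
        return float(np.mean(self.precision))

    @property
    def macro_recall(self) -> float:
        return float(np.mean(self.recall))

    def to_dict(self) -> dict:
        return {
            "class_names": list(self.class_names),
            "confusion": self.confusion.tolist(),
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "chosen_parameters": (
                list(self.chosen_parameters) if self.chosen_parameters is not None else None
            ),
        }


@dataclass
class PipelineResult:
    report: EvaluationReport
    archive: ParetoArchive | None
    chosen: ArchiveMember | None
    pareto: "object"  # pandas DataFrame
    fold_choices: list[tuple[float, float, float]] = field(default_factory=list)


def evaluation_metrics(
    y_true: Sequence, y_pred: Sequence, class_names: Sequence[str]
) -> EvaluationReport:
    """Confusion matrix, per-class precision/recall, and mean accuracy.

    Recall of class i equals the per-class recognition rate
    ``NC_i / (NC_i + NE_i)``; precision is the column-normalized diagonal.
    """
    from sklearn.metrics import confusion_matrix

    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred differ in length")
    class_names = tuple(class_names)
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        bad = set(arr.tolist()) - set(class_names)
        if bad:
            raise ValueError(f"{name} contains labels outside the class set: {sorted(bad)}")
    cm = confusion_matrix(y_true, y_pred, labels=list(class_names))
    row = cm.sum(axis=1)
    col = cm.sum(axis=0)
    diag = np.diag(cm)
    recall = np.divide(diag, row, out=np.zeros(len(class_names)), where=row > 0)
    precision = np.divide(diag, col, out=np.zeros(len(class_names)), where=col > 0)
    accuracy = float(diag.sum() / cm.sum())
    return EvaluationReport(
        confusion=cm,
        class_names=class_names,
        precision=precision,
        recall=recall,
        accuracy=accuracy,
    )


def decompose_trials(
    dataset: EEGTrialSet, config: PipelineConfig
) -> tuple[list[list[PFDecomposition]], int]:
    """Preprocess every trial and LMD-decompose every channel.

    Decomposition is per-trial and unsupervised, so it can be computed once
    up front without leaking information across cross-validation folds.
    With the default ``fixed:i`` selection rule only the first ``i`` product
    functions are ever used, so sifting stops there.
    """
    lmd_cfg = config.lmd
    rule_kind, _, rule_arg = config.selection_rule.partition(":")
    if rule_kind == "fixed":
        lmd_cfg = replace(lmd_cfg, max_pfs=min(lmd_cfg.max_pfs, int(rule_arg)))
    decomps: list[list[PFDecomposition]] = []
    n_samples = None
    for idx, trial in enumerate(dataset.trials):
        t0 = time.perf_counter()
        try:
            prep = preprocess_trial(
                trial,
                low=config.band[0],
                high=config.band[1],
                order=config.filter_order,
                car=config.car,
                crop_seconds=config.crop_seconds,
            )
            n_samples = prep.n_samples
            per_channel = [
                decompose(mirror_extend(prep.data[ch]), lmd_cfg)
                for ch in range(prep.n_channels)
            ]
        except Exception as err:  # surface the failing stage and trial
            raise RuntimeError(f"preprocess/LMD failed on trial {idx} ({trial.label})") from err
        decomps.append(per_channel)
        logger.debug("trial %d decomposed in %.3f s", idx, time.perf_counter() - t0)
    return decomps, n_samples


def _fold_features(
    decomps: list[list[PFDecomposition]],
    labels: np.ndarray,
    n_samples: int,
    train_idx: np.ndarray,
    config: PipelineConfig,
    matrix_cache: dict,
) -> tuple[np.ndarray, tuple[int, ...]]:
    """Select PFs and fit CSP on the training trials only, then extract
    features for *all* trials with that bank.  Returns the feature table
    and the selected PF indices."""
    selected = cloudmodel.select_effective_pfs(
        [decomps[i] for i in train_idx], rule=config.selection_rule
    )
    if selected not in matrix_cache:
        matrix_cache[selected] = [
            cloudmodel.reconstruct_matrix(per_channel, selected, n_samples)
            for per_channel in decomps
        ]
    matrices = matrix_cache[selected]
    by_class: dict[str, list[np.ndarray]] = {}
    for i in train_idx:
        by_class.setdefault(labels[i], []).append(matrices[i])
    bank = csp.fit_ovo_bank(by_class, m=config.csp_m)
    feats = np.vstack([csp.extract_features(X, bank) for X in matrices])
    return feats, selected


def _pooled_cv(
    feats_per_fold: list[np.ndarray],
    fold_indices: list[tuple[np.ndarray, np.ndarray]],
    labels: np.ndarray,
    classes: list[str],
    position: np.ndarray,
    kernel_kind: str,
) -> tuple[ObjectiveVector, np.ndarray]:
    """Train/predict each fold at one hyperparameter triple; returns pooled
    objectives and the full prediction vector (aligned with ``labels``)."""
    c1, c2, lam = (float(v) for v in position)
    kern = KernelConfig(kind=kernel_kind, lam=lam)
    nc = {c: 0 for c in classes}
    ne = {c: 0 for c in classes}
    y_pred = np.empty(len(labels), dtype=object)
    for (tr, te), feats in zip(fold_indices, feats_per_fold):
        by_class = {c: feats[tr][labels[tr] == c] for c in classes}
        models = train_ovo(by_class, c1, c2, kern)
        pred = ovo_predict(models, feats[te])
        for j, p in zip(te, pred):
            y_pred[j] = p
            if p == labels[j]:
                nc[labels[j]] += 1
            else:
                ne[labels[j]] += 1
    obj = ObjectiveVector.from_counts([nc[c] for c in classes], [ne[c] for c in classes])
    return obj, y_pred


def run(dataset: EEGTrialSet, config: PipelineConfig = PipelineConfig()) -> PipelineResult:
    """Execute the full decoding chain on one subject's trial set.

    PF selection and CSP filters are always fitted inside the training
    split of each fold; the optimizer then tunes (c1, c2, lambda) on the
    resulting per-fold feature tables.
    """
    labels = dataset.labels
    classes = sorted(set(labels.tolist()))
    decomps, n_samples = decompose_trials(dataset, config)
    matrix_cache: dict = {}
    fold_indices = mogwo.stratified_fold_indices(labels, config.folds, config.seed)
    fold_of = np.empty(len(labels), dtype=int)
    for f, (_, te) in enumerate(fold_indices):
        fold_of[te] = f

    if config.mode == "single":
        feats_per_fold = [
            _fold_features(decomps, labels, n_samples, tr, config, matrix_cache)[0]
            for tr, _ in fold_indices
        ]

        def objective(position: np.ndarray) -> ObjectiveVector:
            return _pooled_cv(feats_per_fold, fold_indices, labels, classes, position, config.kernel_kind)[0]

        mog_cfg = replace(config.mogwo, seed=config.seed)
        archive, chosen = mogwo.optimize_objective(objective, config.bounds, mog_cfg)
        _, y_pred = _pooled_cv(
            feats_per_fold, fold_indices, labels, classes, chosen.position, config.kernel_kind
        )
        report = evaluation_metrics(labels, y_pred, classes)
        report = replace(
            report,
            fold_assignments=fold_of,
            chosen_parameters=tuple(float(v) for v in chosen.position),
        )
        return PipelineResult(
            report=report,
            archive=archive,
            chosen=chosen,
            pareto=mogwo.archive_table(archive, chosen),
            fold_choices=[tuple(float(v) for v in chosen.position)],
        )

    # nested: tune on inner folds of each outer training split, score once
    # on the outer test fold
    y_pred = np.empty(len(labels), dtype=object)
    fold_choices: list[tuple[float, float, float]] = []
    archive = chosen = None
    for f, (tr, te) in enumerate(fold_indices):
        inner_labels = labels[tr]
        inner_folds_n = min(config.folds, min(np.bincount(np.searchsorted(classes, inner_labels))))
        inner_indices = mogwo.stratified_fold_indices(
            inner_labels, inner_folds_n, config.seed + 1000 + f
        )
        inner_feats = []
        for itr, _ in inner_indices:
            feats, _sel = _fold_features(
                decomps, labels, n_samples, tr[itr], config, matrix_cache
            )
            inner_feats.append(feats[tr])

        def inner_objective(position: np.ndarray) -> ObjectiveVector:
            return _pooled_cv(
                inner_feats, inner_indices, inner_labels, classes, position, config.kernel_kind
            )[0]

        mog_cfg = replace(config.mogwo, seed=config.seed + f)
        archive, chosen = mogwo.optimize_objective(inner_objective, config.bounds, mog_cfg)
        fold_choices.append(tuple(float(v) for v in chosen.position))
        feats, _sel = _fold_features(decomps, labels, n_samples, tr, config, matrix_cache)
        c1, c2, lam = chosen.position
        models = train_ovo(
            {c: feats[tr][labels[tr] == c] for c in classes},
            float(c1),
            float(c2),
            KernelConfig(kind=config.kernel_kind, lam=float(lam)),
        )
        y_pred[te] = ovo_predict(models, feats[te])
        logger.info("outer fold %d: chose %s", f, fold_choices[-1])
    report = evaluation_metrics(labels, y_pred, classes)
    report = replace(report, fold_assignments=fold_of, chosen_parameters=fold_choices[-1])
    return PipelineResult(
        report=report,
        archive=archive,
        chosen=chosen,
        pareto=mogwo.archive_table(archive, chosen) if archive is not None else None,
        fold_choices=fold_choices,
    )
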