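"""Kernel twin support vector machine (TWSVM) with one-versus-one voting.

A TWSVM fits two nonparallel hyperplanes in kernel space,
``K(x^T, C^T) w_i + b_i = 0``: the first passes close to class-1 samples
while staying at least unit distance from class 2 (slack-penalized by
``c1``), the second symmetrically for class 2.  Each hyperplane comes from a
small box-constrained dual quadratic program; a new sample is assigned to
the class whose hyperplane lies closer.  Multiclass decisions combine the
three pairwise machines by majority vote.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist


@dataclass(frozen=True)
class KernelConfig:
    """Kernel choice: ``linear`` (``X Y^T``) or ``gaussian`` with width
    ``lam``, ``K(x, y) = exp(-||x - y||^2 / (2 lam^2))``."""

    kind: str = "gaussian"
    lam: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "gaussian"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "gaussian" and not self.lam > 0:
            raise ValueError("gaussian kernel width lam must be positive")


def kernel_matrix(X: np.ndarray, Y: np.ndarray, config: KernelConfig) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError("feature dimensions do not match")
    if config.kind == "linear":
        return X @ Y.T
    d2 = cdist(X, Y, metric="sqeuclidean")
    return np.exp(-d2 / (2.0 * config.lam**2))


def _box_qp(M: np.ndarray, q: np.ndarray, ub: float, tol: float = 1e-10, max_iter: int = 300) -> np.ndarray:
    """Minimize ``0.5 x^T M x + q^T x`` subject to ``0 <= x <= ub``.

    Projected-Newton active-set iteration from a deterministic start at 0;
    falls back to L-BFGS-B if the KKT residual has not converged.  ``M``
    must be symmetric positive semidefinite.
    """
    n = len(q)
    ubv = np.full(n, float(ub))
    x = np.zeros(n)
    scale = max(1.0, float(np.abs(np.diag(M)).max()))
    ridge = 1e-12 * scale

    def objective(z: np.ndarray) -> float:
        return float(0.5 * z @ M @ z + q @ z)

    def kkt_residual(x: np.ndarray) -> float:
        g = M @ x + q
        r = np.where(x <= 1e-12, np.minimum(g, 0.0), np.where(x >= ubv - 1e-12, np.maximum(g, 0.0), g))
        return float(np.abs(r).max(initial=0.0))

    for _ in range(max_iter):
        g = M @ x + q
        at_lo = (x <= 1e-12) & (g >= 0)
        at_hi = (x >= ubv - 1e-12) & (g <= 0)
        free = ~(at_lo | at_hi)
        if not free.any():
            break
        gf = g[free]
        if np.abs(gf).max() < tol * scale:
            break
        nf = int(free.sum())
        Mff = M[np.ix_(free, free)]
        try:
            df = -np.linalg.solve(Mff + ridge * np.eye(nf), gf)
        except np.linalg.LinAlgError:
            df = -gf / scale
        if df @ gf >= 0:  # numerical non-descent: fall back to gradient
            df = -gf / scale
        d = np.zeros(n)
        d[free] = df
        # backtracking search along the projection arc: clipping at the box
        # replaces the truncated line step, so bound-hugging components
        # cannot stall the iteration
        f0 = objective(x)
        alpha = 1.0
        accepted = False
        for _ls in range(60):
            xt = np.clip(x + alpha * d, 0.0, ubv)
            if objective(xt) <= f0 + 1e-4 * float(g @ (xt - x)):
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            break
        x = xt

    if kkt_residual(x) > 1e-6 * scale:
        from scipy.optimize import minimize

        res = minimize(
            lambda z: 0.5 * z @ M @ z + q @ z,
            x,
            jac=lambda z: M @ z + q,
            bounds=[(0.0, ub)] * n,
            method="L-BFGS-B",
            options={"ftol": 1e-16, "gtol": 1e-12, "maxiter": 2000},
        )
        x = np.clip(res.x, 0.0, ub)
    return x


@dataclass(frozen=True)
class TWSVMModel:
    """Fitted twin-SVM pair for one binary task.

    ``w1``/``b1`` define the hyperplane hugging class 1 (label ``classes[0]``,
    the ``A`` samples), ``w2``/``b2`` the one hugging class 2.  Weights live
    in the kernel expansion over the stacked training data ``C``.
    """

    w1: np.ndarray
    b1: float
    w2: np.ndarray
    b2: float
    c1: float
    c2: float
    kernel: KernelConfig
    support_data: np.ndarray
    classes: tuple[str, str]
    dual_objectives: tuple[float, float] = (np.nan, np.nan)
    normalized_distance: bool = True


def train_binary(
    A: np.ndarray,
    B: np.ndarray,
    c1: float,
    c2: float,
    kernel: KernelConfig,
    labels: tuple[str, str] = ("1", "2"),
    normalized_distance: bool = True,
) -> TWSVMModel:
    """Fit the two hyperplanes by solving the Wolfe duals of both primal
    problems.

    With ``H = [K(A, C^T), e]`` and ``G = [K(B, C^T), e]``, hyperplane 1
    solves ``max e^T a - 0.5 a^T G (H^T H)^{-1} G^T a`` over ``0 <= a <= c1``
    and recovers ``[w1; b1] = -(H^T H + eps I)^{-1} G^T a``; hyperplane 2 is
    the mirror image.  The Tikhonov term ``eps`` (1e-7, trace-scaled) keeps
    the augmented Gram matrices invertible.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[0] < 1 or B.shape[0] < 1:
        raise ValueError("both classes need at least one sample")
    if not (c1 > 0 and c2 > 0):
        raise ValueError("penalty parameters c1, c2 must be positive")
    C = np.vstack([A, B])
    m1, m2 = A.shape[0], B.shape[0]
    H = np.hstack([kernel_matrix(A, C, kernel), np.ones((m1, 1))])
    G = np.hstack([kernel_matrix(B, C, kernel), np.ones((m2, 1))])
    dim = C.shape[0] + 1

    def dual_pieces(Hm: np.ndarray, Gm: np.ndarray):
        HtH = Hm.T @ Hm
        eps = 1e-7 * np.trace(HtH) / dim
        P = np.linalg.solve(HtH + eps * np.eye(dim), Gm.T)
        Mdual = Gm @ P
        Mdual = 0.5 * (Mdual + Mdual.T)
        return P, Mdual

    P1, M1 = dual_pieces(H, G)
    e2 = np.ones(m2)
    alpha = _box_qp(M1, -e2, c1)
    u1 = -P1 @ alpha
    obj1 = float(e2 @ alpha - 0.5 * alpha @ M1 @ alpha)

    # the second problem mirrors the first with the same constraint sign
    # (-(K(A,C')w2 + e b2) >= e - xi), so its recovery also carries a minus;
    # predictions only use |K w + b| and are unaffected by the convention
    P2, M2 = dual_pieces(G, H)
    e1 = np.ones(m1)
    gamma = _box_qp(M2, -e1, c2)
    u2 = -P2 @ gamma
    obj2 = float(e1 @ gamma - 0.5 * gamma @ M2 @ gamma)

    return TWSVMModel(
        w1=u1[:-1],
        b1=float(u1[-1]),
        w2=u2[:-1],
        b2=float(u2[-1]),
        c1=float(c1),
        c2=float(c2),
        kernel=kernel,
        support_data=C,
        classes=labels,
        dual_objectives=(obj1, obj2),
        normalized_distance=normalized_distance,
    )


def decision_values(model: TWSVMModel, x: np.ndarray) -> np.ndarray:
    """Distances of sample(s) to both hyperplanes, shape ``(n, 2)``.

    ``d_i = |K(x^T, C^T) w_i + b_i| / ||w_i||`` (perpendicular convention)
    unless the model was trained with ``normalized_distance=False``, in
    which case the raw absolute values are returned.
    """
    X = np.atleast_2d(np.asarray(x, dtype=float))
    k = kernel_matrix(X, model.support_data, model.kernel)
    n1, n2 = np.linalg.norm(model.w1), np.linalg.norm(model.w2)
    if n1 == 0 or n2 == 0:
        raise ValueError("degenerate model: zero hyperplane normal")
    d1 = np.abs(k @ model.w1 + model.b1)
    d2 = np.abs(k @ model.w2 + model.b2)
    if model.normalized_distance:
        d1, d2 = d1 / n1, d2 / n2
    return np.column_stack([d1, d2])


def predict_binary(model: TWSVMModel, x: np.ndarray) -> np.ndarray:
    """Label of the nearer hyperplane for each sample."""
    d = decision_values(model, x)
    return np.where(d[:, 0] <= d[:, 1], model.classes[0], model.classes[1])


def ovo_predict(models: Mapping[tuple[str, str], TWSVMModel], x: np.ndarray) -> np.ndarray:
    """Majority vote over the pairwise machines.

    Circular three-way ties are broken by the smallest total perpendicular
    distance of the sample to each candidate class's hyperplanes; any
    remaining tie falls back to sorted label order for determinism.
    """
    X = np.atleast_2d(np.asarray(x, dtype=float))
    classes = sorted({c for pair in models for c in pair})
    votes = {c: np.zeros(X.shape[0], dtype=int) for c in classes}
    dist_sum = {c: np.zeros(X.shape[0]) for c in classes}
    count = {c: 0 for c in classes}
    for pair, model in models.items():
        d = decision_values(model, X)
        pred_first = d[:, 0] <= d[:, 1]
        a, b = model.classes
        votes[a] += pred_first
        votes[b] += ~pred_first
        dist_sum[a] += d[:, 0]
        dist_sum[b] += d[:, 1]
        count[a] += 1
        count[b] += 1
    out = np.empty(X.shape[0], dtype=object)
    for i in range(X.shape[0]):
        best = max(votes[c][i] for c in classes)
        tied = [c for c in classes if votes[c][i] == best]
        if len(tied) > 1:
            tied.sort(key=lambda c: (dist_sum[c][i] / max(count[c], 1), c))
        out[i] = tied[0]
    return out


def train_ovo(
    features_by_class: Mapping[str, np.ndarray],
    c1: float,
    c2: float,
    kernel: KernelConfig,
    shared_parameters: bool = True,
    per_pair: Mapping[tuple[str, str], tuple[float, float, float]] | None = None,
) -> dict[tuple[str, str], TWSVMModel]:
    """Train all pairwise machines of a multiclass problem.

    By default one (c1, c2, lambda) triple is shared across the three
    binary tasks; pass ``per_pair`` (and ``shared_parameters=False``) to
    give each pair its own triple.
    """
    labels = sorted(features_by_class)
    models: dict[tuple[str, str], TWSVMModel] = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            if shared_parameters or per_pair is None or (a, b) not in per_pair:
                cc1, cc2, kern = c1, c2, kernel
            else:
                cc1, cc2, lam = per_pair[(a, b)]
                kern = KernelConfig(kind=kernel.kind, lam=lam)
            models[(a, b)] = train_binary(
                features_by_class[a], features_by_class[b], cc1, cc2, kern, labels=(a, b)
            )
    return models
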