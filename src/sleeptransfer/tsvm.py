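"""Transfer support vector machine (linear, binary) and one-vs-rest wrapper.

The transfer SVM augments the soft-margin SVM objective with a pull toward
a source-domain weight vector ``w_s``::

    min_{w_t, b_t, xi}  1/2 ||w_t||^2 + C_t sum_i xi_i + mu ||w_t - w_s||^2
    s.t.  y_i (w_t . x_i + b_t) >= 1 - xi_i,   xi_i >= 0

``mu >= 0`` sets the transfer strength: ``mu = 0`` recovers the classic
SVM, ``mu -> inf`` forces ``w_t -> w_s``. Eliminating the primal variables
gives the dual quadratic program over multipliers ``beta``::

    min_beta  1/(2(2mu+1)) sum_ij beta_i beta_j y_i y_j (x_i . x_j)
              + sum_i (2 mu y_i (x_i . w_s)/(2mu+1) - 1) beta_i
              - mu/(2mu+1) ||w_s||^2
    s.t.      0 <= beta_i <= C_t,   sum_i beta_i y_i = 0

solved here by an SMO-style maximal-violating-pair method on the Gram
matrix (training sets are small: a handful of labeled target epochs). The
primal weights are recovered as

    w_t = (2 mu w_s + sum_i beta_i y_i x_i) / (2 mu + 1)

and the bias from margin support vectors (``beta`` strictly inside
``(0, C_t)``): ``b_t = mean_j (y_j - w_t . x_j)``, averaged over all such
points for stability. If no multiplier is interior, the midpoint between
the hulls along ``w_t`` is used and a warning logged.

Only the linear kernel is implemented: the transfer term couples ``w_s``
and the data in input space, which has no printed kernelized counterpart.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

log = logging.getLogger(__name__)

#: default transfer-weight candidates for validation-based selection
DEFAULT_MU_GRID: tuple[float, ...] = (0.001, 0.005, 0.1, 0.3, 0.5, 0.7, 0.9, 0.99)


@dataclass
class LabeledDataset:
    """Feature matrix X (n, d) with binary labels y in {-1, +1}."""

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.ndim != 2 or self.y.ndim != 1 or self.X.shape[0] != self.y.size:
            raise ValueError("X must be (n, d) and y length n")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("features must be finite")
        if not np.all(np.isin(self.y, (-1.0, 1.0))):
            raise ValueError("labels must be -1 or +1")

    def both_classes(self) -> bool:
        return bool(np.any(self.y > 0) and np.any(self.y < 0))


@dataclass
class SourceModel:
    """Linear classifier transferred from the source domain."""

    w_s: np.ndarray
    b_s: float = 0.0

    def __post_init__(self) -> None:
        self.w_s = np.asarray(self.w_s, dtype=float)
        if not np.all(np.isfinite(self.w_s)) or not np.isfinite(self.b_s):
            raise ValueError("source model must be finite")


@dataclass
class TsvmConfig:
    C_t: float = 1.0
    mu: float = 0.0
    qp_tolerance: float = 1e-10
    sv_margin_tolerance: float = 1e-6  # interior means beta in (eps*C, (1-eps)*C)
    mu_grid: tuple[float, ...] = DEFAULT_MU_GRID
    max_iter: int = 200_000

    def __post_init__(self) -> None:
        if self.C_t <= 0:
            raise ValueError("C_t must be positive")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")


@dataclass
class DualSolution:
    """Lagrange multipliers solving the dual QP, with its objective value."""

    beta: np.ndarray
    objective: float
    kkt_gap: float
    n_iter: int


@dataclass
class TargetModel:
    """Recovered target-domain linear classifier."""

    w_t: np.ndarray
    b_t: float
    support_indices: tuple[int, ...] = ()
    mu: float = 0.0
    C_t: float = 1.0


# ---------------------------------------------------------------------------
# Dual QP
# ---------------------------------------------------------------------------


def _dual_matrices(
    data: LabeledDataset, source: SourceModel, cfg: TsvmConfig
) -> tuple[np.ndarray, np.ndarray, float]:
    """Q, p and the additive constant of the dual objective."""
    denom = 2.0 * cfg.mu + 1.0
    K = data.X @ data.X.T
    Q = (data.y[:, None] * data.y[None, :]) * K / denom
    p = (2.0 * cfg.mu / denom) * data.y * (data.X @ source.w_s) - 1.0
    const = -(cfg.mu / denom) * float(source.w_s @ source.w_s)
    return Q, p, const


def _smo(
    Q: np.ndarray,
    p: np.ndarray,
    y: np.ndarray,
    C: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, float, int]:
    """Maximal-violating-pair SMO for min 1/2 b'Qb + p'b, 0<=b<=C, y'b=0."""
    n = p.size
    beta = np.zeros(n)
    grad = p.copy()
    gap = np.inf
    for it in range(1, max_iter + 1):
        yg = -y * grad
        up = ((y > 0) & (beta < C)) | ((y < 0) & (beta > 0))
        low = ((y > 0) & (beta > 0)) | ((y < 0) & (beta < C))
        if not up.any() or not low.any():
            gap = 0.0
            return beta, gap, it
        i = int(np.argmax(np.where(up, yg, -np.inf)))
        j = int(np.argmin(np.where(low, yg, np.inf)))
        gap = yg[i] - yg[j]
        if gap <= tol:
            return beta, gap, it
        a = Q[i, i] + Q[j, j] - 2.0 * y[i] * y[j] * Q[i, j]
        t = gap / max(a, 1e-12)
        # box limits along the feasible direction (+y_i at i, -y_j at j)
        t_max_i = C - beta[i] if y[i] > 0 else beta[i]
        t_max_j = beta[j] if y[j] > 0 else C - beta[j]
        t = min(t, t_max_i, t_max_j)
        beta[i] = min(max(beta[i] + y[i] * t, 0.0), C)
        beta[j] = min(max(beta[j] - y[j] * t, 0.0), C)
        grad += t * (y[i] * Q[:, i] - y[j] * Q[:, j])
        if it % 4096 == 0:  # shed accumulated round-off
            grad = Q @ beta + p
    log.warning("SMO reached max_iter=%d with KKT gap %.3e > tol %.3e", max_iter, gap, tol)
    return beta, gap, max_iter


def solve_dual(
    data: LabeledDataset, source: SourceModel, cfg: TsvmConfig
) -> DualSolution:
    """Solve the transfer-SVM dual QP for the Lagrange multipliers.

    The reported objective is the full dual minimand including the
    ``-mu/(2mu+1) ||w_s||^2`` constant, so that (by strong duality) it is
    the negative of the optimal primal objective.
    """
    if not data.both_classes():
        raise ValueError("training data must contain both classes")
    if source.w_s.size != data.X.shape[1]:
        raise ValueError(
            f"source weight dimension {source.w_s.size} != feature dimension {data.X.shape[1]}"
        )
    Q, p, const = _dual_matrices(data, source, cfg)
    beta, gap, n_iter = _smo(Q, p, data.y, cfg.C_t, cfg.qp_tolerance, cfg.max_iter)
    obj = 0.5 * beta @ Q @ beta + p @ beta + const
    return DualSolution(beta=beta, objective=float(obj), kkt_gap=float(gap), n_iter=n_iter)


def dual_objective(
    beta: np.ndarray, data: LabeledDataset, source: SourceModel, cfg: TsvmConfig
) -> float:
    """Evaluate the dual minimand at an arbitrary feasible ``beta``."""
    Q, p, const = _dual_matrices(data, source, cfg)
    beta = np.asarray(beta, dtype=float)
    return float(0.5 * beta @ Q @ beta + p @ beta + const)


def primal_objective(
    model: TargetModel, data: LabeledDataset, source: SourceModel
) -> float:
    """Primal objective at (w_t, b_t) with hinge slacks."""
    margins = data.y * (data.X @ model.w_t + model.b_t)
    xi = np.maximum(0.0, 1.0 - margins)
    diff = model.w_t - source.w_s
    return float(
        0.5 * model.w_t @ model.w_t + model.C_t * xi.sum() + model.mu * (diff @ diff)
    )


# ---------------------------------------------------------------------------
# Primal recovery
# ---------------------------------------------------------------------------


def primal_from_dual(
    sol: DualSolution, data: LabeledDataset, source: SourceModel, cfg: TsvmConfig
) -> np.ndarray:
    """w_t = (2 mu w_s + sum_i beta_i y_i x_i) / (2 mu + 1)."""
    if source.w_s.size != data.X.shape[1]:
        raise ValueError("source weight / feature dimension mismatch")
    sv_part = data.X.T @ (sol.beta * data.y)
    return (2.0 * cfg.mu * source.w_s + sv_part) / (2.0 * cfg.mu + 1.0)


def bias_from_margin_sv(
    sol: DualSolution, data: LabeledDataset, w_t: np.ndarray, cfg: TsvmConfig
) -> float:
    """Bias from margin support vectors (multipliers interior to (0, C_t)).

    Any point with ``beta_j`` strictly inside the box sits exactly on its
    margin, so ``b_t = y_j - w_t . x_j``; averaging over all such points is
    more stable than picking one. With no interior multiplier the bias is
    set midway between the closest opposing projections onto ``w_t`` and a
    warning is logged.
    """
    eps = cfg.sv_margin_tolerance * cfg.C_t
    interior = (sol.beta > eps) & (sol.beta < cfg.C_t - eps)
    scores = data.X @ w_t
    if interior.any():
        return float(np.mean(data.y[interior] - scores[interior]))
    pos = scores[data.y > 0]
    neg = scores[data.y < 0]
    log.warning("no margin support vector in (0, C_t); using midpoint bias fallback")
    return float(-(neg.max() + pos.min()) / 2.0)


def decide(model: TargetModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Classify points: returns ``(labels in {-1,+1}, raw scores g)``.

    ``g(x) = w_t . x + b_t``; a point exactly on the hyperplane (g == 0)
    is assigned +1.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.w_t.size:
        raise ValueError("feature dimension mismatch")
    g = X @ model.w_t + model.b_t
    labels = np.where(g >= 0.0, 1.0, -1.0)
    return labels, g


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def fit_tsvm(
    data: LabeledDataset, source: SourceModel, cfg: TsvmConfig
) -> TargetModel:
    """Solve the dual, recover the primal weights and estimate the bias."""
    sol = solve_dual(data, source, cfg)
    w_t = primal_from_dual(sol, data, source, cfg)
    b_t = bias_from_margin_sv(sol, data, w_t, cfg)
    eps = cfg.sv_margin_tolerance * cfg.C_t
    support = tuple(int(i) for i in np.flatnonzero(sol.beta > eps))
    return TargetModel(w_t=w_t, b_t=b_t, support_indices=support, mu=cfg.mu, C_t=cfg.C_t)


def fit_svm(data: LabeledDataset, cfg: TsvmConfig) -> TargetModel:
    """Classic soft-margin linear SVM: the transfer fit with w_s = 0, mu = 0."""
    zero = SourceModel(w_s=np.zeros(data.X.shape[1]))
    return fit_tsvm(data, zero, replace(cfg, mu=0.0))


def select_mu(
    data_train: LabeledDataset,
    data_val: LabeledDataset,
    source: SourceModel,
    cfg: TsvmConfig,
) -> float:
    """Pick the transfer weight from ``cfg.mu_grid`` by validation accuracy.

    Ties break toward the smaller mu (weaker transfer). Deterministic.
    """
    best_mu, best_acc = None, -1.0
    for mu in sorted(cfg.mu_grid):
        model = fit_tsvm(data_train, source, replace(cfg, mu=mu))
        labels, _ = decide(model, data_val.X)
        acc = float(np.mean(labels == data_val.y))
        if acc > best_acc + 1e-12:
            best_mu, best_acc = mu, acc
    assert best_mu is not None
    return best_mu


# ---------------------------------------------------------------------------
# Standardization and one-vs-rest multiclass
# ---------------------------------------------------------------------------


@dataclass
class Standardizer:
    """Per-feature z-scoring; fit on source-domain data, applied to both domains."""

    mean: np.ndarray = field(default_factory=lambda: np.zeros(0))
    scale: np.ndarray = field(default_factory=lambda: np.ones(0))

    def fit(self, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        self.mean = X.mean(axis=0)
        sd = X.std(axis=0)
        self.scale = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.scale


@dataclass
class MulticlassModel:
    """One-vs-rest bundle of binary linear models; predicts by argmax score."""

    classes: tuple[str, ...]
    models: dict[str, TargetModel]

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.column_stack([decide(self.models[c], X)[1] for c in self.classes])

    def predict(self, X: np.ndarray) -> list[str]:
        scores = self.decision_scores(X)
        idx = np.argmax(scores, axis=1)  # ties -> first class in `classes`
        return [self.classes[i] for i in idx]


def _ordered_classes(labels: Sequence[str]) -> tuple[str, ...]:
    from .stages import STAGES

    uniq = sorted(set(labels))
    if all(u in STAGES for u in uniq):
        uniq = [s for s in STAGES if s in uniq]
    return tuple(uniq)


def fit_one_vs_rest(
    X: np.ndarray,
    labels: Sequence[str],
    sources: Mapping[str, SourceModel] | None,
    cfg: TsvmConfig,
) -> MulticlassModel:
    """Fit one binary (T)SVM per class against the rest.

    ``sources`` maps class name to its transferred source model; ``None``
    (or a missing class) means no transfer for that class (w_s = 0 — with
    ``cfg.mu = 0`` this is the plain one-vs-rest SVM).
    """
    X = np.asarray(X, dtype=float)
    classes = _ordered_classes(labels)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    y_arr = np.asarray(labels)
    models: dict[str, TargetModel] = {}
    for c in classes:
        yb = np.where(y_arr == c, 1.0, -1.0)
        data = LabeledDataset(X=X, y=yb)
        src = (sources or {}).get(c) or SourceModel(w_s=np.zeros(X.shape[1]))
        models[c] = fit_tsvm(data, src, cfg)
    return MulticlassModel(classes=classes, models=models)


def fit_source_models(
    X: np.ndarray, labels: Sequence[str], cfg: TsvmConfig
) -> dict[str, SourceModel]:
    """Train per-class source models: standard one-vs-rest SVM (mu = 0)."""
    ovr = fit_one_vs_rest(X, labels, None, replace(cfg, mu=0.0))
    return {c: SourceModel(w_s=m.w_t, b_s=m.b_t) for c, m in ovr.models.items()}


def save_model(
    path,
    model: MulticlassModel,
    standardizer: Standardizer | None = None,
    feature_names: Sequence[str] | None = None,
) -> None:
    """Serialize a one-vs-rest model as JSON (weights, bias, mu, C_t,
    feature ordering and standardization constants)."""
    import json

    doc = {
        "classes": list(model.classes),
        "models": {
            c: {"w_t": m.w_t.tolist(), "b_t": m.b_t, "mu": m.mu, "C_t": m.C_t}
            for c, m in model.models.items()
        },
        "feature_names": list(feature_names) if feature_names is not None else None,
        "standardizer": None
        if standardizer is None
        else {"mean": standardizer.mean.tolist(), "scale": standardizer.scale.tolist()},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)


def load_model(path) -> tuple[MulticlassModel, Standardizer | None, list[str] | None]:
    """Inverse of :func:`save_model`."""
    import json

    with open(path) as fh:
        doc = json.load(fh)
    models = {
        c: TargetModel(
            w_t=np.asarray(m["w_t"], dtype=float), b_t=m["b_t"], mu=m["mu"], C_t=m["C_t"]
        )
        for c, m in doc["models"].items()
    }
    std = None
    if doc.get("standardizer"):
        std = Standardizer(
            mean=np.asarray(doc["standardizer"]["mean"], dtype=float),
            scale=np.asarray(doc["standardizer"]["scale"], dtype=float),
        )
    return (
        MulticlassModel(classes=tuple(doc["classes"]), models=models),
        std,
        doc.get("feature_names"),
    )


def select_mu_multiclass(
    X_train: np.ndarray,
    y_train: Sequence[str],
    X_val: np.ndarray,
    y_val: Sequence[str],
    sources: Mapping[str, SourceModel],
    cfg: TsvmConfig,
) -> float:
    """Grid-select one shared transfer weight by one-vs-rest validation accuracy."""
    y_val_arr = np.asarray(y_val)
    best_mu, best_acc = None, -1.0
    for mu in sorted(cfg.mu_grid):
        model = fit_one_vs_rest(X_train, y_train, sources, replace(cfg, mu=mu))
        acc = float(np.mean(np.asarray(model.predict(X_val)) == y_val_arr))
        if acc > best_acc + 1e-12:
            best_mu, best_acc = mu, acc
    assert best_mu is not None
    return best_mu
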