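"""Experiment harness and staging metrics.

Per-stage performance is reported one-vs-rest with the three ratios used
throughout the sleep-staging literature::

    TPR (recall/sensitivity)   = TP / (TP + FN)
    TNR (specificity)          = TN / (TN + FP)
    precision                  = TP / (TP + FP)

A zero denominator makes the ratio *undefined*: it is reported as ``None``
and excluded from macro averages, never silently mapped to 0 or 1.

:func:`run_experiment` mirrors the recording-level protocol: recordings are
split into a training pool and held-out test recordings (never by epoch, to
avoid within-recording leakage). A source one-vs-rest SVM is fit on the
pooled training features; on each test recording a small number of labeled
epochs train the transfer SVM (with the transfer weight chosen on a held-out
half of those labels), and the remaining epochs are scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .stages import stage_sort_key
from .tsvm import (
    MulticlassModel,
    Standardizer,
    TsvmConfig,
    fit_one_vs_rest,
    fit_source_models,
    select_mu_multiclass,
)


@dataclass
class ConfusionCounts:
    """One-vs-rest confusion counts for a single positive class."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


def confusion(
    y_true: Sequence[str], y_pred: Sequence[str], positive_class: str
) -> ConfusionCounts:
    """Binarize a multiclass labeling as ``positive_class`` vs rest and count."""
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted")
    if len(y_true) == 0:
        raise ValueError("empty label sequences")
    c = ConfusionCounts()
    for t, p in zip(y_true, y_pred):
        t_pos, p_pos = t == positive_class, p == positive_class
        if t_pos and p_pos:
            c.tp += 1
        elif not t_pos and not p_pos:
            c.tn += 1
        elif p_pos:
            c.fp += 1
        else:
            c.fn += 1
    return c


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def tpr(c: ConfusionCounts) -> float | None:
    """True positive rate (recall); ``None`` when no positives exist."""
    return _ratio(c.tp, c.tp + c.fn)


def tnr(c: ConfusionCounts) -> float | None:
    """True negative rate (specificity); ``None`` when no negatives exist."""
    return _ratio(c.tn, c.tn + c.fp)


def precision(c: ConfusionCounts) -> float | None:
    """Positive predictive value; ``None`` when nothing was predicted positive."""
    return _ratio(c.tp, c.tp + c.fp)


def _metrics(c: ConfusionCounts) -> dict[str, float | None]:
    return {"tpr": tpr(c), "tnr": tnr(c), "precision": precision(c)}


def _macro(per_class: dict[str, dict[str, float | None]]) -> dict[str, float | None]:
    out: dict[str, float | None] = {}
    for m in ("tpr", "tnr", "precision"):
        vals = [v[m] for v in per_class.values() if v[m] is not None]
        out[m] = float(np.mean(vals)) if vals else None
    return out


# ---------------------------------------------------------------------------
# Experiment harness
# ---------------------------------------------------------------------------


@dataclass
class FeatureRecording:
    """Per-epoch features and stage labels for one recording."""

    recording_id: str
    X: np.ndarray
    stages: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape[0] != len(self.stages):
            raise ValueError(
                f"{self.X.shape[0]} feature rows but {len(self.stages)} labels "
                f"in recording {self.recording_id!r}"
            )
        if not self.stages:
            raise ValueError(f"recording {self.recording_id!r} has no labels")


@dataclass
class SplitSpec:
    """Recording-level train/test split (never by epoch)."""

    n_train: int
    seed: int = 0


@dataclass
class ExperimentConfig:
    tsvm: TsvmConfig = field(default_factory=TsvmConfig)
    n_labeled_per_class: int = 10
    classifier: str = "tsvm"  # "tsvm" | "svm" | "oracle"


@dataclass
class EvaluationReport:
    per_class: dict[str, dict[str, float | None]]
    macro: dict[str, float | None]
    per_recording: list[dict]
    config: dict
    seed: int

    def to_dict(self) -> dict:
        return {
            "per_class": self.per_class,
            "macro": self.macro,
            "per_recording": self.per_recording,
            "config": self.config,
            "seed": self.seed,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _split_labeled(
    stages: Sequence[str], n_per_class: int, rng: np.random.Generator
) -> tuple[list[int], list[int]]:
    """Pick up to n_per_class labeled epochs per class, keep >= 1 for evaluation."""
    stages_arr = np.asarray(stages)
    labeled: list[int] = []
    for c in sorted(set(stages), key=stage_sort_key):
        idx = np.flatnonzero(stages_arr == c)
        idx = rng.permutation(idx)
        take = min(n_per_class, max(1, idx.size - 1)) if idx.size > 1 else idx.size
        labeled.extend(int(i) for i in idx[:take])
    labeled_set = set(labeled)
    evaluation = [i for i in range(len(stages)) if i not in labeled_set]
    return sorted(labeled), evaluation


def _halves(indices: Sequence[int], stages: Sequence[str]) -> tuple[list[int], list[int]]:
    """Stratified alternate split of labeled indices into mu-train/mu-val halves."""
    a: list[int] = []
    b: list[int] = []
    by_class: dict[str, list[int]] = {}
    for i in indices:
        by_class.setdefault(stages[i], []).append(i)
    for idx in by_class.values():
        a.extend(idx[0::2])
        b.extend(idx[1::2])
    return a, b


def fit_target_classifier(
    X: np.ndarray,
    stages: Sequence[str],
    labeled: Sequence[int],
    sources,
    cfg: ExperimentConfig,
) -> tuple[MulticlassModel, float]:
    """Fit the per-recording classifier on its labeled epochs.

    For the transfer path the shared transfer weight is selected on a
    stratified held-out half of the labeled epochs, then the model is refit
    on all of them. Returns ``(model, mu_used)``.
    """
    Xl = X[list(labeled)]
    yl = [stages[i] for i in labeled]
    if cfg.classifier == "svm":
        return fit_one_vs_rest(Xl, yl, None, replace(cfg.tsvm, mu=0.0)), 0.0
    tr, va = _halves(labeled, stages)
    if tr and va and len(set(stages[i] for i in tr)) >= 2:
        mu = select_mu_multiclass(
            X[tr], [stages[i] for i in tr], X[va], [stages[i] for i in va], sources, cfg.tsvm
        )
    else:
        mu = min(cfg.tsvm.mu_grid)
    model = fit_one_vs_rest(Xl, yl, sources, replace(cfg.tsvm, mu=mu))
    return model, mu


def run_experiment(
    recordings: Sequence[FeatureRecording],
    split: SplitSpec,
    cfg: ExperimentConfig | None = None,
) -> EvaluationReport:
    """Recording-level train/test experiment, reproducible given ``split.seed``.

    Training recordings are pooled to fit the feature standardizer and the
    per-class source SVMs; each held-out recording then gets its own target
    classifier (per ``cfg.classifier``) and its unlabeled epochs are scored.
    Metrics are reported per class (pooled over test recordings, one-vs-rest)
    with macro means, plus a per-recording breakdown.
    """
    cfg = cfg or ExperimentConfig()
    if len(recordings) < 2:
        raise ValueError("need at least two recordings to split")
    if not 1 <= split.n_train < len(recordings):
        raise ValueError("n_train must leave at least one test recording")

    rng = np.random.default_rng(np.random.SeedSequence(split.seed, spawn_key=(0,)))
    order = rng.permutation(len(recordings))
    train = [recordings[i] for i in order[: split.n_train]]
    test = [recordings[i] for i in order[split.n_train :]]

    X_pool = np.vstack([r.X for r in train])
    y_pool = [s for r in train for s in r.stages]
    std = Standardizer().fit(X_pool)
    sources = None
    if cfg.classifier == "tsvm":
        sources = fit_source_models(std.transform(X_pool), y_pool, cfg.tsvm)

    classes = sorted(set(y_pool), key=stage_sort_key)
    pooled = {c: ConfusionCounts() for c in classes}
    per_recording = []
    for k, rec in enumerate(test):
        Xr = std.transform(rec.X)
        rec_rng = np.random.default_rng(np.random.SeedSequence(split.seed, spawn_key=(1, k)))
        labeled, evaluation = _split_labeled(rec.stages, cfg.n_labeled_per_class, rec_rng)
        if not evaluation:
            continue
        y_eval = [rec.stages[i] for i in evaluation]
        if cfg.classifier == "oracle":
            y_hat, mu = list(y_eval), None
        else:
            model, mu = fit_target_classifier(Xr, rec.stages, labeled, sources, cfg)
            y_hat = model.predict(Xr[evaluation])
        rec_counts = {c: confusion(y_eval, y_hat, c) for c in classes}
        for c in classes:
            pooled[c] = pooled[c] + rec_counts[c]
        rec_metrics = {c: _metrics(cc) for c, cc in rec_counts.items()}
        per_recording.append(
            {
                "recording_id": rec.recording_id,
                "mu": mu,
                "n_labeled": len(labeled),
                "n_evaluated": len(evaluation),
                "per_class": rec_metrics,
                "macro": _macro(rec_metrics),
            }
        )

    per_class = {c: _metrics(cc) for c, cc in pooled.items()}
    return EvaluationReport(
        per_class=per_class,
        macro=_macro(per_class),
        per_recording=per_recording,
        config={
            "classifier": cfg.classifier,
            "n_labeled_per_class": cfg.n_labeled_per_class,
            "C_t": cfg.tsvm.C_t,
            "mu_grid": list(cfg.tsvm.mu_grid),
            "n_train_recordings": split.n_train,
        },
        seed=split.seed,
    )
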