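"""End-to-end glue: recording → features, and the source/target transfer benchmark.

These helpers wire the modules together the way the experiments use them:
synthesize (or load) a recording, band-pass it, cut it into epochs, extract
the 32 multiscale wavelet statistics, then train and score classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .eeg_io import Hypnogram, RawRecording, segment_epochs
from .evaluate import ExperimentConfig, _macro, _metrics, confusion, fit_target_classifier
from .features import extract_features
from .preprocess import PreprocessConfig, bandpass
from .stages import stage_sort_key
from .synthgen import DomainShift, HypnogramSpec, StageSpec, generate_domain_pair
from .tsvm import Standardizer, TsvmConfig, fit_source_models


def features_from_recording(
    rec: RawRecording,
    hypnogram: Hypnogram | None = None,
    epoch_duration: float = 25.0,
    preprocess_cfg: PreprocessConfig | None = None,
) -> tuple[np.ndarray, list[str] | None]:
    """Preprocess (optional), segment and featurize a recording.

    Returns ``(features (n, 32), stage labels or None)``. Pass
    ``preprocess_cfg=None`` to skip filtering (synthetic recordings are
    already band-limited); pass a config to band-pass first.
    """
    if preprocess_cfg is not None:
        rec = bandpass(rec, preprocess_cfg)
    epochs = segment_epochs(rec, epoch_duration, hypnogram)
    X = extract_features(epochs, epoch_duration=epoch_duration)
    labels = [ep.stage for ep in epochs] if hypnogram is not None else None
    return X, labels


@dataclass
class TransferTrialResult:
    """Macro metrics of the transfer SVM vs the target-only SVM on one trial."""

    tsvm_macro: dict[str, float | None]
    svm_macro: dict[str, float | None]
    mu_selected: float
    n_labeled: int
    n_evaluated: int


def transfer_benefit_trial(
    seed: int,
    shift: DomainShift = DomainShift(amplitude_scale=1.5, extra_noise_sd=10.0),
    n_source_epochs: int = 150,
    n_target_epochs: int = 120,
    n_labeled_per_class: int = 10,
    stage_specs: Mapping[str, StageSpec] | None = None,
    tsvm_cfg: TsvmConfig | None = None,
    sampling_rate: float = 125.0,
) -> TransferTrialResult:
    """One seeded source/target trial comparing transfer vs target-only SVM.

    A source and a domain-shifted target recording are synthesized; the
    source trains the per-class source SVMs and the feature standardizer; on
    the target, ``n_labeled_per_class`` epochs per stage are labeled and the
    rest evaluated, once with the transfer SVM (grid-selected transfer
    weight) and once with an SVM trained on the same labeled epochs alone.
    """
    cfg = tsvm_cfg or TsvmConfig(C_t=1.0)
    hyp_spec = HypnogramSpec(n_epochs=n_source_epochs, seed=seed)
    (src_rec, src_hyp), (tgt_rec, tgt_hyp) = generate_domain_pair(
        replace(hyp_spec, n_epochs=max(n_source_epochs, n_target_epochs)),
        stage_specs,
        shift,
        seeds=(2 * seed, 2 * seed + 1),
        sampling_rate=sampling_rate,
    )
    # trim target to its own epoch budget
    n_t = n_target_epochs
    L = int(round(tgt_hyp.epoch_duration * sampling_rate))
    tgt_rec = RawRecording(
        samples=tgt_rec.samples[: n_t * L],
        sampling_rate=sampling_rate,
        channel=tgt_rec.channel,
        recording_id=tgt_rec.recording_id,
    )
    tgt_hyp = Hypnogram(stages=tgt_hyp.stages[:n_t], epoch_duration=tgt_hyp.epoch_duration)

    X_src, y_src = features_from_recording(src_rec, src_hyp)
    X_tgt, y_tgt = features_from_recording(tgt_rec, tgt_hyp)
    assert y_src is not None and y_tgt is not None

    std = Standardizer().fit(X_src)
    X_src_z, X_tgt_z = std.transform(X_src), std.transform(X_tgt)
    sources = fit_source_models(X_src_z, y_src, cfg)

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
    from .evaluate import _split_labeled

    labeled, evaluation = _split_labeled(y_tgt, n_labeled_per_class, rng)
    y_eval = [y_tgt[i] for i in evaluation]
    classes = sorted(set(y_src), key=stage_sort_key)

    exp_cfg = ExperimentConfig(tsvm=cfg, n_labeled_per_class=n_labeled_per_class)
    tsvm_model, mu = fit_target_classifier(X_tgt_z, y_tgt, labeled, sources, exp_cfg)
    svm_model, _ = fit_target_classifier(
        X_tgt_z, y_tgt, labeled, None, replace(exp_cfg, classifier="svm")
    )

    out = {}
    for name, model in (("tsvm", tsvm_model), ("svm", svm_model)):
        y_hat = model.predict(X_tgt_z[evaluation])
        per_class = {c: _metrics(confusion(y_eval, y_hat, c)) for c in classes}
        out[name] = _macro(per_class)
    return TransferTrialResult(
        tsvm_macro=out["tsvm"],
        svm_macro=out["svm"],
        mu_selected=mu,
        n_labeled=len(labeled),
        n_evaluated=len(evaluation),
    )
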