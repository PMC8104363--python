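"""EEG preprocessing: drift removal, noise suppression and artifact rejection.

Scalp EEG is weak (tens of μV) and contaminated by baseline drift,
high-frequency noise, mains interference and movement artifacts. The chain
here is deliberately conventional:

* zero-phase FIR band-pass (default 0.3–35 Hz) — removes drift/DC below the
  high-pass edge and noise above the low-pass edge while preserving every
  band the wavelet features use, with no phase distortion;
* optional mains notch (50 or 60 Hz) via a zero-phase IIR notch;
* amplitude-threshold epoch rejection (default ±250 μV) for gross artifacts,
  reporting the rejected indices for audit.

The defaults are implementation choices (standard sleep-EEG practice), all
configurable through :class:`PreprocessConfig`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal

from .eeg_io import Epoch, RawRecording

log = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    highpass_cutoff: float = 0.3
    lowpass_cutoff: float = 35.0
    notch_freq: float | None = None
    artifact_amplitude_limit: float = 250.0

    def validate(self, sampling_rate: float) -> None:
        nyq = sampling_rate / 2.0
        if not (0.0 < self.highpass_cutoff < self.lowpass_cutoff < nyq):
            raise ValueError(
                f"need 0 < highpass ({self.highpass_cutoff}) < lowpass "
                f"({self.lowpass_cutoff}) < Nyquist ({nyq})"
            )
        if self.notch_freq is not None and not (0.0 < self.notch_freq < nyq):
            raise ValueError(f"notch_freq must lie below Nyquist ({nyq})")
        if self.artifact_amplitude_limit <= 0:
            raise ValueError("artifact_amplitude_limit must be positive")


def _bandpass_taps(cfg: PreprocessConfig, fs: float) -> np.ndarray:
    # transition width tied to the high-pass edge so DC is well attenuated
    width = min(cfg.highpass_cutoff, (fs / 2.0 - cfg.lowpass_cutoff))
    numtaps = int(np.ceil(3.3 * fs / width))
    numtaps += 1 - numtaps % 2  # odd length -> type-I linear phase
    return signal.firwin(
        numtaps,
        [cfg.highpass_cutoff, cfg.lowpass_cutoff],
        pass_zero=False,
        fs=fs,
    )


def bandpass(rec: RawRecording, cfg: PreprocessConfig | None = None) -> RawRecording:
    """Zero-phase band-pass (and optional notch) filter a recording.

    Output has the same length and rate; passband gain is ~1 and the filter
    is applied forward-backward (``filtfilt``) so features are not shifted
    in time. Input must be comfortably longer than the filter (a few times
    ``3.3 * fs / highpass_cutoff`` samples).
    """
    cfg = cfg or PreprocessConfig()
    cfg.validate(rec.sampling_rate)
    taps = _bandpass_taps(cfg, rec.sampling_rate)
    if rec.samples.size <= 3 * len(taps):
        raise ValueError(
            f"recording too short to filter: {rec.samples.size} samples vs "
            f"{len(taps)}-tap FIR (need > {3 * len(taps)})"
        )
    y = signal.filtfilt(taps, [1.0], rec.samples)
    if cfg.notch_freq is not None:
        b, a = signal.iirnotch(cfg.notch_freq, Q=30.0, fs=rec.sampling_rate)
        y = signal.filtfilt(b, a, y)
    return RawRecording(
        samples=y,
        sampling_rate=rec.sampling_rate,
        channel=rec.channel,
        recording_id=rec.recording_id,
    )


def reject_artifacts(
    epochs: Sequence[Epoch],
    amplitude_limit: float = 250.0,
) -> tuple[list[Epoch], list[int]]:
    """Drop epochs whose peak absolute amplitude exceeds ``amplitude_limit`` μV.

    Returns the kept epochs and the rejected epoch indices (positions in the
    input sequence). An empty kept list is allowed but logged as a warning.
    """
    kept: list[Epoch] = []
    rejected: list[int] = []
    for i, ep in enumerate(epochs):
        if np.max(np.abs(ep.samples)) > amplitude_limit:
            rejected.append(i)
        else:
            kept.append(ep)
    if epochs and not kept:
        log.warning(
            "artifact rejection removed all %d epochs (limit %.1f uV)",
            len(epochs),
            amplitude_limit,
        )
    return kept, rejected
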