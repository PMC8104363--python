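"""Wavelet sub-band features for sleep staging.

Each 25-s epoch is decomposed with a 4-level discrete wavelet transform
(Daubechies-4, periodized). At a 125 Hz sampling rate the sub-bands map
onto the classical EEG rhythms:

=========  ===================  =================
component  nominal band (Hz)    EEG rhythm
=========  ===================  =================
A4         0 – 3.9              delta
D4         3.9 – 7.8            theta
D3         7.8 – 15.6           alpha (+ low beta, sigma spindles)
D2         15.6 – 31.2          beta
D1         31.2 – 62.5          (noise; discarded)
=========  ===================  =================

For each of A4, D4, D3 and D2 the mean and the (population) standard
deviation of the absolute coefficients are computed — 8 statistics per
epoch. These base-scale values are then averaged over centered sliding
windows of 3, 6 and 8 epochs (~80, 140 and 200 s), giving a 32-dimensional
feature vector per epoch that captures both the instantaneous spectral
content and its local stability across neighbouring epochs.

Numerical conventions (the method description leaves them open):

* periodized wavelet extension, so level-k coefficient counts are exactly
  ``L / 2**k`` and Parseval's identity holds;
* a 3125-sample epoch (25 s @ 125 Hz) is zero-padded to 3136 (next multiple
  of 16) before the transform; truncation to 3120 is available;
* sliding windows are centered with edge truncation (a window of ``w``
  epochs at epoch ``i`` covers ``[i - (w-1)//2, i + w//2]`` clipped to the
  recording).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pywt

from .eeg_io import Epoch

#: sub-bands used for features, slowest first; D1 carries essentially no EEG
#: signal below a 35 Hz low-pass and is discarded
BANDS: tuple[str, ...] = ("A4", "D4", "D3", "D2")

#: default analysis timescales in seconds (base epoch + sliding-window means)
DEFAULT_SCALES: tuple[int, ...] = (25, 80, 140, 200)

_LEVEL = 4


@dataclass
class WaveletDecomposition:
    """Coefficients of a 4-level DWT: approximation A4 and details D4..D1."""

    A4: np.ndarray
    D4: np.ndarray
    D3: np.ndarray
    D2: np.ndarray
    D1: np.ndarray

    def band(self, name: str) -> np.ndarray:
        return getattr(self, name)

    def total_energy(self) -> float:
        return float(
            sum(np.sum(self.band(b) ** 2) for b in ("A4", "D4", "D3", "D2", "D1"))
        )


def _pad_epoch(x: np.ndarray, mode: str) -> np.ndarray:
    block = 2**_LEVEL
    rem = x.size % block
    if rem == 0:
        return x
    if mode == "zero":
        return np.concatenate([x, np.zeros(block - rem)])
    if mode == "truncate":
        return x[: x.size - rem]
    raise ValueError(f"unknown pad mode {mode!r}; use 'zero' or 'truncate'")


def dwt4(
    epoch: Epoch | np.ndarray,
    wavelet: str = "db4",
    pad: str = "zero",
) -> WaveletDecomposition:
    """4-level DWT of one epoch with periodized extension.

    Epochs whose length is not a multiple of 16 are zero-padded (default)
    or truncated to one. The transform is orthogonal, so the inverse
    reconstructs the (padded) epoch to machine precision and coefficient
    energy equals signal energy.
    """
    x = epoch.samples if isinstance(epoch, Epoch) else np.asarray(epoch, dtype=float)
    x = _pad_epoch(x, pad)
    if x.size < 2**_LEVEL:
        raise ValueError(f"epoch too short for a {_LEVEL}-level transform: {x.size} samples")
    cA4, cD4, cD3, cD2, cD1 = pywt.wavedec(x, wavelet, mode="periodization", level=_LEVEL)
    return WaveletDecomposition(A4=cA4, D4=cD4, D3=cD3, D2=cD2, D1=cD1)


def reconstruct(dec: WaveletDecomposition, wavelet: str = "db4") -> np.ndarray:
    """Inverse of :func:`dwt4` (returns the padded-length signal)."""
    return pywt.waverec(
        [dec.A4, dec.D4, dec.D3, dec.D2, dec.D1], wavelet, mode="periodization"
    )


def band_stats(dec: WaveletDecomposition) -> np.ndarray:
    """Mean and population sd of |coefficients| for A4, D4, D3, D2.

    Returns an 8-vector ordered ``(A4, D4, D3, D2) × (mean_abs, sd_abs)``.
    """
    out = np.empty(2 * len(BANDS))
    for k, b in enumerate(BANDS):
        c = dec.band(b)
        if c.size == 0:
            raise ValueError(f"empty coefficient sequence for band {b}")
        a = np.abs(c)
        out[2 * k] = a.mean()
        out[2 * k + 1] = a.std()  # population convention (divide by n)
    return out


def _window_bounds(i: int, n: int, w: int) -> tuple[int, int]:
    lo = max(0, i - (w - 1) // 2)
    hi = min(n, i + w // 2 + 1)
    return lo, hi


def multiscale(
    base: np.ndarray,
    scales: Sequence[int] = DEFAULT_SCALES,
    epoch_duration: float = 25.0,
) -> np.ndarray:
    """Aggregate base-scale statistics over sliding windows of epochs.

    ``base`` is the (n_epochs, 8) matrix from :func:`band_stats`. For every
    scale, the window length is ``round(scale / epoch_duration)`` epochs
    (3, 6, 8 for 80/140/200 s at 25-s epochs), centered at each epoch and
    truncated at the recording edges; the 25-s scale is the identity.

    Returns (n_epochs, 8 × n_scales) ordered
    ``(A4, D4, D3, D2) × (mean_abs, sd_abs) × scales``.
    """
    base = np.asarray(base, dtype=float)
    if base.ndim != 2 or base.shape[0] == 0:
        raise ValueError("base must be a non-empty (n_epochs, n_stats) matrix")
    n, m = base.shape
    per_scale = []
    for s in scales:
        w = max(1, int(round(s / epoch_duration)))
        if w == 1:
            per_scale.append(base)
            continue
        agg = np.empty_like(base)
        for i in range(n):
            lo, hi = _window_bounds(i, n, w)
            agg[i] = base[lo:hi].mean(axis=0)
        per_scale.append(agg)
    # interleave: band/stat slowest, scale fastest
    out = np.empty((n, m * len(per_scale)))
    for j in range(m):
        for k, agg in enumerate(per_scale):
            out[:, j * len(per_scale) + k] = agg[:, j]
    return out


def feature_names(scales: Sequence[int] = DEFAULT_SCALES) -> list[str]:
    """Column names matching :func:`multiscale` ordering, e.g. ``D3_mean_abs_80s``."""
    names = []
    for b in BANDS:
        for stat in ("mean_abs", "sd_abs"):
            for s in scales:
                names.append(f"{b}_{stat}_{s}s")
    return names


def extract_features(
    epochs: Sequence[Epoch],
    wavelet: str = "db4",
    scales: Sequence[int] = DEFAULT_SCALES,
    epoch_duration: float = 25.0,
    pad: str = "zero",
) -> np.ndarray:
    """Epochs → (n_epochs, 32) multiscale wavelet-statistic matrix."""
    if not epochs:
        raise ValueError("no epochs to extract features from")
    base = np.vstack([band_stats(dwt4(ep, wavelet=wavelet, pad=pad)) for ep in epochs])
    return multiscale(base, scales=scales, epoch_duration=epoch_duration)
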