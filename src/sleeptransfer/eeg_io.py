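"""Recording containers and I/O: EDF signals, hypnogram text files, feature tables.

The on-disk formats are deliberately minimal and text-friendly:

* **EDF** (European Data Format) for signals — 16-bit, physical units μV.
  A compact reader/writer pair is implemented here so recordings written by
  the synthetic generator round-trip exactly up to 16-bit quantization.
* **Hypnogram** files — one stage label per line (``W``/``N1``/``N2``/``N3``/
  ``REM``).  SHHS/NSRR numeric staging codes can be converted via
  :func:`sleeptransfer.stages.SHHS_STAGE_CODES` (stage 4 merges into N3).
* **Feature tables** — CSV with a header row; one row per epoch, a ``stage``
  column when labels are present, and one column per wavelet statistic.

Epoch indexing is 0-based; epoch ``i`` covers the half-open sample interval
``[i*L, (i+1)*L)``.  A trailing partial epoch is dropped, never padded,
because the wavelet features require full-length windows.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .stages import SHHS_STAGE_CODES, check_stage


@dataclass
class RawRecording:
    """Continuous single-channel EEG in physical units (μV)."""

    samples: np.ndarray
    sampling_rate: float
    channel: str = "EEG"
    recording_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.samples.size / self.sampling_rate


@dataclass
class Epoch:
    """A fixed-length signal segment with an optional stage label."""

    samples: np.ndarray
    index: int = 0
    stage: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.stage is not None:
            check_stage(self.stage)


@dataclass
class Hypnogram:
    """Per-epoch sleep-stage label sequence."""

    stages: list[str]
    epoch_duration: float = 25.0

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("hypnogram must contain at least one epoch label")
        for s in self.stages:
            check_stage(s)

    def __len__(self) -> int:
        return len(self.stages)

    def fractions(self) -> dict[str, float]:
        """Realized fraction of epochs per stage present in the hypnogram."""
        from collections import Counter

        n = len(self.stages)
        return {s: c / n for s, c in Counter(self.stages).items()}


class ChannelNotFoundError(ValueError):
    """Requested channel is absent from an EDF file."""


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

_EDF_HEADER = 256  # bytes for the fixed part; +256 per signal


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(path: str | Path, recordings: RawRecording | Sequence[RawRecording]) -> None:
    """Write one or more channels to a 16-bit EDF file.

    Each channel keeps its own sampling rate (must be a whole number of
    samples per second; data records are 1 s long). Signals shorter than a
    whole number of records are zero-padded to the record boundary. The
    physical scale is chosen per channel as the symmetric peak amplitude, so
    quantization error is at most ``peak/32767/2`` μV.
    """
    if isinstance(recordings, RawRecording):
        recordings = [recordings]
    if not recordings:
        raise ValueError("no channels to write")
    for rec in recordings:
        if abs(rec.sampling_rate - round(rec.sampling_rate)) > 1e-9:
            raise ValueError("EDF writer requires integer sampling rates (1-s records)")

    n_records = max(int(np.ceil(r.duration)) for r in recordings)
    ns = len(recordings)

    labels, phys_ranges, sprs, digitized = [], [], [], []
    for rec in recordings:
        spr = int(round(rec.sampling_rate))
        x = np.zeros(n_records * spr)
        x[: rec.samples.size] = rec.samples
        peak = float(np.max(np.abs(x)))
        if peak == 0.0:
            peak = 1.0
        # format the physical bounds first and digitize against the parsed
        # value, so reconstruction from the header is exact
        pmax_s = f"{peak:.6g}"[:8]
        pmax = float(pmax_s)
        dig = np.clip(np.rint(x / pmax * 32767.0), -32767, 32767).astype("<i2")
        labels.append(rec.channel)
        phys_ranges.append(pmax_s)
        sprs.append(spr)
        digitized.append(dig)

    rec_id = recordings[0].recording_id or "synthetic"
    header = b"".join(
        [
            _pad("0", 8),
            _pad("X X X X", 80),
            _pad(rec_id, 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(_EDF_HEADER * (1 + ns)), 8),
            _pad("", 44),
            _pad(str(n_records), 8),
            _pad("1", 8),
            _pad(str(ns), 4),
        ]
    )
    sig_header = b"".join(
        [
            b"".join(_pad(lab, 16) for lab in labels),
            b"".join(_pad("", 80) for _ in labels),
            b"".join(_pad("uV", 8) for _ in labels),
            b"".join(_pad("-" + p, 8) for p in phys_ranges),
            b"".join(_pad(p, 8) for p in phys_ranges),
            b"".join(_pad("-32767", 8) for _ in labels),
            b"".join(_pad("32767", 8) for _ in labels),
            b"".join(_pad("", 80) for _ in labels),
            b"".join(_pad(str(s), 8) for s in sprs),
            b"".join(_pad("", 32) for _ in labels),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for r in range(n_records):
            for dig, spr in zip(digitized, sprs):
                fh.write(struct.pack(f"<{spr}h", *dig[r * spr : (r + 1) * spr]))


def _read_edf_header(fh) -> dict:
    head = fh.read(_EDF_HEADER)
    if len(head) < _EDF_HEADER:
        raise ValueError("corrupt EDF header: file shorter than 256 bytes")

    def fld(off: int, width: int) -> str:
        return head[off : off + width].decode("ascii", errors="replace").strip()

    try:
        n_records = int(fld(236, 8))
        record_duration = float(fld(244, 8))
        ns = int(fld(252, 4))
    except ValueError as exc:  # non-numeric header fields
        raise ValueError("corrupt EDF header: non-numeric record fields") from exc
    if ns < 1 or n_records < 0 or record_duration <= 0:
        raise ValueError("corrupt EDF header: implausible record geometry")

    sig = fh.read(256 * ns)
    if len(sig) < 256 * ns:
        raise ValueError("corrupt EDF header: truncated signal headers")

    def sig_fld(block_off: int, width: int, i: int) -> str:
        off = block_off * ns + i * width
        return sig[off : off + width].decode("ascii", errors="replace").strip()

    labels = [sig_fld(0, 16, i) for i in range(ns)]
    try:
        phys_min = [float(sig_fld(16 + 80 + 8, 8, i)) for i in range(ns)]
        phys_max = [float(sig_fld(16 + 80 + 8 + 8, 8, i)) for i in range(ns)]
        dig_min = [int(sig_fld(16 + 80 + 8 + 16, 8, i)) for i in range(ns)]
        dig_max = [int(sig_fld(16 + 80 + 8 + 24, 8, i)) for i in range(ns)]
        spr = [int(sig_fld(16 + 80 + 8 + 32 + 80, 8, i)) for i in range(ns)]
    except ValueError as exc:
        raise ValueError("corrupt EDF header: non-numeric signal fields") from exc
    return {
        "recording_id": fld(88, 80),
        "n_records": n_records,
        "record_duration": record_duration,
        "labels": labels,
        "phys_min": phys_min,
        "phys_max": phys_max,
        "dig_min": dig_min,
        "dig_max": dig_max,
        "spr": spr,
    }


def read_edf(path: str | Path, channel: str | None = None) -> RawRecording:
    """Read one channel from an EDF file in physical units (μV).

    Parameters
    ----------
    path
        EDF file path.
    channel
        Channel label to extract; ``None`` selects the first channel.
        The returned recording carries that channel's own sampling rate,
        even in files mixing rates.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "rb") as fh:
        hdr = _read_edf_header(fh)
        labels = hdr["labels"]
        if channel is None:
            idx = 0
        else:
            if channel not in labels:
                raise ChannelNotFoundError(
                    f"channel {channel!r} not in file; available channels: {labels}"
                )
            idx = labels.index(channel)
        record_words = sum(hdr["spr"])
        data = np.frombuffer(fh.read(2 * record_words * hdr["n_records"]), dtype="<i2")
    if data.size < record_words * hdr["n_records"]:
        raise ValueError("corrupt EDF file: truncated data records")
    data = data.reshape(hdr["n_records"], record_words)
    offsets = np.concatenate([[0], np.cumsum(hdr["spr"])])
    dig = data[:, offsets[idx] : offsets[idx + 1]].reshape(-1).astype(float)
    pmin, pmax = hdr["phys_min"][idx], hdr["phys_max"][idx]
    dmin, dmax = hdr["dig_min"][idx], hdr["dig_max"][idx]
    phys = (dig - dmin) * (pmax - pmin) / (dmax - dmin) + pmin
    return RawRecording(
        samples=phys,
        sampling_rate=hdr["spr"][idx] / hdr["record_duration"],
        channel=labels[idx],
        recording_id=hdr["recording_id"],
    )


# ---------------------------------------------------------------------------
# Epoch segmentation
# ---------------------------------------------------------------------------


def segment_epochs(
    rec: RawRecording,
    epoch_duration: float = 25.0,
    hypnogram: Hypnogram | Sequence[str] | None = None,
) -> list[Epoch]:
    """Cut a recording into fixed-length epochs, optionally attaching labels.

    ``floor(n_samples / epoch_samples)`` epochs are produced; a trailing
    partial epoch is discarded. When a hypnogram is given, epoch ``i``
    carries label ``i``; a hypnogram shorter than the epoch count is an
    error rather than a silent truncation.
    """
    n_per = epoch_duration * rec.sampling_rate
    if abs(n_per - round(n_per)) > 1e-9:
        raise ValueError("epoch_duration * sampling_rate must be an integer sample count")
    n_per = int(round(n_per))
    n_epochs = rec.samples.size // n_per
    labels: Sequence[str] | None = None
    if hypnogram is not None:
        labels = hypnogram.stages if isinstance(hypnogram, Hypnogram) else list(hypnogram)
        if len(labels) < n_epochs:
            raise ValueError(
                f"hypnogram has {len(labels)} labels but the recording yields "
                f"{n_epochs} epochs"
            )
    return [
        Epoch(
            samples=rec.samples[i * n_per : (i + 1) * n_per],
            index=i,
            stage=None if labels is None else labels[i],
        )
        for i in range(n_epochs)
    ]


# ---------------------------------------------------------------------------
# Hypnogram text files
# ---------------------------------------------------------------------------


def write_hypnogram(path: str | Path, hyp: Hypnogram) -> None:
    """Write one stage label per line."""
    Path(path).write_text("\n".join(hyp.stages) + "\n")


def read_hypnogram(
    path: str | Path,
    epoch_duration: float = 25.0,
    numeric_codes: dict[int, str] | None = None,
) -> Hypnogram:
    """Read a one-label-per-line hypnogram.

    Lines may be AASM labels or numeric staging codes; numeric lines are
    converted via ``numeric_codes`` (default: the SHHS convention with the
    legacy stage 4 merged into N3).
    """
    codes = SHHS_STAGE_CODES if numeric_codes is None else numeric_codes
    stages = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.lstrip("-").isdigit():
            code = int(line)
            if code not in codes:
                raise ValueError(f"unknown numeric stage code {code}")
            stages.append(codes[code])
        else:
            stages.append(check_stage(line))
    return Hypnogram(stages=stages, epoch_duration=epoch_duration)


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------


def write_feature_table(
    features: np.ndarray,
    labels: Sequence[str] | None,
    path: str | Path,
    feature_names: Sequence[str] | None = None,
) -> None:
    """Write a per-epoch feature matrix (and optional labels) as CSV.

    Values round-trip at full float64 precision (shortest-repr encoding).
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.size == 0:
        raise ValueError("features must be a non-empty 2-D array")
    if labels is not None and len(labels) != features.shape[0]:
        raise ValueError(
            f"{features.shape[0]} feature rows but {len(labels)} labels"
        )
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(features.shape[1])]
    if len(feature_names) != features.shape[1]:
        raise ValueError("feature_names length must match feature columns")
    df = pd.DataFrame(features, columns=list(feature_names))
    if labels is not None:
        df.insert(0, "stage", list(labels))
    df.to_csv(path, index=False, float_format="%.17g")  # bit-exact round trip


def read_feature_table(path: str | Path) -> tuple[np.ndarray, list[str] | None, list[str]]:
    """Read a feature CSV; returns ``(features, labels_or_None, feature_names)``."""
    df = pd.read_csv(path, float_precision="round_trip")
    labels: list[str] | None = None
    if "stage" in df.columns:
        labels = [check_stage(str(s)) for s in df["stage"]]
        df = df.drop(columns=["stage"])
    return df.to_numpy(dtype=float), labels, list(df.columns)
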