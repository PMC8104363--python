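"""Synthetic polysomnography generator.

Sleep staging research data (SHHS/NSRR polysomnography) is access
restricted, so this module fabricates recordings with just enough
structure for the downstream feature extractor and classifier to be
exercised end to end:

* **Hypnograms** — a night is a sequence of sleep cycles, each visiting
  stages in the order W → N1 → N2 → N3 → N2 → REM (descent into deep
  sleep, partial re-ascent, then REM). Normal adults show roughly 4–6
  such cycles per night with sleep-time proportions of about 5% N1,
  20% N2, 50% N3 and 25% REM; those proportions are the generator
  defaults.
* **Stage-conditioned EEG** — each stage is a sum of narrow-band
  rhythms on Gaussian background noise: alpha 9–11 Hz in wake, theta
  5–7 Hz in N1, 12–14 Hz sigma spindles in N2, high-amplitude delta in
  N3. REM carries low-amplitude mixed theta as a modeling stand-in
  (no distinctive single-channel REM EEG rhythm is defined).
* **Domain pairs** — a source/target recording pair where the target is
  perturbed by an amplitude rescaling, added noise and a frequency
  shift, emulating the cross-cohort discrepancy that transfer learning
  is meant to absorb.

All outputs are bit-for-bit reproducible given the spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .eeg_io import Epoch, Hypnogram, RawRecording
from .stages import STAGES, check_stage

#: default sleep-time stage proportions for normal adults
DEFAULT_PROPORTIONS: dict[str, float] = {"N1": 0.05, "N2": 0.20, "N3": 0.50, "REM": 0.25}

#: stage order visited within one sleep cycle (N2 appears twice: descent and re-ascent)
CYCLE_TEMPLATE: tuple[str, ...] = ("W", "N1", "N2", "N3", "N2", "REM")


@dataclass
class StageSpec:
    """Spectral recipe for one sleep stage.

    ``rhythm_components`` is a list of ``(low_hz, high_hz, amplitude_uv)``
    narrow bands; each synthesized epoch draws one frequency uniformly from
    every band. ``burst_probability`` adds an amplitude-modulated 12–14 Hz
    spindle burst (0.5–2 s, Hann envelope) with that per-epoch probability,
    at 1.5× the largest component amplitude. ``amplitude_cv`` is the
    coefficient of variation of unit-mean log-normal per-epoch gains (one
    shared by the rhythms, an independent one for the noise floor), modeling
    the waxing and waning of rhythm amplitude across epochs of one stage.
    """

    stage: str
    rhythm_components: list[tuple[float, float, float]]
    background_noise_sd: float = 0.0
    burst_probability: float = 0.0
    amplitude_cv: float = 0.0

    def __post_init__(self) -> None:
        check_stage(self.stage)
        if self.amplitude_cv < 0:
            raise ValueError("amplitude_cv must be >= 0")
        if not self.rhythm_components:
            raise ValueError("at least one rhythm component is required")
        for lo, hi, amp in self.rhythm_components:
            if not (0 < lo < hi):
                raise ValueError(f"need 0 < low < high, got ({lo}, {hi})")
            if amp < 0:
                raise ValueError("rhythm amplitude must be >= 0")
        if self.background_noise_sd < 0:
            raise ValueError("background_noise_sd must be >= 0")
        if not 0.0 <= self.burst_probability <= 1.0:
            raise ValueError("burst_probability must be in [0, 1]")

    def dominant_band(self) -> tuple[float, float]:
        """(low, high) of the largest-amplitude rhythm component."""
        lo, hi, _ = max(self.rhythm_components, key=lambda c: c[2])
        return lo, hi


def default_stage_specs() -> dict[str, StageSpec]:
    """Per-stage spectral recipes used throughout the package.

    Amplitudes are in the tens-of-μV range typical of scalp EEG; N3 delta
    is the largest, REM theta the smallest, so stages differ both in band
    and in amplitude statistics.
    """
    return {
        "W": StageSpec("W", [(9.0, 11.0, 30.0)], background_noise_sd=25.0, amplitude_cv=0.5),
        "N1": StageSpec("N1", [(5.0, 7.0, 40.0)], background_noise_sd=30.0, amplitude_cv=0.5),
        "N2": StageSpec(
            "N2",
            [(12.0, 14.0, 35.0), (5.0, 7.0, 20.0)],
            background_noise_sd=30.0,
            burst_probability=0.9,
            amplitude_cv=0.5,
        ),
        "N3": StageSpec("N3", [(0.75, 3.0, 75.0)], background_noise_sd=35.0, amplitude_cv=0.5),
        # REM has no distinctive single-channel rhythm; low-amplitude mixed
        # theta is a stand-in choice, not a physiological claim.
        "REM": StageSpec("REM", [(5.0, 7.0, 25.0)], background_noise_sd=25.0, amplitude_cv=0.5),
    }


@dataclass
class HypnogramSpec:
    """Recipe for a synthetic hypnogram."""

    n_epochs: int
    stage_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    n_cycles: int = 5
    seed: int = 0
    epoch_duration: float = 25.0

    def __post_init__(self) -> None:
        for s in self.stage_proportions:
            check_stage(s)
        total = sum(self.stage_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"stage proportions must sum to 1, got {total}")
        if any(p < 0 for p in self.stage_proportions.values()):
            raise ValueError("stage proportions must be non-negative")
        if not (self.n_epochs >= self.n_cycles >= 1):
            raise ValueError("need n_epochs >= n_cycles >= 1")


@dataclass
class DomainShift:
    """Source→target distribution shift applied to stage recipes.

    ``amplitude_scale`` multiplies every rhythm amplitude and the background
    noise sd; ``extra_noise_sd`` (μV) is added independently to the target
    recording; ``frequency_jitter`` (Hz) shifts every rhythm band upward.
    The identity shift (1, 0, 0) leaves the generator untouched.
    """

    amplitude_scale: float = 1.0
    extra_noise_sd: float = 0.0
    frequency_jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude_scale <= 0:
            raise ValueError("amplitude_scale must be positive")
        if self.extra_noise_sd < 0:
            raise ValueError("extra_noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# Hypnogram generation
# ---------------------------------------------------------------------------


def generate_hypnogram(spec: HypnogramSpec) -> Hypnogram:
    """Draw a hypnogram with the requested stage proportions and cycle layout.

    Total per-stage epoch counts are a single multinomial draw at the
    requested proportions (realized fractions therefore converge to the
    request as ``n_epochs`` grows), then spread as evenly as possible over
    ``n_cycles`` cycles, each laid out in :data:`CYCLE_TEMPLATE` order with
    a cycle's N2 share split between its descending and re-ascending block.
    Deterministic given ``spec.seed``.
    """
    stages = [s for s in STAGES if spec.stage_proportions.get(s, 0.0) > 0]
    probs = np.array([spec.stage_proportions[s] for s in stages])
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(0,)))
    counts = dict(zip(stages, rng.multinomial(spec.n_epochs, probs / probs.sum())))

    # floor share per cycle; remainders go to the earliest cycles
    per_cycle: dict[str, list[int]] = {}
    for s, c in counts.items():
        shares = [c // spec.n_cycles] * spec.n_cycles
        for k in range(c % spec.n_cycles):
            shares[k] += 1
        per_cycle[s] = shares

    labels: list[str] = []
    for k in range(spec.n_cycles):
        n2 = per_cycle.get("N2", [0] * spec.n_cycles)[k]
        blocks = {
            0: per_cycle.get("W", [0] * spec.n_cycles)[k],
            1: per_cycle.get("N1", [0] * spec.n_cycles)[k],
            2: n2 // 2,
            3: per_cycle.get("N3", [0] * spec.n_cycles)[k],
            4: n2 - n2 // 2,
            5: per_cycle.get("REM", [0] * spec.n_cycles)[k],
        }
        for pos, stage in enumerate(CYCLE_TEMPLATE):
            labels.extend([stage] * blocks[pos])
    return Hypnogram(stages=labels, epoch_duration=spec.epoch_duration)


# ---------------------------------------------------------------------------
# Epoch and recording synthesis
# ---------------------------------------------------------------------------


def synthesize_epoch(
    stage: str,
    spec: StageSpec,
    sampling_rate: float = 125.0,
    duration: float = 25.0,
    seed: int | np.random.SeedSequence = 0,
) -> Epoch:
    """Synthesize one EEG epoch for a sleep stage.

    The epoch is a sum of one sinusoid per rhythm component (frequency drawn
    uniformly inside the component band, random phase), an optional spindle
    burst, and white Gaussian background noise. With zero noise, spectral
    power concentrates in the rhythm bands and the periodogram peak falls in
    the dominant component's band.

    The random call sequence is fixed, so recipes that differ only in
    amplitudes yield sample-wise proportional epochs for equal seeds.
    """
    check_stage(stage)
    if duration <= 0:
        raise ValueError("duration must be positive")
    n_f = duration * sampling_rate
    if abs(n_f - round(n_f)) > 1e-9:
        raise ValueError("duration * sampling_rate must be an integer sample count")
    n = int(round(n_f))
    nyq = sampling_rate / 2.0
    for lo, hi, _ in spec.rhythm_components:
        if hi > nyq + 1e-12:
            raise ValueError(f"rhythm band ({lo}, {hi}) exceeds Nyquist {nyq} Hz")

    rng = np.random.default_rng(seed)
    rhythm_gain = noise_gain = 1.0
    if spec.amplitude_cv > 0.0:
        # unit-mean log-normal per-epoch gains (vigilance-level fluctuation)
        s = np.sqrt(np.log1p(spec.amplitude_cv**2))
        rhythm_gain = rng.lognormal(-0.5 * s * s, s)
        noise_gain = rng.lognormal(-0.5 * s * s, s)
    t = np.arange(n) / sampling_rate
    x = np.zeros(n)
    for lo, hi, amp in spec.rhythm_components:
        f = rng.uniform(lo, hi)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        x += rhythm_gain * amp * np.sin(2.0 * np.pi * f * t + phase)

    if spec.burst_probability > 0.0:
        # draws happen unconditionally so the call sequence does not depend
        # on the realized burst decision's amplitude recipe
        u = rng.uniform()
        burst_dur = rng.uniform(0.5, 2.0)
        burst_f = rng.uniform(12.0, 14.0)
        start = rng.uniform(0.0, max(duration - burst_dur, 0.0))
        phase = rng.uniform(0.0, 2.0 * np.pi)
        if u < spec.burst_probability:
            amp_b = 1.5 * rhythm_gain * max(a for _, _, a in spec.rhythm_components)
            i0 = int(round(start * sampling_rate))
            i1 = min(n, i0 + int(round(burst_dur * sampling_rate)))
            m = i1 - i0
            if m > 0:
                env = np.hanning(m)
                tb = np.arange(m) / sampling_rate
                x[i0:i1] += amp_b * env * np.sin(2.0 * np.pi * burst_f * tb + phase)

    if spec.background_noise_sd > 0.0:
        x += noise_gain * rng.normal(0.0, spec.background_noise_sd, n)
    return Epoch(samples=x, index=0, stage=stage)


def generate_recording(
    hyp_spec: HypnogramSpec,
    stage_specs: Mapping[str, StageSpec] | None = None,
    sampling_rate: float = 125.0,
    recording_id: str = "synthetic",
    channel: str = "EEG",
) -> tuple[RawRecording, Hypnogram]:
    """Generate a labeled recording by concatenating stage-conditioned epochs.

    Epoch ``i`` uses an independent random stream derived from
    ``(hyp_spec.seed, 1, i)``, so matched-seed recordings generated from
    amplitude-rescaled recipes are sample-wise proportional.
    """
    if stage_specs is None:
        stage_specs = default_stage_specs()
    hyp = generate_hypnogram(hyp_spec)
    missing = sorted({s for s in hyp.stages if s not in stage_specs})
    if missing:
        raise ValueError(f"no StageSpec for generated stage(s): {missing}")
    chunks = []
    for i, stage in enumerate(hyp.stages):
        ep = synthesize_epoch(
            stage,
            stage_specs[stage],
            sampling_rate=sampling_rate,
            duration=hyp_spec.epoch_duration,
            seed=np.random.SeedSequence(hyp_spec.seed, spawn_key=(1, i)),
        )
        chunks.append(ep.samples)
    rec = RawRecording(
        samples=np.concatenate(chunks),
        sampling_rate=sampling_rate,
        channel=channel,
        recording_id=recording_id,
    )
    return rec, hyp


def shift_stage_specs(
    stage_specs: Mapping[str, StageSpec], shift: DomainShift
) -> dict[str, StageSpec]:
    """Apply a :class:`DomainShift` to every stage recipe."""
    out = {}
    for name, sp in stage_specs.items():
        comps = [
            (lo + shift.frequency_jitter, hi + shift.frequency_jitter, amp * shift.amplitude_scale)
            for lo, hi, amp in sp.rhythm_components
        ]
        out[name] = replace(
            sp,
            rhythm_components=comps,
            background_noise_sd=sp.background_noise_sd * shift.amplitude_scale,
        )
    return out


def generate_domain_pair(
    hyp_spec: HypnogramSpec,
    stage_specs: Mapping[str, StageSpec] | None = None,
    shift: DomainShift = DomainShift(),
    seeds: tuple[int, int] = (0, 1),
    sampling_rate: float = 125.0,
) -> tuple[tuple[RawRecording, Hypnogram], tuple[RawRecording, Hypnogram]]:
    """Generate a source recording and a domain-shifted target recording.

    The source uses ``stage_specs`` unchanged with ``seeds[0]``; the target
    uses the shifted recipes with ``seeds[1]`` plus independent additive
    noise of sd ``shift.extra_noise_sd``. The identity shift with equal
    seeds reproduces the source exactly.
    """
    if stage_specs is None:
        stage_specs = default_stage_specs()
    src = generate_recording(
        replace(hyp_spec, seed=seeds[0]), stage_specs, sampling_rate, recording_id="source"
    )
    tgt_rec, tgt_hyp = generate_recording(
        replace(hyp_spec, seed=seeds[1]),
        shift_stage_specs(stage_specs, shift),
        sampling_rate,
        recording_id="target",
    )
    if shift.extra_noise_sd > 0.0:
        rng = np.random.default_rng(np.random.SeedSequence(seeds[1], spawn_key=(2,)))
        tgt_rec = RawRecording(
            samples=tgt_rec.samples + rng.normal(0.0, shift.extra_noise_sd, tgt_rec.samples.size),
            sampling_rate=tgt_rec.sampling_rate,
            channel=tgt_rec.channel,
            recording_id=tgt_rec.recording_id,
        )
    return src, (tgt_rec, tgt_hyp)
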