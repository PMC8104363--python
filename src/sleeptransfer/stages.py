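"""Sleep-stage vocabulary.

Staging follows the AASM convention: wake (W), three NREM depths (N1, N2,
N3) and REM. Stage labels are plain strings throughout the package;
:data:`STAGES` fixes the canonical ordering used for feature tables,
one-vs-rest class ordering and report layout.
"""

from __future__ import annotations

#: Canonical stage ordering (wake first, then increasing NREM depth, then REM).
STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3", "REM")

_STAGE_SET = frozenset(STAGES)

#: SHHS/NSRR numeric staging codes -> AASM labels. The legacy R&K stage 4 is
#: merged into N3, as AASM scoring prescribes.
SHHS_STAGE_CODES: dict[int, str] = {0: "W", 1: "N1", 2: "N2", 3: "N3", 4: "N3", 5: "REM"}


def check_stage(stage: str) -> str:
    """Validate a stage label, returning it unchanged.

    Raises
    ------
    ValueError
        If ``stage`` is not one of ``W, N1, N2, N3, REM``.
    """
    if stage not in _STAGE_SET:
        raise ValueError(f"unknown sleep stage {stage!r}; expected one of {STAGES}")
    return stage


def stage_sort_key(stage: str) -> int:
    """Sort key placing labels in canonical :data:`STAGES` order."""
    return STAGES.index(stage)
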