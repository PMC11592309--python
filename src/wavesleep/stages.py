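"""Five-class AASM sleep-stage vocabulary shared across the package.

Stages are coded as integers 0..4 in the fixed order (W, N1, N2, N3, REM).
This order is also the hidden/observed state order of the HMM corrector.
"""

from __future__ import annotations

N_STAGES = 5

STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3", "REM")

STAGE_TO_CODE: dict[str, int] = {name: i for i, name in enumerate(STAGES)}

# R&K hypnogram symbols -> AASM 5-class codes. R&K stages 3 and 4 merge
# into N3; MOVEMENT/UNKNOWN epochs carry no stage and are dropped later.
RK_TO_AASM: dict[str, int | None] = {
    "W": 0,
    "1": 1,
    "2": 2,
    "3": 3,
    "4": 3,
    "R": 4,
    "MOVEMENT": None,
    "UNKNOWN": None,
}


def code_of(label: str) -> int:
    """Return the integer code of an AASM stage name."""
    try:
        return STAGE_TO_CODE[label]
    except KeyError:
        raise ValueError(f"unknown stage {label!r}; expected one of {STAGES}") from None
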