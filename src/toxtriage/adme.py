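"""Categorical ADME classification: hepatic clearance and plasma binding.

Intrinsic hepatic clearance (CL_int, ul/min/1e6 hepatocytes) maps to a
most-specific category:

    0                no_metabolism   (little or no metabolism / bioaccumulation potential)
    (0, 2.5)         very_slow
    [2.5, 10]        intermediate
    (10, 100]        fast
    (100, inf)       rapid

The unbound plasma fraction F_u splits at 50% (inclusive) into
high_availability vs lower_availability. Metals and inorganic chemicals are
outside the models' applicability domain; carry that as a record-level flag
upstream rather than a category here.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

CL_NO_METABOLISM = "no_metabolism"
CL_VERY_SLOW = "very_slow"
CL_INTERMEDIATE = "intermediate"
CL_FAST = "fast"
CL_RAPID = "rapid"

FU_HIGH = "high_availability"
FU_LOWER = "lower_availability"

SOURCES = ("human", "rodent", "predicted", "absent")


@dataclass(frozen=True)
class AdmeRecord:
    """Optional clearance / unbound-fraction data with their source.

    Source precedence follows reporting practice (human > rodent >
    predicted) and is carried for audit only; it does not change the
    classification.
    """

    clint: float | None = None  # ul/min/1e6 cells
    fu: float | None = None  # fraction unbound in plasma
    source: str = "absent"

    def __post_init__(self):
        if self.source not in SOURCES:
            raise ValidationError(f"source must be one of {SOURCES}")
        if self.clint is not None and self.clint < 0:
            raise ValidationError(f"clint negative: {self.clint}")
        if self.fu is not None and not 0.0 <= self.fu <= 1.0:
            raise ValidationError(f"fu out of [0, 1]: {self.fu}")


def classify_clearance(clint: float) -> str:
    """Most-specific clearance category for a non-negative CL_int."""
    if clint < 0:
        raise ValidationError(f"clint negative: {clint}")
    if clint == 0:
        return CL_NO_METABOLISM
    if clint < 2.5:
        return CL_VERY_SLOW
    if clint <= 10:
        return CL_INTERMEDIATE
    if clint <= 100:
        return CL_FAST
    return CL_RAPID


def classify_fu(fu: float) -> str:
    """Plasma availability category; boundary 0.5 is high_availability."""
    if not 0.0 <= fu <= 1.0:
        raise ValidationError(f"fu out of [0, 1]: {fu}")
    return FU_HIGH if fu >= 0.5 else FU_LOWER
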