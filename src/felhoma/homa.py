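"""HOMA-IR computation and adiposity classification.

The homeostasis model assessment of insulin resistance (HOMA-IR) is the
product of fasting serum insulin (mU/L) and fasting glucose (mmol/L)
divided by 22.5.  Cats are graded either clinically, by body condition
score (BCS) on a 1-5 or 1-9 scale, or quantitatively by CT-derived body
fat percentage (BF%).
"""

from __future__ import annotations

from enum import Enum

HOMA_DIVISOR = 22.5
#: ng/L -> mU/L conversion factor for the feline insulin ELISA.
INSULIN_NGL_TO_MUL = 0.023

BF_OVERWEIGHT_CUT = 35.0
BF_OBESE_CUT = 45.0


class WeightClassBCS(str, Enum):
    """Two-level adiposity grade from the clinical body condition score."""

    lean = "lean"
    overweight = "overweight"


class WeightClassBF(str, Enum):
    """Three-level adiposity grade from CT body fat percentage."""

    lean = "lean"
    overweight = "overweight"
    obese = "obese"


def homa_ir(insulin_mUL: float, glucose_mmolL: float) -> float:
    """HOMA-IR = insulin (mU/L) x glucose (mmol/L) / 22.5.

    Both inputs must be strictly positive.  The value is unitless and
    carried at full precision; round only for reporting.
    """
    if insulin_mUL <= 0 or glucose_mmolL <= 0:
        raise ValueError(
            f"insulin and glucose must be > 0, got {insulin_mUL}, {glucose_mmolL}"
        )
    return insulin_mUL * glucose_mmolL / HOMA_DIVISOR


def insulin_ngL_to_mUL(x_ngL: float) -> float:
    """Convert an insulin concentration from ng/L to mU/L (factor 0.023)."""
    if x_ngL < 0:
        raise ValueError(f"insulin concentration must be >= 0, got {x_ngL}")
    return INSULIN_NGL_TO_MUL * x_ngL


def insulin_mUL_to_ngL(x_mUL: float) -> float:
    """Inverse of :func:`insulin_ngL_to_mUL`."""
    if x_mUL < 0:
        raise ValueError(f"insulin concentration must be >= 0, got {x_mUL}")
    return x_mUL / INSULIN_NGL_TO_MUL


def classify_bcs(bcs_value: int, bcs_scale: int) -> WeightClassBCS:
    """Lean/overweight from BCS: lean is <=5 on the 1-9 scale, <=3 on 1-5."""
    if bcs_scale not in (5, 9):
        raise ValueError(f"bcs_scale must be 5 or 9, got {bcs_scale}")
    if not 1 <= bcs_value <= bcs_scale:
        raise ValueError(f"BCS {bcs_value} outside 1..{bcs_scale}")
    cut = 5 if bcs_scale == 9 else 3
    return WeightClassBCS.lean if bcs_value <= cut else WeightClassBCS.overweight


def classify_bf(bf_percent: float) -> WeightClassBF:
    """Lean (<35), overweight (35 <= BF% < 45) or obese (>=45).

    Intervals are closed on the left, so 35.0 is overweight and 45.0 obese.
    """
    if not 0 < bf_percent < 100:
        raise ValueError(f"BF% must lie in (0, 100), got {bf_percent}")
    if bf_percent < BF_OVERWEIGHT_CUT:
        return WeightClassBF.lean
    if bf_percent < BF_OBESE_CUT:
        return WeightClassBF.overweight
    return WeightClassBF.obese
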