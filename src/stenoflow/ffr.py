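"""Fractional flow reserve from cycle-averaged pressure drops.

FFR approximates the distal-to-proximal pressure ratio across a lesion as
1 − Δp̄/p̄ₒ, with Δp̄ the cycle-averaged trans-stenotic pressure drop and p̄ₒ
the mean proximal (aortic root) pressure.  Clinical three-class reading:
positive (revascularise) at FFR ≤ 0.75, negative at FFR ≥ 0.80, intermediate
in between.  Both boundaries are closed, exactly as used clinically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "POSITIVE_MAX",
    "NEGATIVE_MIN",
    "DEFAULT_REFERENCE_PRESSURE",
    "FFRResult",
    "classify",
    "ffr",
    "classification_agreement",
]

POSITIVE_MAX = 0.75
NEGATIVE_MIN = 0.80

#: Mean aortic pressure of 100 mmHg in Pa — the reference proximal pressure
#: used when none is supplied.
DEFAULT_REFERENCE_PRESSURE = 13332.2


def classify(value: float) -> str:
    """Three-class clinical reading of an FFR value (closed boundaries)."""
    if value <= POSITIVE_MAX:
        return "positive"
    if value >= NEGATIVE_MIN:
        return "negative"
    return "intermediate"


@dataclass(frozen=True)
class FFRResult:
    """FFR value, inputs and clinical class for one lesion/condition."""

    dp_mean: float
    reference_pressure: float
    value: float
    category: str
    in_range: bool  # False when FFR falls outside [0, 1] (Δp̄ > p̄ₒ or < 0)


def ffr(dp_mean: float, reference_pressure: float = DEFAULT_REFERENCE_PRESSURE) -> FFRResult:
    """FFR = 1 − Δp̄/p̄ₒ with its clinical class.

    Out-of-range values (negative FFR when the drop exceeds the reference
    pressure, or FFR > 1 for a negative drop) are reported as computed and
    flagged via ``in_range`` — never silently clamped.
    """
    if reference_pressure <= 0:
        raise ValueError("reference pressure must be positive")
    value = 1.0 - dp_mean / reference_pressure
    return FFRResult(
        dp_mean=dp_mean,
        reference_pressure=reference_pressure,
        value=value,
        category=classify(value),
        in_range=0.0 <= value <= 1.0,
    )


def _category(item) -> str:
    if isinstance(item, FFRResult):
        return item.category
    if isinstance(item, str):
        return item
    return classify(float(item))


def classification_agreement(
    results_a: Sequence | Iterable, results_b: Sequence | Iterable
) -> float:
    """Fraction of paired cases whose clinical classes differ.

    Accepts FFRResult objects, raw FFR values, or class strings on either
    side, so model output can be compared directly against an externally
    supplied reference column.
    """
    a = [_category(x) for x in results_a]
    b = [_category(x) for x in results_b]
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if not a:
        raise ValueError("empty comparison")
    return sum(x != y for x, y in zip(a, b)) / len(a)
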