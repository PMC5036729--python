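"""The bounded bipolar 0.1–0.9 rating scale and its 1–9 ratio-scale twin.

A ratio rating ``r`` in [1/9, 9] corresponds to the bipolar rating
``r / (1 + r)`` in [0.1, 0.9]; the neutral rating 1 maps to 0.5 and
reciprocal ratios map to complementary ratings (``1/r`` to ``1 - r/(1+r)``).
The nine classical verbal anchors are tabulated in :data:`ANCHORS`.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

__all__ = [
    "ScaleRating",
    "ANCHORS",
    "SCALE_LO",
    "SCALE_HI",
    "saaty_to_cross_ratio",
    "cross_ratio_to_saaty",
    "in_scale",
]

SCALE_LO = 0.1
SCALE_HI = 0.9


@dataclass(frozen=True)
class ScaleRating:
    """One row of the scale correspondence table."""

    saaty_value: float
    cross_ratio_value: float
    label: str = ""


def _anchor(r: Fraction, label: str) -> ScaleRating:
    return ScaleRating(float(r), float(r / (1 + r)), label)


#: The nine verbal anchor points, exact as rationals before float conversion.
ANCHORS: tuple[ScaleRating, ...] = (
    _anchor(Fraction(9), "Absolutely preferred"),
    _anchor(Fraction(7), "Very strongly preferred"),
    _anchor(Fraction(5), "Strongly preferred"),
    _anchor(Fraction(3), "Moderately preferred"),
    _anchor(Fraction(1), "Equally preferred"),
    _anchor(Fraction(1, 3), "Moderately less preferred"),
    _anchor(Fraction(1, 5), "Strongly less preferred"),
    _anchor(Fraction(1, 7), "Very strongly less preferred"),
    _anchor(Fraction(1, 9), "Extremely less preferred"),
)


def saaty_to_cross_ratio(r: float) -> float:
    """Map a 1–9 ratio rating to the bipolar scale: ``r -> r/(1+r)``."""
    r = float(r)
    if not Fraction(1, 9) - 1e-12 <= r <= 9 + 1e-12:
        raise ValueError(f"ratio rating must lie in [1/9, 9], got {r!r}")
    return r / (1.0 + r)


def cross_ratio_to_saaty(v: float) -> float:
    """Inverse map ``v -> v/(1-v)`` from [0.1, 0.9] back to [1/9, 9]."""
    v = float(v)
    if not SCALE_LO - 1e-12 <= v <= SCALE_HI + 1e-12:
        raise ValueError(f"bipolar rating must lie in [0.1, 0.9], got {v!r}")
    return v / (1.0 - v)


def in_scale(x: float, tol: float = 1e-9) -> bool:
    """Whether a component lies in the bounded band [0.1, 0.9]."""
    return SCALE_LO - tol <= x <= SCALE_HI + tol
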