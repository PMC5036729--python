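"""Score, hesitation margin, accuracy and ordering of cross-ratio IFVs.

Two score variants are provided.  Writing ``u = m/(1-m)`` and ``v = n/(1-n)``
for the component odds of a value ``(m, n)``:

* ``"geometric"`` (default) — ``sqrt(u/v)`` normalised back to (0, 1), i.e.
  ``sqrt(m(1-n)) / (sqrt(m(1-n)) + sqrt((1-m)n))``.  This is the variant that
  reproduces the reference case-study figures to every printed digit.
* ``"eq4"`` — the plain odds ratio normalised, ``m(1-n) / (m(1-n) + (1-m)n)``.

Both are strictly increasing transforms of the odds ratio ``u/v``, so they
induce the same strict order; only the reported magnitudes differ.  The
accuracy is the odds product ``u*v`` (equal to 1 exactly for ordinary fuzzy
values) and breaks score ties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from .core import CrossRatioIFV

__all__ = [
    "ScoreVariant",
    "SCORE_VARIANTS",
    "RankedValue",
    "score",
    "hesitation",
    "accuracy",
    "compare",
]

ScoreVariant = Literal["geometric", "eq4"]
SCORE_VARIANTS: tuple[str, ...] = ("geometric", "eq4")

#: Relative tolerance used when comparing odds-space quantities.
_REL_TOL = 1e-10


def _odds(x: float) -> float:
    return x / (1.0 - x)


def _check_variant(variant: str) -> None:
    if variant not in SCORE_VARIANTS:
        raise ValueError(
            f"unknown score variant {variant!r}; expected one of {SCORE_VARIANTS}"
        )


def score(a: CrossRatioIFV, variant: ScoreVariant = "geometric") -> float:
    """Score in (0, 1); 0.5 exactly when membership equals non-membership."""
    _check_variant(variant)
    p = a.membership * (1.0 - a.nonmembership)
    q = (1.0 - a.membership) * a.nonmembership
    if variant == "geometric":
        p = math.sqrt(p)
        q = math.sqrt(q)
    return p / (p + q)


def hesitation(a: CrossRatioIFV) -> float:
    """Hesitation margin ``(1 - m - n) / ((1-m)(1-n))`` in [0, 1).

    Vanishes exactly on ordinary fuzzy values (``m + n = 1``); equals
    ``1 - accuracy``.
    """
    num = 1.0 - a.membership - a.nonmembership
    if num <= 0.0:  # m + n == 1 up to the sum tolerance
        return 0.0
    return num / ((1.0 - a.membership) * (1.0 - a.nonmembership))


def accuracy(a: CrossRatioIFV) -> float:
    """Accuracy ``m n / ((1-m)(1-n))`` in (0, 1]; 1 iff ``m + n = 1``."""
    return min(
        1.0,
        (a.membership * a.nonmembership)
        / ((1.0 - a.membership) * (1.0 - a.nonmembership)),
    )


def compare(a: CrossRatioIFV, b: CrossRatioIFV) -> int:
    """Two-stage order: by score, then by accuracy.

    Returns -1, 0 or 1.  Equality (0) holds exactly when both components
    coincide (within the relative tolerance), since score and accuracy
    together determine the value.  The result does not depend on the score
    variant: both variants are increasing in the same odds ratio.

    Comparisons are made on the exact odds-space quantities ``u/v`` (score
    odds) and ``u*v`` (accuracy) to avoid double rounding.
    """
    ua, va = _odds(a.membership), _odds(a.nonmembership)
    ub, vb = _odds(b.membership), _odds(b.nonmembership)
    ra, rb = ua / va, ub / vb
    if not math.isclose(ra, rb, rel_tol=_REL_TOL):
        return 1 if ra > rb else -1
    ha, hb = ua * va, ub * vb
    if not math.isclose(ha, hb, rel_tol=_REL_TOL):
        return 1 if ha > hb else -1
    return 0


@dataclass(frozen=True)
class RankedValue:
    """A value bundled with its ranking statistics."""

    value: CrossRatioIFV
    score: float
    accuracy: float
    hesitation: float

    @classmethod
    def of(
        cls, a: CrossRatioIFV, variant: ScoreVariant = "geometric"
    ) -> "RankedValue":
        return cls(
            value=a,
            score=score(a, variant),
            accuracy=accuracy(a),
            hesitation=hesitation(a),
        )
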