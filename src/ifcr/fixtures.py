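"""Embedded reference case study: medical waste disposal method selection.

Five disposal methods (incineration, autoclave, microwave, sterilization,
other alternative treatments) are compared pairwise under three criteria
(technical, economic, social-and-environmental) on the bipolar 0.1–0.9
scale, with criterion weights (0.4, 0.35, 0.25).  Cells are kept as exact
fraction strings, so fixture precision exceeds the 4-decimal precision of
the published figures.

``EXPECTED`` collects the published 4-decimal reference figures for
regression testing.  Note the published pipeline carries 4-decimal roundings
forward between stages (the overall priorities were evidently computed from
the rounded decision matrix, and the scores from the re-rounded overall
priorities), so full-precision recomputation can differ from a printed
figure by up to ~1e-4 in the last digit.
"""

from __future__ import annotations

from .aggregation import WeightVector
from .decision import DecisionProblem
from .preference import IPRMatrix
from .core import make_ifv

__all__ = ["mwdms_problem", "EXPECTED", "FIXTURES"]

_ALTS = ("x1", "x2", "x3", "x4", "x5")
_CRITERIA = ("technical", "economic", "social_environmental")
_WEIGHTS = (0.4, 0.35, 0.25)

# one row per alternative; cells (membership, nonmembership) as exact strings
_TECHNICAL = [
    [("0.5", "0.5"), ("5/8", "1/5"), ("7/8", "0.1"), ("3/4", "1/8"), ("0.5", "1/6")],
    [("1/5", "5/8"), ("0.5", "0.5"), ("5/8", "1/5"), ("2/3", "1/6"), ("3/8", "0.5")],
    [("0.1", "7/8"), ("1/5", "5/8"), ("0.5", "0.5"), ("0.5", "3/8"), ("1/5", "5/8")],
    [("1/8", "3/4"), ("1/6", "2/3"), ("3/8", "0.5"), ("0.5", "0.5"), ("3/7", "3/7")],
    [("1/6", "0.5"), ("0.5", "3/8"), ("5/8", "1/5"), ("3/7", "3/7"), ("0.5", "0.5")],
]
_ECONOMIC = [
    [("0.5", "0.5"), ("3/4", "1/8"), ("6/7", "0.1"), ("7/8", "0.1"), ("5/8", "1/5")],
    [("1/8", "3/4"), ("0.5", "0.5"), ("3/4", "1/8"), ("5/8", "1/4"), ("3/7", "3/7")],
    [("0.1", "6/7"), ("1/8", "3/4"), ("0.5", "0.5"), ("6/7", "1/8"), ("3/8", "0.5")],
    [("0.1", "7/8"), ("1/4", "5/8"), ("1/8", "6/7"), ("0.5", "0.5"), ("4/7", "3/8")],
    [("1/5", "5/8"), ("3/7", "3/7"), ("0.5", "3/8"), ("3/8", "4/7"), ("0.5", "0.5")],
]
_SOCIAL = [
    [("0.5", "0.5"), ("3/5", "1/3"), ("2/3", "1/4"), ("3/4", "1/5"), ("5/7", "1/7")],
    [("1/3", "3/5"), ("0.5", "0.5"), ("3/5", "2/7"), ("5/7", "1/4"), ("4/7", "2/7")],
    [("1/4", "2/3"), ("2/7", "3/5"), ("0.5", "0.5"), ("4/7", "2/7"), ("3/7", "3/7")],
    [("1/5", "3/4"), ("1/4", "5/7"), ("2/7", "4/7"), ("0.5", "0.5"), ("3/7", "0.5")],
    [("1/7", "5/7"), ("2/7", "4/7"), ("3/7", "3/7"), ("0.5", "3/7"), ("0.5", "0.5")],
]

FIXTURES = {"mwdms": (_TECHNICAL, _ECONOMIC, _SOCIAL)}


def _matrix(cells) -> IPRMatrix:
    return IPRMatrix(
        tuple(tuple(make_ifv(m, n) for m, n in row) for row in cells),
        _ALTS,
    )


def mwdms_problem() -> DecisionProblem:
    """The embedded medical-waste case study as a ready-to-solve problem."""
    return DecisionProblem(
        alternatives=_ALTS,
        criteria=_CRITERIA,
        criterion_weights=WeightVector(_WEIGHTS),
        relations=tuple(_matrix(t) for t in FIXTURES["mwdms"]),
    )


#: Published 4-decimal reference figures for the case study.
EXPECTED = {
    # decision matrix: row per alternative, (membership, nonmembership) per criterion
    "decision_matrix": (
        ((0.6706, 0.1934), (0.7445, 0.1758), (0.6508, 0.2701)),
        ((0.4654, 0.3783), (0.4688, 0.3901), (0.5457, 0.3763)),
        ((0.2701, 0.6204), (0.3607, 0.5471), (0.4006, 0.4947)),
        ((0.2951, 0.5746), (0.2708, 0.6786), (0.3235, 0.6131)),
        ((0.4311, 0.3925), (0.3925, 0.5000), (0.3545, 0.5314)),
    ),
    "overall": (
        (0.6930, 0.2042),
        (0.4867, 0.3819),
        (0.3321, 0.5640),
        (0.2933, 0.6217),
        (0.3980, 0.4642),
    ),
    "scores": (0.7479, 0.5533, 0.3827, 0.3345, 0.4664),
    "ranking": ("x1", "x2", "x5", "x3", "x4"),
}
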