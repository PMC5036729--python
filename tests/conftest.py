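"""Shared strategies and the independent odds-space oracle.

The oracle works directly on plain ``(odds_membership, odds_nonmembership)``
tuples with textbook formulas — no reuse of the package's log-odds internals
— so each operation can be checked against an independent computation path.
"""

from __future__ import annotations

import math

import pytest
from hypothesis import strategies as st

from ifcr.core import CrossRatioIFV

# component bounds keeping odds within a safely representable range
_LO = 1e-3
_HI = 1.0 - 2e-3


@st.composite
def ifvs(draw, lo: float = _LO, hi: float = _HI) -> CrossRatioIFV:
    """Valid values with components in [lo, hi] and sum <= 1."""
    m = draw(st.floats(lo, hi, allow_nan=False, allow_infinity=False))
    n = draw(st.floats(lo, max(lo, min(hi, 1.0 - m)),
                       allow_nan=False, allow_infinity=False))
    n = min(n, 1.0 - m) if 1.0 - m >= lo else 1.0 - m
    return CrossRatioIFV(m, n)


@st.composite
def banded_ifvs(draw) -> CrossRatioIFV:
    """Values restricted to the bipolar rating band [0.1, 0.9]."""
    m = draw(st.floats(0.1, 0.9, allow_nan=False, allow_infinity=False))
    t = draw(st.floats(0.0, 1.0, allow_nan=False, allow_infinity=False))
    hi_n = min(0.9, 1.0 - m)
    n = 0.1 + t * max(0.0, hi_n - 0.1)
    return CrossRatioIFV(m, max(0.1, min(n, max(hi_n, 0.1))))


@st.composite
def fuzzy_ifvs(draw) -> CrossRatioIFV:
    """Ordinary fuzzy values: membership + nonmembership == 1."""
    m = draw(st.floats(_LO, _HI, allow_nan=False, allow_infinity=False))
    return CrossRatioIFV(m, 1.0 - m)


#: positive scalars for scalar_mul / power, kept moderate to avoid saturation
lams = st.floats(0.05, 20.0, allow_nan=False, allow_infinity=False)

#: exponents for composed-law tests: |logit| stays below the float-saturation
#: threshold (~36.7) even after two stacked powers of extreme components
law_lams = st.floats(0.05, 4.0, allow_nan=False, allow_infinity=False)


# -- odds-space oracle --------------------------------------------------------

def odds_of(a: CrossRatioIFV) -> tuple[float, float]:
    return a.membership / (1 - a.membership), a.nonmembership / (1 - a.nonmembership)


def value_of(u: float, v: float) -> tuple[float, float]:
    return u / (1 + u), v / (1 + v)


def oracle_oplus(a: CrossRatioIFV, b: CrossRatioIFV) -> tuple[float, float]:
    (u1, v1), (u2, v2) = odds_of(a), odds_of(b)
    return value_of(u1 + u2, 1.0 / (1.0 / v1 + 1.0 / v2))


def oracle_otimes(a: CrossRatioIFV, b: CrossRatioIFV) -> tuple[float, float]:
    (u1, v1), (u2, v2) = odds_of(a), odds_of(b)
    return value_of(u1 * u2, v1 * v2)


def oracle_scalar_mul(lam: float, a: CrossRatioIFV) -> tuple[float, float]:
    u, v = odds_of(a)
    return value_of(lam * u, v / lam)


def oracle_power(a: CrossRatioIFV, lam: float) -> tuple[float, float]:
    u, v = odds_of(a)
    return value_of(u**lam, v**lam)


def oracle_icrwg(values, weights) -> tuple[float, float]:
    u = math.prod(odds_of(a)[0] ** w for a, w in zip(values, weights))
    v = math.prod(odds_of(a)[1] ** w for a, w in zip(values, weights))
    return value_of(u, v)


def assert_pair_close(
    got: CrossRatioIFV,
    expected: tuple[float, float],
    rel: float = 1e-10,
    abs_tol: float = 1e-12,
) -> None:
    for g, e in zip((got.membership, got.nonmembership), expected):
        assert math.isclose(g, e, rel_tol=rel, abs_tol=abs_tol), (got, expected)


@pytest.fixture
def mwdms():
    from ifcr.fixtures import mwdms_problem

    return mwdms_problem()
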