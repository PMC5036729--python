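"""Cross-ratio intuitionistic fuzzy values and their algebra.

A :class:`CrossRatioIFV` is a pair ``(membership, nonmembership)`` of strictly
open-unit-interval degrees whose sum does not exceed 1.  The four operations
``oplus``, ``otimes``, ``scalar_mul`` and ``power`` act on both components
through the cross-ratio (odds) transform ``x -> x / (1 - x)``:

* ``oplus``  — membership odds add, non-membership odds combine harmonically;
* ``otimes`` — odds multiply componentwise (the and-like representable
  cross-ratio uninorm ``xy / (xy + (1-x)(1-y))``, neutral element 0.5);
* ``scalar_mul(lam, a)`` — membership odds scale by ``lam``, non-membership
  odds by ``1/lam``;
* ``power(a, lam)`` — both odds are raised to ``lam``.

:class:`OddsPair` exposes the odds-space view directly; it doubles as an
independent oracle representation in the test-suite.

Internally ``otimes``, ``scalar_mul`` and ``power`` work in log-odds space
(they are linear there), which keeps results stable for components very close
to 0 or 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from numbers import Real
from typing import Union

__all__ = [
    "CrossRatioIFV",
    "OddsPair",
    "IFVError",
    "IFVDomainError",
    "IFVConstraintError",
    "make_ifv",
    "parse_component",
    "complement",
    "oplus",
    "otimes",
    "scalar_mul",
    "power",
    "to_odds",
    "from_odds",
    "INDIFFERENT",
    "SUM_TOL",
]

#: Tolerance on the constraint membership + nonmembership <= 1.
SUM_TOL = 1e-9

#: Clamp bounds used by ``make_ifv(..., clamp=True)`` for file input.
_CLAMP_LO = 1e-9
_CLAMP_HI = 1.0 - 1e-9

ComponentLike = Union[Real, str]


class IFVError(ValueError):
    """Base class for invalid intuitionistic fuzzy values."""


class IFVDomainError(IFVError):
    """A component falls outside the open interval (0, 1)."""


class IFVConstraintError(IFVError):
    """membership + nonmembership exceeds 1 (beyond tolerance)."""


def parse_component(value: ComponentLike) -> float:
    """Parse a component given as a number or a string.

    Strings may be decimals (``"0.5"``) or exact fractions (``"5/8"``); the
    fraction is converted to float only after exact rational parsing, so
    ``"1/3"`` is as precise as the float format allows.
    """
    if isinstance(value, str):
        return float(Fraction(value.strip()))
    if isinstance(value, bool):
        raise IFVDomainError(f"component must be a real number, got {value!r}")
    if isinstance(value, Real):
        return float(value)
    raise IFVDomainError(f"component must be a real number or string, got {value!r}")


@dataclass(frozen=True)
class CrossRatioIFV:
    """An intuitionistic fuzzy value with ]0, 1[ components.

    Invariants (checked at construction):

    * ``0 < membership < 1`` and ``0 < nonmembership < 1`` (strict);
    * ``membership + nonmembership <= 1 + SUM_TOL``.

    The hesitancy ``1 - membership - nonmembership`` is derived, not stored.
    """

    membership: float
    nonmembership: float

    def __post_init__(self) -> None:
        mu = self.membership
        nu = self.nonmembership
        for name, x in (("membership", mu), ("nonmembership", nu)):
            if not isinstance(x, Real) or not math.isfinite(x):
                raise IFVDomainError(f"{name} must be a finite real, got {x!r}")
            if not 0.0 < x < 1.0:
                raise IFVDomainError(
                    f"{name} must lie strictly inside (0, 1), got {x!r}"
                )
        if mu + nu > 1.0 + SUM_TOL:
            raise IFVConstraintError(
                f"membership + nonmembership = {mu + nu!r} exceeds 1"
            )

    @property
    def hesitancy(self) -> float:
        """Residual degree ``1 - membership - nonmembership`` (clipped at 0)."""
        return max(0.0, 1.0 - self.membership - self.nonmembership)

    def isclose(self, other: "CrossRatioIFV", tol: float = 1e-9) -> bool:
        """Componentwise equality within absolute tolerance *tol*."""
        return (
            abs(self.membership - other.membership) <= tol
            and abs(self.nonmembership - other.nonmembership) <= tol
        )

    def __str__(self) -> str:
        return f"({self.membership:.6g}, {self.nonmembership:.6g})"


#: The indifference value, neutral element of ``otimes``.
INDIFFERENT = CrossRatioIFV(0.5, 0.5)


@dataclass(frozen=True)
class OddsPair:
    """Odds-space view of a :class:`CrossRatioIFV`.

    ``odds_membership = mu/(1-mu)`` and ``odds_nonmembership = nu/(1-nu)``;
    the sum constraint ``mu + nu <= 1`` becomes ``u * v <= 1``.
    """

    odds_membership: float
    odds_nonmembership: float

    def __post_init__(self) -> None:
        u = self.odds_membership
        v = self.odds_nonmembership
        for name, x in (("odds_membership", u), ("odds_nonmembership", v)):
            if not isinstance(x, Real) or not math.isfinite(x) or x <= 0.0:
                raise IFVDomainError(f"{name} must be a finite positive real, got {x!r}")
        if u * v > 1.0 + SUM_TOL:
            raise IFVConstraintError(
                f"odds product {u * v!r} exceeds 1 (sum constraint violated)"
            )


def make_ifv(
    membership: ComponentLike,
    nonmembership: ComponentLike,
    *,
    clamp: bool = False,
) -> CrossRatioIFV:
    """Build a validated :class:`CrossRatioIFV`.

    Parameters
    ----------
    membership, nonmembership:
        Numbers, or strings holding decimals or exact fractions ("5/8").
    clamp:
        Permissive mode for file input: components within the closed unit
        interval are clamped into ``[1e-9, 1 - 1e-9]`` instead of being
        rejected for sitting on the boundary.  The sum constraint is still
        enforced.

    Raises
    ------
    IFVDomainError
        If a component is outside (0, 1) (outside [0, 1] with ``clamp``).
    IFVConstraintError
        If the components sum to more than 1.
    """
    mu = parse_component(membership)
    nu = parse_component(nonmembership)
    if clamp:
        if not (0.0 <= mu <= 1.0 and 0.0 <= nu <= 1.0):
            raise IFVDomainError(
                f"components ({mu!r}, {nu!r}) outside [0, 1] cannot be clamped"
            )
        mu = min(max(mu, _CLAMP_LO), _CLAMP_HI)
        nu = min(max(nu, _CLAMP_LO), _CLAMP_HI)
    return CrossRatioIFV(mu, nu)


def complement(a: CrossRatioIFV) -> CrossRatioIFV:
    """Swap membership and non-membership; an involution."""
    return CrossRatioIFV(a.nonmembership, a.membership)


# -- odds / log-odds plumbing -------------------------------------------------

# open-interval clamp bounds: results are pulled off exact 0/1 so that the
# algebra stays closed in floating point even when odds saturate
_ALMOST_ONE = math.nextafter(1.0, 0.0)
_ALMOST_ZERO = math.nextafter(0.0, 1.0)


def _logit(x: float) -> float:
    return math.log(x) - math.log1p(-x)

def _expit(t: float) -> float:
    # logistic, stable on both tails
    if t >= 0.0:
        out = 1.0 / (1.0 + math.exp(-t))
    else:
        e = math.exp(t)
        out = e / (1.0 + e)
    return min(max(out, _ALMOST_ZERO), _ALMOST_ONE)

def _from_odds_scalar(u: float) -> float:
    return min(max(u / (1.0 + u), _ALMOST_ZERO), _ALMOST_ONE)


def to_odds(a: CrossRatioIFV) -> OddsPair:
    """Map both components through ``x -> x/(1-x)``."""
    return OddsPair(
        a.membership / (1.0 - a.membership),
        a.nonmembership / (1.0 - a.nonmembership),
    )


def from_odds(o: OddsPair) -> CrossRatioIFV:
    """Inverse of :func:`to_odds`: ``u -> u/(1+u)`` componentwise."""
    return CrossRatioIFV(
        _from_odds_scalar(o.odds_membership),
        _from_odds_scalar(o.odds_nonmembership),
    )


# -- the four operations ------------------------------------------------------

def oplus(a: CrossRatioIFV, b: CrossRatioIFV) -> CrossRatioIFV:
    """Cross-ratio addition.

    Membership: ``(m1 + m2 - 2 m1 m2) / (1 - m1 m2)`` (odds add);
    non-membership: ``n1 n2 / (n1 + n2 - n1 n2)`` (odds combine
    harmonically).  Closed on valid values.
    """
    u = math.exp(_logit(a.membership)) + math.exp(_logit(b.membership))
    va = math.exp(_logit(a.nonmembership))
    vb = math.exp(_logit(b.nonmembership))
    v = (va * vb) / (va + vb)
    return CrossRatioIFV(_from_odds_scalar(u), _from_odds_scalar(v))


def otimes(a: CrossRatioIFV, b: CrossRatioIFV) -> CrossRatioIFV:
    """Cross-ratio multiplication: the uninorm ``xy/(xy + (1-x)(1-y))``
    applied to each component; odds multiply, 0.5 is neutral."""
    m = _expit(_logit(a.membership) + _logit(b.membership))
    n = _expit(_logit(a.nonmembership) + _logit(b.nonmembership))
    return CrossRatioIFV(m, n)


def scalar_mul(lam: float, a: CrossRatioIFV) -> CrossRatioIFV:
    """Scale: membership odds by ``lam``, non-membership odds by ``1/lam``.

    Closed form ``(lam*m/(lam*m + 1 - m), n/(n + lam*(1 - n)))``; requires
    ``lam > 0``.  The accuracy (odds product) is invariant under this map.
    """
    if not (isinstance(lam, Real) and math.isfinite(lam) and lam > 0):
        raise IFVDomainError(f"scalar must be a positive real, got {lam!r}")
    m = _expit(_logit(a.membership) + math.log(lam))
    n = _expit(_logit(a.nonmembership) - math.log(lam))
    return CrossRatioIFV(m, n)


def power(a: CrossRatioIFV, lam: float) -> CrossRatioIFV:
    """Raise both odds to ``lam``: ``(m^lam/(m^lam + (1-m)^lam), ...)``.

    ``lam = 0`` is allowed and yields the neutral value (0.5, 0.5), so that
    zero weights degrade gracefully in aggregation; ``lam < 0`` is rejected.
    """
    if not (isinstance(lam, Real) and math.isfinite(lam) and lam >= 0):
        raise IFVDomainError(f"exponent must be a non-negative real, got {lam!r}")
    if lam == 0:
        return INDIFFERENT
    m = _expit(lam * _logit(a.membership))
    n = _expit(lam * _logit(a.nonmembership))
    return CrossRatioIFV(m, n)
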