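"""Weighted geometric aggregation of cross-ratio IFVs.

The workhorse is :func:`icrwg`, the weighted ``otimes``-product of powered
values.  In odds space this is the componentwise weighted geometric mean:

    component(result) = prod_i x_i^{w_i} / (prod_i x_i^{w_i} + prod_i (1-x_i)^{w_i})

equivalently a weighted arithmetic mean in log-odds space, which is how it is
computed here (no underflow for long inputs; analytically identical).
:func:`icrwgm` is the equal-weights special case.

Two published aggregators that treat the components asymmetrically live in
:mod:`ifcr.aggregation.baseline`; they are for comparison reporting only and
are never used by the decision procedure.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence, Union

from ..core import CrossRatioIFV, _expit, _logit

__all__ = ["WeightVector", "icrwg", "icrwgm"]

_WEIGHT_SUM_TOL = 1e-6


class WeightVector:
    """A vector of non-negative weights summing to 1.

    In strict mode (default) the sum must equal 1 within ``1e-6``; in
    permissive mode (``strict=False``) any positive-sum vector is accepted
    and renormalised.  Individual weights may be 0 (the corresponding value
    then contributes nothing) but must not be negative.
    """

    __slots__ = ("_weights",)

    def __init__(self, weights: Iterable[float], *, strict: bool = True) -> None:
        w = [float(x) for x in weights]
        if not w:
            raise ValueError("weight vector must be non-empty")
        for x in w:
            if not math.isfinite(x) or x < 0.0:
                raise ValueError(f"weights must be finite and >= 0, got {x!r}")
        total = math.fsum(w)
        if strict:
            if abs(total - 1.0) > _WEIGHT_SUM_TOL:
                raise ValueError(
                    f"weights must sum to 1 (got {total!r}); "
                    "pass strict=False to renormalise"
                )
        else:
            if total <= 0.0:
                raise ValueError("weights must have positive sum")
            w = [x / total for x in w]
        self._weights = tuple(w)

    @property
    def weights(self) -> tuple[float, ...]:
        return self._weights

    def __len__(self) -> int:
        return len(self._weights)

    def __iter__(self):
        return iter(self._weights)

    def __getitem__(self, i: int) -> float:
        return self._weights[i]

    def __eq__(self, other) -> bool:
        if isinstance(other, WeightVector):
            return self._weights == other._weights
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self._weights)

    def __repr__(self) -> str:
        return f"WeightVector({list(self._weights)!r})"

    @classmethod
    def equal(cls, m: int) -> "WeightVector":
        """Equal weights ``1/m``."""
        if m < 1:
            raise ValueError("need at least one weight")
        return cls([1.0 / m] * m, strict=False)


WeightsLike = Union[WeightVector, Sequence[float]]


def _as_weight_vector(w: WeightsLike) -> WeightVector:
    return w if isinstance(w, WeightVector) else WeightVector(w)


def icrwg(values: Sequence[CrossRatioIFV], w: WeightsLike) -> CrossRatioIFV:
    """Intuitionistic cross-ratio weighted geometric aggregate.

    Both components are the weighted geometric mean of the input odds.
    Idempotent, monotone and bounded between the componentwise extremes of
    the inputs; maps inputs with all components in [0.1, 0.9] into the same
    band.
    """
    values = list(values)
    wv = _as_weight_vector(w)
    if not values:
        raise ValueError("cannot aggregate an empty sequence of values")
    if len(values) != len(wv):
        raise ValueError(
            f"got {len(values)} values but {len(wv)} weights"
        )
    lm = math.fsum(wi * _logit(v.membership) for v, wi in zip(values, wv))
    ln = math.fsum(wi * _logit(v.nonmembership) for v, wi in zip(values, wv))
    return CrossRatioIFV(_expit(lm), _expit(ln))


def icrwgm(values: Sequence[CrossRatioIFV]) -> CrossRatioIFV:
    """Equal-weights cross-ratio geometric mean."""
    values = list(values)
    if not values:
        raise ValueError("cannot aggregate an empty sequence of values")
    return icrwg(values, WeightVector.equal(len(values)))
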