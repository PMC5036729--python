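"""Published baseline aggregators, kept for comparison reporting only.

Unlike :func:`ifcr.aggregation.icrwg`, both operators below treat membership
and non-membership with different operational rules, which compresses the
gap between the two aggregated degrees.  Nothing in the decision procedure
depends on this module.
"""

from __future__ import annotations

import math
from typing import Sequence

from ..core import CrossRatioIFV
from . import WeightsLike, _as_weight_vector

__all__ = ["ifwg", "ifga_einstein"]


def _check(values: Sequence[CrossRatioIFV], w: WeightsLike):
    values = list(values)
    wv = _as_weight_vector(w)
    if not values:
        raise ValueError("cannot aggregate an empty sequence of values")
    if len(values) != len(wv):
        raise ValueError(f"got {len(values)} values but {len(wv)} weights")
    return values, wv


def ifwg(values: Sequence[CrossRatioIFV], w: WeightsLike) -> CrossRatioIFV:
    """Xu–Yager weighted geometric:
    ``(prod m_i^w_i, 1 - prod (1-n_i)^w_i)``."""
    values, wv = _check(values, w)
    mu = math.prod(v.membership ** wi for v, wi in zip(values, wv))
    nu = 1.0 - math.prod((1.0 - v.nonmembership) ** wi for v, wi in zip(values, wv))
    return CrossRatioIFV(mu, nu)


def ifga_einstein(values: Sequence[CrossRatioIFV], w: WeightsLike) -> CrossRatioIFV:
    """Einstein weighted geometric:

    membership ``2 prod m_i^w_i / (prod (2-m_i)^w_i + prod m_i^w_i)``,
    non-membership
    ``(prod (1+n_i)^w_i - prod (1-n_i)^w_i) / (prod (1+n_i)^w_i + prod (1-n_i)^w_i)``.
    """
    values, wv = _check(values, w)
    pm = math.prod(v.membership ** wi for v, wi in zip(values, wv))
    qm = math.prod((2.0 - v.membership) ** wi for v, wi in zip(values, wv))
    pn = math.prod((1.0 + v.nonmembership) ** wi for v, wi in zip(values, wv))
    qn = math.prod((1.0 - v.nonmembership) ** wi for v, wi in zip(values, wv))
    return CrossRatioIFV(2.0 * pm / (qm + pm), (pn - qn) / (pn + qn))
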