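"""Two-level hierarchical multicriteria decision procedure.

Given one IPR per criterion and a real criterion weight vector, the pipeline
runs:

1. per-criterion local priorities — equal-weights row aggregation of each
   IPR (:func:`ifcr.preference.local_priorities`);
2. the ``n x m`` decision matrix of local priorities;
3. per-alternative overall priorities — weighted aggregation of each decision
   matrix row with the criterion weights (:func:`ifcr.aggregation.icrwg`);
4. scores and accuracies of the overall priorities;
5. a descending total order with explicit tie groups.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Sequence

from .aggregation import WeightVector, icrwg
from .core import CrossRatioIFV
from .preference import IPRMatrix, IPRValidationError, local_priorities, validate_ipr
from .ranking import ScoreVariant, accuracy, compare, score

__all__ = [
    "DecisionProblem",
    "DecisionMatrix",
    "RankingResult",
    "decision_matrix",
    "solve",
]


@dataclass(frozen=True)
class DecisionProblem:
    """Alternatives, weighted criteria, and one IPR per criterion."""

    alternatives: tuple[str, ...]
    criteria: tuple[str, ...]
    criterion_weights: WeightVector
    relations: tuple[IPRMatrix, ...]
    scale_mode: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "alternatives", tuple(self.alternatives))
        object.__setattr__(self, "criteria", tuple(self.criteria))
        object.__setattr__(self, "relations", tuple(self.relations))
        n, m = len(self.alternatives), len(self.criteria)
        if n < 2:
            raise ValueError("need at least 2 alternatives")
        if m < 1:
            raise ValueError("need at least 1 criterion")
        if len(self.criterion_weights) != m:
            raise ValueError(
                f"{m} criteria but {len(self.criterion_weights)} weights"
            )
        if len(self.relations) != m:
            raise ValueError(f"{m} criteria but {len(self.relations)} relations")
        for name, rel in zip(self.criteria, self.relations):
            if rel.n != n:
                raise ValueError(
                    f"relation for criterion {name!r} is {rel.n}x{rel.n}, "
                    f"expected {n}x{n}"
                )
            if rel.labels != self.alternatives:
                raise ValueError(
                    f"relation for criterion {name!r} has labels {rel.labels}, "
                    f"expected {self.alternatives}"
                )

    @property
    def n_alternatives(self) -> int:
        return len(self.alternatives)

    @property
    def n_criteria(self) -> int:
        return len(self.criteria)

    def validate_relations(self) -> None:
        """Raise :class:`IPRValidationError` naming the offending criterion."""
        for name, rel in zip(self.criteria, self.relations):
            report = validate_ipr(rel, scale_mode=self.scale_mode)
            if not report.ok:
                raise IPRValidationError(report, context=f"criterion {name!r}")


@dataclass(frozen=True)
class DecisionMatrix:
    """Alternative-by-criterion grid of local priorities."""

    entries: tuple[tuple[CrossRatioIFV, ...], ...]
    alternatives: tuple[str, ...]
    criteria: tuple[str, ...]

    def entry(self, i: int, l: int) -> CrossRatioIFV:
        return self.entries[i][l]

    def row(self, i: int) -> tuple[CrossRatioIFV, ...]:
        return self.entries[i]


@dataclass(frozen=True)
class RankingResult:
    """Everything the pipeline produces, plus the final order.

    ``order`` lists alternative indices best-first; ``tie_groups`` partitions
    the same indices into groups of pairwise-equal overall priorities (each
    group sorted by input index).  ``ranking`` renders the labels.
    """

    problem: DecisionProblem
    matrix: DecisionMatrix
    overall: tuple[CrossRatioIFV, ...]
    scores: tuple[float, ...]
    accuracies: tuple[float, ...]
    order: tuple[int, ...]
    tie_groups: tuple[tuple[int, ...], ...]
    score_variant: str

    @property
    def ranking(self) -> tuple[str, ...]:
        return tuple(self.problem.alternatives[i] for i in self.order)

    def ranking_expression(self) -> str:
        """Human-readable chain, e.g. ``x1 > x2 = x3 > x4``."""
        parts = []
        for group in self.tie_groups:
            parts.append(" = ".join(self.problem.alternatives[i] for i in group))
        return " > ".join(parts)


def decision_matrix(p: DecisionProblem, *, validate: bool = True) -> DecisionMatrix:
    """Local priorities of every alternative under every criterion."""
    if validate:
        p.validate_relations()
    columns = [
        local_priorities(rel, scale_mode=p.scale_mode, validate=False)
        for rel in p.relations
    ]
    rows = tuple(
        tuple(columns[l][i] for l in range(p.n_criteria))
        for i in range(p.n_alternatives)
    )
    return DecisionMatrix(rows, p.alternatives, p.criteria)


def _tie_groups(order: Sequence[int], overall: Sequence[CrossRatioIFV]):
    groups: list[list[int]] = []
    for i in order:
        if groups and compare(overall[groups[-1][-1]], overall[i]) == 0:
            groups[-1].append(i)
        else:
            groups.append([i])
    return tuple(tuple(sorted(g)) for g in groups)


def solve(
    p: DecisionProblem,
    score_variant: ScoreVariant = "geometric",
    *,
    validate: bool = True,
) -> RankingResult:
    """Run the full pipeline and rank the alternatives.

    The order is by descending score with accuracy breaking ties; exact ties
    (equal score and accuracy) are grouped and kept in input order.  The
    order is identical for both score variants.
    """
    matrix = decision_matrix(p, validate=validate)
    overall = tuple(
        icrwg(matrix.row(i), p.criterion_weights)
        for i in range(p.n_alternatives)
    )
    scores = tuple(score(b, score_variant) for b in overall)
    accuracies = tuple(accuracy(b) for b in overall)
    # stable sort: descending by the two-stage comparison, input index last
    idx = sorted(
        range(p.n_alternatives),
        key=functools.cmp_to_key(lambda i, j: -compare(overall[i], overall[j])),
    )
    order = tuple(idx)
    return RankingResult(
        problem=p,
        matrix=matrix,
        overall=overall,
        scores=scores,
        accuracies=accuracies,
        order=order,
        tie_groups=_tie_groups(order, overall),
        score_variant=score_variant,
    )
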