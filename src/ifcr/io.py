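"""Problem files and result reports.

Problem files are YAML or JSON with keys:

.. code-block:: yaml

    alternatives: [x1, x2, x3]
    criteria:
      - {name: cost, weight: 0.5}
      - {name: risk, weight: 0.5}
    relations:
      cost:
        - ["(0.5, 0.5)", "(3/4, 1/8)", "(0.5, 1/6)"]
        - ["(1/8, 3/4)", "(0.5, 0.5)", "(5/8, 1/5)"]
        - ["(1/6, 0.5)", "(1/5, 5/8)", "(0.5, 0.5)"]
      risk: ...

Cells accept ``"m,n"`` or ``"(m, n)"`` with decimal or fraction components.
Reports are emitted as JSON (full precision plus a 4-decimal ``display``
view, under a versioned schema) or as a plain-text table.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Union

import yaml

from .aggregation import WeightVector
from .core import CrossRatioIFV, IFVError, make_ifv
from .decision import DecisionProblem, RankingResult
from .preference import IPRMatrix

__all__ = [
    "SCHEMA_VERSION",
    "ProblemFormatError",
    "load_problem",
    "problem_to_dict",
    "save_problem",
    "report_dict",
    "format_report_text",
    "write_report",
]

SCHEMA_VERSION = "1"

PathLike = Union[str, Path]


class ProblemFormatError(ValueError):
    """A problem file violates the schema; message carries the location."""


def _err(path: PathLike, where: str, what: str) -> ProblemFormatError:
    return ProblemFormatError(f"{path}: {where}: {what}")


def _parse_cell(raw: Any, path: PathLike, where: str, clamp: bool) -> CrossRatioIFV:
    if isinstance(raw, (list, tuple)) and len(raw) == 2:
        parts = [raw[0], raw[1]]
    elif isinstance(raw, str):
        text = raw.strip()
        if text.startswith("(") and text.endswith(")"):
            text = text[1:-1]
        parts = [p.strip() for p in text.split(",")]
        if len(parts) != 2:
            raise _err(path, where, f"cell {raw!r} is not a pair")
    else:
        raise _err(path, where, f"cell {raw!r} is not a pair")
    try:
        return make_ifv(parts[0], parts[1], clamp=clamp)
    except (IFVError, ValueError, ZeroDivisionError) as exc:
        raise _err(path, where, f"cell {raw!r}: {exc}") from exc


def load_problem(
    path: PathLike,
    *,
    strict_weights: bool = True,
    scale_mode: bool = True,
    clamp: bool = False,
) -> DecisionProblem:
    """Load and fully validate a decision problem from YAML or JSON.

    ``strict_weights=False`` renormalises weight vectors that do not sum
    to 1; ``clamp`` forwards the permissive component clamping of
    :func:`ifcr.core.make_ifv`.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        try:
            data = json.loads(text)
        except json.JSONDecodeError as exc:
            raise _err(path, f"line {exc.lineno}", f"JSON parse error: {exc.msg}")
    else:
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise _err(path, "-", f"YAML parse error: {exc}")
    if not isinstance(data, dict):
        raise _err(path, "top level", "expected a mapping")
    for key in ("alternatives", "criteria", "relations"):
        if key not in data:
            raise _err(path, "top level", f"missing key {key!r}")

    alts = data["alternatives"]
    if not isinstance(alts, list) or not all(isinstance(a, str) for a in alts):
        raise _err(path, "alternatives", "expected a list of strings")
    alternatives = tuple(alts)

    crits = data["criteria"]
    if not isinstance(crits, list) or not crits:
        raise _err(path, "criteria", "expected a non-empty list")
    names: list[str] = []
    weights: list[float] = []
    for k, c in enumerate(crits):
        where = f"criteria[{k}]"
        if not isinstance(c, dict) or "name" not in c or "weight" not in c:
            raise _err(path, where, "expected {name: ..., weight: ...}")
        names.append(str(c["name"]))
        try:
            weights.append(float(c["weight"]))
        except (TypeError, ValueError):
            raise _err(path, where, f"weight {c['weight']!r} is not a number")
    try:
        wv = WeightVector(weights, strict=strict_weights)
    except ValueError as exc:
        raise _err(path, "criteria", str(exc))

    rels = data["relations"]
    if not isinstance(rels, dict):
        raise _err(path, "relations", "expected a mapping criterion -> matrix")
    n = len(alternatives)
    matrices: list[IPRMatrix] = []
    for name in names:
        if name not in rels:
            raise _err(path, "relations", f"missing relation for criterion {name!r}")
        grid = rels[name]
        if not isinstance(grid, list) or len(grid) != n:
            raise _err(path, f"relations[{name!r}]", f"expected {n} rows")
        rows = []
        for i, row in enumerate(grid):
            if not isinstance(row, list) or len(row) != n:
                raise _err(
                    path, f"relations[{name!r}] row {i + 1}", f"expected {n} cells"
                )
            rows.append(
                tuple(
                    _parse_cell(
                        cell, path, f"relations[{name!r}] row {i + 1} col {j + 1}",
                        clamp,
                    )
                    for j, cell in enumerate(row)
                )
            )
        matrices.append(IPRMatrix(tuple(rows), alternatives))

    problem = DecisionProblem(
        alternatives=alternatives,
        criteria=tuple(names),
        criterion_weights=wv,
        relations=tuple(matrices),
        scale_mode=scale_mode,
    )
    problem.validate_relations()
    return problem


def problem_to_dict(p: DecisionProblem) -> dict:
    """Plain-data view of a problem (inverse of :func:`load_problem`)."""
    return {
        "alternatives": list(p.alternatives),
        "criteria": [
            {"name": name, "weight": w}
            for name, w in zip(p.criteria, p.criterion_weights)
        ],
        "relations": {
            name: [
                [f"({e.membership!r}, {e.nonmembership!r})" for e in rel.row(i)]
                for i in range(rel.n)
            ]
            for name, rel in zip(p.criteria, p.relations)
        },
    }


def save_problem(p: DecisionProblem, path: PathLike) -> None:
    path = Path(path)
    data = problem_to_dict(p)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n", encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")


def _pair(v: CrossRatioIFV) -> dict:
    return {
        "membership": v.membership,
        "nonmembership": v.nonmembership,
        "display": f"({v.membership:.4f}, {v.nonmembership:.4f})",
    }


def report_dict(r: RankingResult) -> dict:
    """Machine-readable report: full precision plus 4-decimal display."""
    from . import __version__

    p = r.problem
    return {
        "schema_version": SCHEMA_VERSION,
        "library_version": __version__,
        "score_variant": r.score_variant,
        "alternatives": list(p.alternatives),
        "criteria": [
            {"name": name, "weight": w}
            for name, w in zip(p.criteria, p.criterion_weights)
        ],
        "decision_matrix": {
            alt: {
                crit: _pair(r.matrix.entry(i, l))
                for l, crit in enumerate(p.criteria)
            }
            for i, alt in enumerate(p.alternatives)
        },
        "overall": {alt: _pair(r.overall[i]) for i, alt in enumerate(p.alternatives)},
        "scores": {
            alt: {"value": r.scores[i], "display": f"{r.scores[i]:.4f}"}
            for i, alt in enumerate(p.alternatives)
        },
        "accuracies": {
            alt: {"value": r.accuracies[i], "display": f"{r.accuracies[i]:.4f}"}
            for i, alt in enumerate(p.alternatives)
        },
        "ranking": list(r.ranking),
        "tie_groups": [
            [p.alternatives[i] for i in group] for group in r.tie_groups
        ],
        "ranking_expression": r.ranking_expression(),
    }


def format_report_text(r: RankingResult) -> str:
    """Human-readable report, decision matrix laid out as a table."""
    p = r.problem
    lines = ["Decision matrix (local priorities):"]
    header = "    " + "  ".join(f"{c:<18}" for c in p.criteria)
    lines.append(header.rstrip())
    for i, alt in enumerate(p.alternatives):
        cells = "  ".join(
            f"({e.membership:.4f}, {e.nonmembership:.4f})" for e in r.matrix.row(i)
        )
        lines.append(f"{alt}  {cells}")
    lines.append("")
    lines.append("Overall priorities, scores and accuracies:")
    for i, alt in enumerate(p.alternatives):
        b = r.overall[i]
        lines.append(
            f"{alt}  ({b.membership:.4f}, {b.nonmembership:.4f})"
            f"  S={r.scores[i]:.4f}  H={r.accuracies[i]:.4f}"
        )
    lines.append("")
    lines.append(f"Ranking: {r.ranking_expression()}")
    return "\n".join(lines) + "\n"


def write_report(r: RankingResult, path: PathLike, fmt: str = "json") -> None:
    """Write a report; ``fmt`` is ``"json"`` or ``"text"``."""
    path = Path(path)
    if fmt == "json":
        path.write_text(
            json.dumps(report_dict(r), indent=2) + "\n", encoding="utf-8"
        )
    elif fmt == "text":
        path.write_text(format_report_text(r), encoding="utf-8")
    else:
        raise ValueError(f"unknown report format {fmt!r}")
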