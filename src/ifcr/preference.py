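"""Intuitionistic preference relations (IPRs).

An IPR over ``n`` alternatives is an ``n x n`` matrix of cross-ratio IFVs
with an indifferent diagonal ``(0.5, 0.5)`` and complement-transposed
reciprocity: ``entry(j, i) == complement(entry(i, j))``.  Matrices are stored
in full; :func:`validate_ipr` reports violations instead of silently
repairing them (a ``fix_reciprocity`` helper rebuilds the lower triangle from
the upper on request).

Text format
-----------
One line per matrix row; each cell is ``(m, n)`` with components given as
decimals or exact fractions, e.g. ``(5/8, 1/5)``.  An optional header line
carries the alternative labels, and each data line may start with its row
label.  :func:`parse_ipr` and :func:`serialize_ipr` round-trip canonically.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import CrossRatioIFV, INDIFFERENT, IFVError, complement, make_ifv
from .scale import SCALE_HI, SCALE_LO, in_scale
from .aggregation import icrwgm

__all__ = [
    "IPRMatrix",
    "Violation",
    "ValidationReport",
    "IPRValidationError",
    "validate_ipr",
    "local_priorities",
    "random_ipr",
    "transpose",
    "fix_reciprocity",
    "parse_ipr",
    "serialize_ipr",
]

_PAIR_TOL = 1e-9


def _default_labels(n: int) -> tuple[str, ...]:
    return tuple(f"x{i + 1}" for i in range(n))


@dataclass(frozen=True)
class IPRMatrix:
    """A square grid of cross-ratio IFVs with alternative labels.

    Construction only checks shape; reciprocity and diagonal invariants are
    the business of :func:`validate_ipr`, so malformed input files can be
    loaded, inspected and reported on.
    """

    entries: tuple[tuple[CrossRatioIFV, ...], ...]
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        n = len(self.entries)
        if n < 2:
            raise ValueError("an IPR needs at least 2 alternatives")
        rows = tuple(tuple(row) for row in self.entries)
        if any(len(row) != n for row in rows):
            raise ValueError("IPR matrix must be square")
        object.__setattr__(self, "entries", rows)
        labels = tuple(self.labels) or _default_labels(n)
        if len(labels) != n:
            raise ValueError(f"expected {n} labels, got {len(labels)}")
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return len(self.entries)

    def entry(self, i: int, j: int) -> CrossRatioIFV:
        return self.entries[i][j]

    def row(self, i: int) -> tuple[CrossRatioIFV, ...]:
        return self.entries[i]


@dataclass(frozen=True)
class Violation:
    """One failed invariant, located by 1-based cell coordinates."""

    row: int
    col: int
    kind: str  # "diagonal" | "reciprocity" | "scale"
    message: str

    def __str__(self) -> str:
        return f"cell ({self.row}, {self.col}): {self.kind}: {self.message}"


@dataclass(frozen=True)
class ValidationReport:
    violations: tuple[Violation, ...] = ()

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self) -> str:
        if self.ok:
            return "valid IPR"
        return "\n".join(str(v) for v in self.violations)


class IPRValidationError(ValueError):
    def __init__(self, report: ValidationReport, context: str = "") -> None:
        self.report = report
        prefix = f"{context}: " if context else ""
        super().__init__(f"{prefix}invalid IPR\n{report}")


def validate_ipr(m: IPRMatrix, scale_mode: bool = True) -> ValidationReport:
    """Check diagonal, reciprocity and (optionally) the [0.1, 0.9] band.

    Every violated cell is listed with 1-based coordinates; an empty report
    means the matrix is a well-formed IPR.
    """
    out: list[Violation] = []
    n = m.n
    for i in range(n):
        d = m.entry(i, i)
        if not d.isclose(INDIFFERENT, tol=_PAIR_TOL):
            out.append(
                Violation(i + 1, i + 1, "diagonal", f"expected (0.5, 0.5), got {d}")
            )
    for i in range(n):
        for j in range(i + 1, n):
            a, b = m.entry(i, j), m.entry(j, i)
            if not b.isclose(complement(a), tol=_PAIR_TOL):
                out.append(
                    Violation(
                        j + 1,
                        i + 1,
                        "reciprocity",
                        f"expected complement of {a}, got {b}",
                    )
                )
    if scale_mode:
        for i in range(n):
            for j in range(n):
                e = m.entry(i, j)
                if not (in_scale(e.membership) and in_scale(e.nonmembership)):
                    out.append(
                        Violation(
                            i + 1,
                            j + 1,
                            "scale",
                            f"components of {e} outside [{SCALE_LO}, {SCALE_HI}]",
                        )
                    )
    return ValidationReport(tuple(out))


def local_priorities(
    m: IPRMatrix, *, scale_mode: bool = True, validate: bool = True
) -> tuple[CrossRatioIFV, ...]:
    """Row-wise equal-weights aggregate (diagonal included), one per
    alternative.  When all entries sit in [0.1, 0.9], so do the outputs."""
    if validate:
        report = validate_ipr(m, scale_mode=scale_mode)
        if not report.ok:
            raise IPRValidationError(report)
    return tuple(icrwgm(m.row(i)) for i in range(m.n))


def transpose(m: IPRMatrix) -> IPRMatrix:
    """Transpose; for a valid IPR this equals the entrywise complement."""
    n = m.n
    return IPRMatrix(
        tuple(tuple(m.entry(j, i) for j in range(n)) for i in range(n)),
        m.labels,
    )


def fix_reciprocity(m: IPRMatrix) -> IPRMatrix:
    """Rebuild diagonal and lower triangle from the upper triangle."""
    n = m.n
    rows = [[m.entry(i, j) for j in range(n)] for i in range(n)]
    for i in range(n):
        rows[i][i] = INDIFFERENT
        for j in range(i + 1, n):
            rows[j][i] = complement(rows[i][j])
    return IPRMatrix(tuple(tuple(r) for r in rows), m.labels)


def random_ipr(n: int, seed: int, scale_mode: bool = True) -> IPRMatrix:
    """Deterministic random valid IPR for a given seed.

    Upper-triangle memberships are uniform on the rating band (default
    [0.1, 0.9]); non-memberships uniform on [lo, min(hi, 1 - membership)];
    diagonal and lower triangle are filled by construction, so the result
    always validates.
    """
    if n < 2:
        raise ValueError("an IPR needs at least 2 alternatives")
    lo, hi = (SCALE_LO, SCALE_HI) if scale_mode else (0.01, 0.99)
    rng = np.random.default_rng(seed)
    rows: list[list[Optional[CrossRatioIFV]]] = [[None] * n for _ in range(n)]
    for i in range(n):
        rows[i][i] = INDIFFERENT
        for j in range(i + 1, n):
            mu = float(rng.uniform(lo, hi))
            nu = float(rng.uniform(lo, min(hi, 1.0 - mu)))
            rows[i][j] = CrossRatioIFV(mu, nu)
            rows[j][i] = complement(rows[i][j])
    return IPRMatrix(tuple(tuple(r) for r in rows))  # type: ignore[arg-type]


# -- text round trip ----------------------------------------------------------

_CELL_RE = re.compile(r"\(([^()]*)\)")


class IPRParseError(ValueError):
    def __init__(self, message: str, line: Optional[int] = None,
                 cell: Optional[int] = None) -> None:
        loc = ""
        if line is not None:
            loc = f"line {line}"
            if cell is not None:
                loc += f", cell {cell}"
            loc = f" ({loc})"
        super().__init__(message + loc)
        self.line = line
        self.cell = cell


def _parse_cell(text: str, line_no: int, cell_no: int, clamp: bool) -> CrossRatioIFV:
    parts = [p.strip() for p in text.split(",")]
    if len(parts) != 2:
        raise IPRParseError(
            f"cell {text!r} is not a '(membership, nonmembership)' pair",
            line_no,
            cell_no,
        )
    try:
        return make_ifv(parts[0], parts[1], clamp=clamp)
    except (IFVError, ValueError, ZeroDivisionError) as exc:
        raise IPRParseError(
            f"cell {text!r} is not a valid value: {exc}", line_no, cell_no
        ) from exc


def parse_ipr(text: str, *, clamp: bool = False) -> IPRMatrix:
    """Parse the text format described in the module docstring."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise IPRParseError("empty input")
    header: Optional[list[str]] = None
    if "(" not in lines[0]:
        header = lines[0].replace(",", "\t").split()
        lines = lines[1:]
    rows: list[tuple[CrossRatioIFV, ...]] = []
    row_labels: list[str] = []
    for offset, line in enumerate(lines):
        line_no = offset + (2 if header is not None else 1)
        first = line.find("(")
        if first < 0:
            raise IPRParseError("no '(m, n)' cells found", line_no)
        label = line[:first].strip().rstrip(",;\t")
        if label:
            row_labels.append(label)
        cells = _CELL_RE.findall(line)
        rows.append(
            tuple(
                _parse_cell(cell, line_no, k + 1, clamp)
                for k, cell in enumerate(cells)
            )
        )
    n = len(rows)
    if any(len(r) != n for r in rows):
        raise IPRParseError(
            f"matrix is not square: {n} rows with lengths {[len(r) for r in rows]}"
        )
    labels: tuple[str, ...] = ()
    if row_labels and len(row_labels) == n:
        labels = tuple(row_labels)
    elif header and len(header) == n:
        labels = tuple(header)
    return IPRMatrix(tuple(rows), labels)


def _fmt_component(x: float) -> str:
    return repr(x)


def serialize_ipr(m: IPRMatrix) -> str:
    """Canonical text form; ``serialize -> parse -> serialize`` is the
    identity byte for byte."""
    head = "\t" + "\t".join(m.labels)
    lines = [head]
    for i in range(m.n):
        cells = "\t".join(
            f"({_fmt_component(e.membership)}, {_fmt_component(e.nonmembership)})"
            for e in m.row(i)
        )
        lines.append(f"{m.labels[i]}\t{cells}")
    return "\n".join(lines) + "\n"
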