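"""Factorial design model and results-table I/O.

A simulation study varies ``P`` parameters; parameter ``p`` takes ``n_p``
ordered levels, so the full factorial has ``N = prod(n_p)`` scenarios.
Results live in a rectangular table: one row per scenario, one column per
parameter, and one numeric column per (criterion, method) pair named
``<criterion>__<method>``.  Levels are compared by their *declared* order,
never re-sorted, because simulation studies routinely order numeric levels
decreasingly (e.g. number of studies 20, 10, 5).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Direction",
    "ParameterSpec",
    "FactorialDesign",
    "ResultsTable",
    "Finding",
    "ValidationReport",
    "expand_grid",
    "read_results",
    "write_results",
    "validate_results",
    "read_design",
    "write_design",
]

RESULT_SEP = "__"

_DIRECTIONS = ("as-given", "reversed")


class Direction:
    """Per-parameter level direction: ``as-given`` or ``reversed``.

    The direction is applied to the declared level list before computing
    sort ranks; it is the only re-ordering ever applied to levels.  A
    compatibility helper accepts the ±1 sign convention of older tools.
    """

    AS_GIVEN = "as-given"
    REVERSED = "reversed"

    @staticmethod
    def validate(value: str) -> str:
        if value not in _DIRECTIONS:
            raise ValueError(
                f"unknown direction {value!r}; expected one of {_DIRECTIONS}"
            )
        return value

    @staticmethod
    def from_sign(sign: int) -> str:
        """Map +1 → as-given, −1 → reversed."""
        if sign == 1:
            return Direction.AS_GIVEN
        if sign == -1:
            return Direction.REVERSED
        raise ValueError(f"sign must be +1 or -1, got {sign!r}")


@dataclass(frozen=True)
class ParameterSpec:
    """One simulation parameter: name, ordered levels, direction.

    Parameters
    ----------
    name : str
        Short identifier; also the CSV column name.
    levels : sequence
        Ordered, pairwise-distinct level values (numeric or categorical).
    direction : str
        ``"as-given"`` or ``"reversed"``; applied to ``levels`` before
        any ordering.
    label : str, optional
        Display label for plots; defaults to ``name``.
    """

    name: str
    levels: tuple = ()
    direction: str = Direction.AS_GIVEN
    label: str = ""

    def __init__(self, name, levels, direction=Direction.AS_GIVEN, label=None):
        object.__setattr__(self, "name", str(name))
        levels = tuple(levels)
        if len(levels) < 1:
            raise ValueError(f"parameter {name!r} needs at least one level")
        if len(set(map(repr, levels))) != len(levels):
            raise ValueError(f"parameter {name!r} has duplicate levels: {levels}")
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "direction", Direction.validate(direction))
        object.__setattr__(self, "label", str(label) if label else str(name))

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def ordered_levels(self) -> tuple:
        """Levels after applying the direction."""
        if self.direction == Direction.REVERSED:
            return self.levels[::-1]
        return self.levels

    def rank(self, value) -> int:
        """Sort rank of ``value`` under the declared order and direction."""
        idx = self.level_index(value)
        if self.direction == Direction.REVERSED:
            return self.n_levels - 1 - idx
        return idx

    def level_index(self, value) -> int:
        """Position of ``value`` in the declared (undirected) level list."""
        for i, lev in enumerate(self.levels):
            if _level_eq(lev, value):
                return i
        raise KeyError(f"value {value!r} is not a level of parameter {self.name!r}")

    def with_direction(self, direction: str) -> "ParameterSpec":
        return ParameterSpec(self.name, self.levels, direction, self.label)


def _level_eq(declared, value) -> bool:
    """Declared-level equality: numeric comparison first, string fallback."""
    if declared is value:
        return True
    try:
        if bool(declared == value):
            return True
    except Exception:
        pass
    try:
        return float(declared) == float(value)
    except (TypeError, ValueError):
        return str(declared) == str(value)


@dataclass(frozen=True)
class FactorialDesign:
    """Ordered sequence of parameters, outer loop first."""

    params: tuple

    def __init__(self, params: Iterable[ParameterSpec]):
        params = tuple(params)
        if not params:
            raise ValueError("a design needs at least one parameter")
        names = [p.name for p in params]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate parameter names: {names}")
        object.__setattr__(self, "params", params)

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.params]

    @property
    def n_scenarios(self) -> int:
        """N = product of n_p over all parameters."""
        n = 1
        for p in self.params:
            n *= p.n_levels
        return n

    def __len__(self) -> int:
        return len(self.params)

    def __getitem__(self, name: str) -> ParameterSpec:
        for p in self.params:
            if p.name == name:
                return p
        raise KeyError(f"no parameter named {name!r} in design {self.names}")

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def reordered(self, varnames: Sequence[str],
                  directions: Sequence[str] | None = None) -> "FactorialDesign":
        """The same parameters in a new outer→inner order.

        ``varnames`` must be a permutation of the design's parameter names;
        ``directions``, if given, replaces each parameter's direction.
        """
        if sorted(varnames) != sorted(self.names):
            raise ValueError(
                f"varnames {list(varnames)} is not a permutation of "
                f"design parameters {self.names}"
            )
        params = [self[name] for name in varnames]
        if directions is not None:
            if len(directions) != len(params):
                raise ValueError("one direction per parameter required")
            params = [p.with_direction(d) for p, d in zip(params, directions)]
        return FactorialDesign(params)

    def grid(self) -> pd.DataFrame:
        """All level combinations, innermost parameter cycling fastest."""
        combos = itertools.product(*(p.levels for p in self.params))
        return pd.DataFrame(combos, columns=self.names)


def expand_grid(params: Iterable[ParameterSpec] | FactorialDesign) -> pd.DataFrame:
    """Expand parameters into the full factorial scenario table.

    Rows appear in lexicographic order of the given parameter order
    (declared level order, directions not applied), with the innermost
    parameter cycling fastest; row count is ``prod(n_p)``.
    """
    design = params if isinstance(params, FactorialDesign) else FactorialDesign(params)
    return design.grid()


def result_column(criterion: str, method: str) -> str:
    return f"{criterion}{RESULT_SEP}{method}"


def split_result_column(column: str) -> tuple[str, str]:
    crit, _, meth = column.partition(RESULT_SEP)
    if not meth:
        raise ValueError(f"{column!r} is not a <criterion>__<method> column")
    return crit, meth


class ResultsTable:
    """Scenario rows plus one numeric column per (criterion, method) cell.

    The underlying :class:`pandas.DataFrame` holds the parameter columns,
    the ``<criterion>__<method>`` result columns, and optionally auxiliary
    per-scenario columns (e.g. the true effect used as a plot benchmark).
    """

    def __init__(self, design: FactorialDesign, data: pd.DataFrame,
                 criteria: Sequence[str] | None = None,
                 methods: Sequence[str] | None = None):
        self.design = design
        data = data.reset_index(drop=True)
        missing = [n for n in design.names if n not in data.columns]
        if missing:
            raise ValueError(f"data lacks parameter columns {missing}")
        if criteria is None or methods is None:
            crits: list[str] = []
            meths: list[str] = []
            for col in data.columns:
                if col in design.names or RESULT_SEP not in col:
                    continue
                c, m = split_result_column(col)
                if c not in crits:
                    crits.append(c)
                if m not in meths:
                    meths.append(m)
            criteria = criteria if criteria is not None else crits
            methods = methods if methods is not None else meths
        self.criteria = list(criteria)
        self.methods = list(methods)
        for c in self.criteria:
            for m in self.methods:
                if result_column(c, m) not in data.columns:
                    raise ValueError(
                        f"missing result column {result_column(c, m)!r}"
                    )
        self.data = data

    @property
    def n_rows(self) -> int:
        return len(self.data)

    def result_columns(self) -> list[str]:
        return [result_column(c, m) for c in self.criteria for m in self.methods]

    def aux_columns(self) -> list[str]:
        known = set(self.design.names) | set(self.result_columns())
        return [c for c in self.data.columns if c not in known]

    def values(self, criterion: str, method: str) -> np.ndarray:
        col = result_column(criterion, method)
        if col not in self.data.columns:
            raise KeyError(f"no result column {col!r}")
        return self.data[col].to_numpy(dtype=float)

    def scenario_tuples(self) -> list[tuple]:
        cols = [self.data[n].tolist() for n in self.design.names]
        return list(zip(*cols))

    def copy_with(self, data: pd.DataFrame) -> "ResultsTable":
        return ResultsTable(self.design, data, self.criteria, self.methods)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ResultsTable):
            return NotImplemented
        return (
            self.design.names == other.design.names
            and list(self.data.columns) == list(other.data.columns)
            and self.data.equals(other.data)
        )


@dataclass(frozen=True)
class Finding:
    """One validation finding: what, and where."""

    kind: str  # missing-combination | duplicate-scenario | missing-value | unknown-level
    message: str
    row: int | None = None
    column: str | None = None


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings

    def of_kind(self, kind: str) -> list[Finding]:
        return [f for f in self.findings if f.kind == kind]

    def __str__(self) -> str:
        if self.ok:
            return "validation: no findings"
        return "\n".join(f"[{f.kind}] {f.message}" for f in self.findings)


def validate_results(table: ResultsTable) -> ValidationReport:
    """Check full-factorial completeness, duplicates and missing cells.

    Pure function: the table is not mutated; all findings are reported,
    none raised.
    """
    report = ValidationReport()
    design = table.design

    def key(tup):
        return tuple(design.params[i].level_index(v) for i, v in enumerate(tup))

    seen: dict[tuple, int] = {}
    for i, tup in enumerate(table.scenario_tuples()):
        k = key(tup)
        if k in seen:
            report.findings.append(Finding(
                "duplicate-scenario",
                f"scenario {tup} appears in rows {seen[k]} and {i}",
                row=i,
            ))
        else:
            seen[k] = i

    for combo in itertools.product(*(range(p.n_levels) for p in design.params)):
        if combo not in seen:
            levels = tuple(p.levels[j] for p, j in zip(design.params, combo))
            report.findings.append(Finding(
                "missing-combination",
                f"no row for scenario {dict(zip(design.names, levels))}",
            ))

    for col in table.result_columns():
        vals = table.data[col]
        for i in np.flatnonzero(vals.isna().to_numpy()):
            report.findings.append(Finding(
                "missing-value",
                f"missing value in row {i}, column {col!r}",
                row=int(i), column=col,
            ))
    return report


def _format_level(value) -> str:
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_results(table: ResultsTable, path: str | Path) -> None:
    """Write a results table as RFC-4180 CSV with repr-faithful levels."""
    out = table.data.copy()
    for p in table.design.params:
        out[p.name] = [_format_level(v) for v in out[p.name]]
    for col in out.columns:
        if out[col].dtype.kind == "f":  # shortest round-trippable repr
            out[col] = ["" if np.isnan(v) else repr(v) for v in out[col]]
    out.to_csv(path, index=False)


def read_results(path: str | Path, design: FactorialDesign,
                 require_complete: bool = True) -> ResultsTable:
    """Read a results CSV against a declared design.

    Every parameter value is matched to a declared level (numeric equality
    after parsing, exact string fallback); unknown values, missing result
    columns and duplicate or absent scenarios raise with row/column detail.
    """
    raw = pd.read_csv(path, float_precision="round_trip")
    for p in design.params:
        if p.name not in raw.columns:
            raise ValueError(f"CSV lacks parameter column {p.name!r}")
        matched = []
        for i, cell in enumerate(raw[p.name]):
            try:
                matched.append(p.levels[p.level_index(cell)])
            except KeyError:
                raise ValueError(
                    f"row {i}, column {p.name!r}: value {cell!r} is not a "
                    f"declared level of {p.name!r} (levels: {list(p.levels)})"
                ) from None
        raw[p.name] = matched
    table = ResultsTable(design, raw)
    report = validate_results(table)
    dupes = report.of_kind("duplicate-scenario")
    if dupes:
        raise ValueError(str(dupes[0].message))
    if require_complete:
        absent = report.of_kind("missing-combination")
        if absent:
            raise ValueError(
                f"{len(absent)} scenario(s) of the full factorial are missing; "
                f"first: {absent[0].message}"
            )
    return table


# ---------------------------------------------------------------------------
# Design declaration files (YAML or JSON): list of {name, label, levels,
# direction} under the key ``parameters``.

def read_design(path: str | Path) -> FactorialDesign:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        doc = json.loads(text)
    else:
        doc = yaml.safe_load(text)
    entries = doc["parameters"] if isinstance(doc, dict) else doc
    params = [
        ParameterSpec(
            e["name"], e["levels"],
            direction=e.get("direction", Direction.AS_GIVEN),
            label=e.get("label"),
        )
        for e in entries
    ]
    return FactorialDesign(params)


def write_design(design: FactorialDesign, path: str | Path) -> None:
    doc = {"parameters": [
        {"name": p.name, "label": p.label, "levels": list(p.levels),
         "direction": p.direction}
        for p in design.params
    ]}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
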