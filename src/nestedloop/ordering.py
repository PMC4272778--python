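"""Nested-loop (sign-adjusted lexicographic) ordering of scenarios.

The nested loop plot arranges all scenarios of a factorial simulation
study consecutively on one axis.  The chosen parameter order defines a
nested sequence of loops — the first parameter is the outermost loop —
and within each loop the levels are ranked by declared order, optionally
reversed.  This module computes the permutation, the loop *period* of each
parameter (the run length over which its level stays constant), the step
series drawn as gray reference lines, and the vertical band geometry used
by the renderer.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .design import Direction, FactorialDesign, ResultsTable

__all__ = [
    "StepSegment",
    "ReferenceBand",
    "NestedLoopLayout",
    "nestedloop_reorder",
    "loop_period",
    "step_series",
    "influence_ranking",
]


@dataclass(frozen=True)
class StepSegment:
    """Half-open x-interval [start, end) on which a parameter is constant."""

    start: int
    end: int
    level_index: int  # index into the parameter's declared levels
    level: object

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ReferenceBand:
    """Vertical sub-band (fractions of the reference region) for one parameter.

    ``level_fractions[j]`` is the height, within [y_low, y_high], at which
    declared level ``j`` is drawn; heights ascend with the direction-adjusted
    rank so each loop's reference line rises as the loop progresses.
    """

    param: str
    y_low: float
    y_high: float
    level_fractions: tuple


@dataclass
class NestedLoopLayout:
    """Geometry of a nested-loop ordering.

    Attributes
    ----------
    design : FactorialDesign
        Parameters in plotted (outer→inner) order with effective directions.
    order : numpy.ndarray
        Permutation: ``order[x]`` is the original row index drawn at
        position ``x``.
    x_positions : numpy.ndarray
        Consecutive integers ``0 … N−1``, one per scenario.
    param_steps : dict[str, list[StepSegment]]
        Per parameter, the runs of constant level tiling ``[0, N)``.
    periods : dict[str, int]
        Nominal run length per parameter: the product of the level counts
        of all strictly inner parameters (innermost period = 1).
    bands : dict[str, ReferenceBand]
        Non-overlapping vertical sub-bands, outermost parameter lowest.
    """

    design: FactorialDesign
    order: np.ndarray
    x_positions: np.ndarray
    param_steps: dict = field(default_factory=dict)
    periods: dict = field(default_factory=dict)
    bands: dict = field(default_factory=dict)

    @property
    def n_scenarios(self) -> int:
        return len(self.order)

    def to_json(self, indent: int | None = None) -> str:
        doc = {
            "n_scenarios": self.n_scenarios,
            "varnames": self.design.names,
            "directions": [p.direction for p in self.design.params],
            "order": self.order.tolist(),
            "periods": self.periods,
            "param_steps": {
                name: [[s.start, s.end, s.level_index] for s in segs]
                for name, segs in self.param_steps.items()
            },
            "bands": {
                name: {"y_low": b.y_low, "y_high": b.y_high,
                       "level_fractions": list(b.level_fractions)}
                for name, b in self.bands.items()
            },
        }
        return json.dumps(doc, indent=indent)


def loop_period(design: FactorialDesign, param_name: str) -> int:
    """Run length of constant level for ``param_name`` in nested-loop order.

    Equals the product of the level counts of all parameters strictly
    inner to it in the design's outer→inner order; 1 for the innermost.
    """
    names = design.names
    if param_name not in names:
        raise KeyError(f"unknown parameter {param_name!r}; design has {names}")
    idx = names.index(param_name)
    period = 1
    for p in design.params[idx + 1:]:
        period *= p.n_levels
    return period


def _rank_matrix(table: ResultsTable, design: FactorialDesign) -> np.ndarray:
    """Direction-adjusted level ranks, one column per parameter (outer first)."""
    ranks = np.empty((table.n_rows, len(design)), dtype=np.int64)
    for j, p in enumerate(design.params):
        col = table.data[p.name]
        ranks[:, j] = [p.rank(v) for v in col]
    return ranks


def _runs(values: Sequence) -> list[tuple[int, int]]:
    """Maximal runs of equal consecutive values as (start, end) pairs."""
    runs = []
    start = 0
    for i in range(1, len(values) + 1):
        if i == len(values) or values[i] != values[start]:
            runs.append((start, i))
            start = i
    return runs


def _build_layout(ordered: ResultsTable, design: FactorialDesign,
                  order: np.ndarray) -> NestedLoopLayout:
    n = ordered.n_rows
    layout = NestedLoopLayout(
        design=design,
        order=order,
        x_positions=np.arange(n, dtype=np.int64),
    )
    n_params = len(design)
    complete = n == design.n_scenarios
    for d, p in enumerate(design.params):
        period = loop_period(design, p.name)
        layout.periods[p.name] = period
        idx = [p.level_index(v) for v in ordered.data[p.name]]
        if complete:
            # a segment per loop period: segments also mark loop turns,
            # so a single-level parameter still shows the periodic breaks
            bounds = [(s, s + period) for s in range(0, n, period)]
        else:
            bounds = _runs(idx)
        segs = [
            StepSegment(s, e, idx[s], p.levels[idx[s]])
            for s, e in bounds
        ]
        layout.param_steps[p.name] = segs
        # outermost parameter occupies the lowest sub-band
        y_low = (n_params - 1 - d) / n_params
        y_high = (n_params - d) / n_params
        margin = 0.15  # keep level lines off sub-band borders
        if p.n_levels == 1:
            fracs = (0.5,)
        else:
            heights = np.linspace(margin, 1.0 - margin, p.n_levels)
            # ascend with direction-adjusted rank
            fracs = tuple(
                float(heights[p.rank(level)]) for level in p.levels
            )
        layout.bands[p.name] = ReferenceBand(p.name, y_low, y_high, fracs)
    return layout


def nestedloop_reorder(
    table: ResultsTable,
    varnames: Sequence[str] | None = None,
    directions: Sequence[str] | None = None,
    signs: Sequence[int] | None = None,
) -> tuple[ResultsTable, NestedLoopLayout]:
    """Reorder scenarios into nested-loop order and compute the layout.

    Rows are sorted stably by the tuple of per-parameter level *ranks*,
    where a rank is the level's position in the declared list after
    applying its direction; ``varnames[0]`` is the outermost loop.

    Parameters
    ----------
    table : ResultsTable
        Results in any row order.
    varnames : sequence of str, optional
        Permutation of the design's parameter names, outer→inner.
        Defaults to the design's own order.
    directions : sequence of str, optional
        Per-parameter direction overriding the design's, aligned with
        ``varnames``.
    signs : sequence of int, optional
        Compatibility alternative to ``directions``: +1 = as-given,
        −1 = reversed.

    Returns
    -------
    (ResultsTable, NestedLoopLayout)
        The reordered table and its layout; ``layout.order`` maps plotted
        position → original row index so callers can map back.
    """
    if directions is not None and signs is not None:
        raise ValueError("give either directions or signs, not both")
    if signs is not None:
        directions = [Direction.from_sign(s) for s in signs]
    if varnames is None:
        varnames = table.design.names
    design = table.design.reordered(varnames, directions)

    ranks = _rank_matrix(table, design)
    # lexsort: last key is primary → innermost parameter first in the list
    keys = tuple(ranks[:, j] for j in range(ranks.shape[1] - 1, -1, -1))
    order = np.lexsort(keys)  # stable

    data = table.data.iloc[order].reset_index(drop=True)
    ordered = ResultsTable(design, data, table.criteria, table.methods)
    if ordered.n_rows != design.n_scenarios:
        warnings.warn(
            f"table has {ordered.n_rows} rows but the full factorial has "
            f"{design.n_scenarios}; reference-line geometry is computed from "
            "the observed levels",
            stacklevel=2,
        )
    return ordered, _build_layout(ordered, design, np.asarray(order))


def step_series(layout: NestedLoopLayout, param_name: str) -> list[StepSegment]:
    """The (start, end, level) segments of one parameter's reference line."""
    if param_name not in layout.param_steps:
        raise KeyError(
            f"unknown parameter {param_name!r}; layout has "
            f"{list(layout.param_steps)}"
        )
    return layout.param_steps[param_name]


def influence_ranking(table: ResultsTable, criterion: str,
                      method: str) -> list[tuple[str, float]]:
    """Rank parameters by their influence on one (criterion, method) column.

    The influence score of a parameter is the range (max − min) of the
    per-level means of the column.  Parameters are returned sorted by
    decreasing score (stable: ties keep design order).  The ranking is
    advisory — a suggested outer→inner loop order — and is never applied
    automatically.
    """
    values = table.values(criterion, method)
    if np.all(np.isnan(values)):
        raise ValueError(
            f"column {criterion}__{method} has no non-missing values"
        )
    scores = []
    for p in table.design.params:
        col = table.data[p.name]
        means = []
        for level in p.levels:
            mask = np.array([p.level_index(v) == p.level_index(level)
                             for v in col])
            sub = values[mask]
            sub = np.sort(sub[~np.isnan(sub)])  # row-order-independent sum
            if sub.size == 0:
                raise ValueError(
                    f"level {level!r} of {p.name!r} has no non-missing "
                    f"values in {criterion}__{method}"
                )
            means.append(float(sub.mean()))
        scores.append((p.name, float(max(means) - min(means))))
    return sorted(scores, key=lambda t: -t[1])
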