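"""Rendering of nested loop plots and hybrid Trellis × nested-loop plots.

Every plot call returns a :class:`RenderSummary` — machine-readable counts
(polylines, step segments, panels, axis ranges) — so tests assert geometry,
never pixels.  The gray reference step lines occupy a band below the data:
the lower ``band_fraction`` of the vertical extent is split into P equal
sub-bands, outermost parameter at the bottom, and within a sub-band the
n_p levels map to evenly spaced heights.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")  # headless rendering; no interactive backend assumed
import matplotlib.pyplot as plt
import numpy as np
import yaml

from .design import FactorialDesign, ResultsTable, result_column
from .ordering import NestedLoopLayout, nestedloop_reorder

__all__ = [
    "PlotConfig",
    "PanelSpec",
    "RenderSummary",
    "nested_loop_plot",
    "hybrid_plot",
]

# colorblind-safe 6-way palette (Okabe–Ito subset)
DEFAULT_PALETTE = (
    "#0072B2", "#D55E00", "#009E73", "#CC79A7", "#E69F00", "#56B4E9",
)

# guardrails beyond which a single-axis plot becomes hard to read
MAX_PARAMS_SOFT = 6
MAX_SCENARIOS_SOFT = 1000

_STYLE = {
    "svg.hashsalt": "nestedloop",  # deterministic SVG ids
    "font.size": 9,
}


@dataclass
class PlotConfig:
    """What to draw: one criterion, a set of methods, optional benchmark.

    Parameters
    ----------
    criterion : str
        Criterion whose ``<criterion>__<method>`` columns are plotted.
    methods : sequence of str, optional
        Methods to draw (defaults to all methods of the table); one
        polyline each.
    truth_column : str, optional
        Per-scenario true-value column drawn as a black benchmark step
        function on the criterion's own scale.
    band_fraction : float
        Fraction of the vertical extent reserved below the data for the
        gray reference lines; must lie in (0, 0.5).
    """

    criterion: str
    methods: Sequence[str] | None = None
    truth_column: str | None = None
    band_fraction: float = 0.3
    title: str = ""
    ylabel: str = ""
    palette: Sequence[str] = DEFAULT_PALETTE
    colors: dict = field(default_factory=dict)  # method -> color override

    def __post_init__(self):
        if not (0.0 < self.band_fraction < 0.5):
            raise ValueError(
                f"band_fraction must be in (0, 0.5), got {self.band_fraction}"
            )

    def resolve_methods(self, table: ResultsTable) -> list[str]:
        methods = list(self.methods) if self.methods else list(table.methods)
        if not methods:
            raise ValueError("no methods to plot")
        for m in methods:
            col = result_column(self.criterion, m)
            if col not in table.data.columns:
                raise KeyError(f"result column {col!r} not found in table")
        return methods

    def color_for(self, method: str, index: int) -> str:
        return self.colors.get(method, self.palette[index % len(self.palette)])

    @classmethod
    def from_file(cls, path: str | Path) -> "PlotConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(**doc)


@dataclass(frozen=True)
class PanelSpec:
    """Trellis grid definition: two panel parameters plus the inner order.

    ``row_param`` indexes panel rows, ``col_param`` panel columns, and
    ``inner_order`` (outer→inner) covers exactly the remaining parameters;
    within each panel the matching scenarios appear in nested-loop order
    of ``inner_order``.
    """

    row_param: str
    col_param: str
    inner_order: tuple
    inner_directions: tuple | None = None

    def __init__(self, row_param, col_param, inner_order,
                 inner_directions=None):
        if row_param == col_param:
            raise ValueError("row_param and col_param must differ")
        object.__setattr__(self, "row_param", row_param)
        object.__setattr__(self, "col_param", col_param)
        object.__setattr__(self, "inner_order", tuple(inner_order))
        object.__setattr__(
            self, "inner_directions",
            tuple(inner_directions) if inner_directions is not None else None,
        )

    def validate(self, design: FactorialDesign) -> None:
        panel = {self.row_param, self.col_param}
        inner = set(self.inner_order)
        if panel & inner:
            raise ValueError(
                f"panel parameters {sorted(panel & inner)} also appear in "
                "inner_order"
            )
        expected = set(design.names) - panel
        if inner != expected:
            raise ValueError(
                f"inner_order must cover exactly {sorted(expected)}, "
                f"got {sorted(inner)}"
            )


@dataclass
class RenderSummary:
    """Machine-readable account of a rendered figure."""

    kind: str
    n_panels: int
    n_scenarios: int
    n_polylines: int  # method polylines, summed over panels
    points_per_polyline: dict  # "panel/method" or method -> plotted points
    ref_segments: dict  # parameter -> step-segment count (single panel)
    x_range: tuple
    y_limits: tuple
    panel_shape: tuple = (1, 1)
    scenarios_per_panel: int | None = None
    truth_drawn: bool = False

    def to_json(self, indent: int | None = 2) -> str:
        doc = dict(self.__dict__)
        doc["x_range"] = list(self.x_range)
        doc["y_limits"] = list(self.y_limits)
        doc["panel_shape"] = list(self.panel_shape)
        return json.dumps(doc, indent=indent)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def _soft_guardrails(design: FactorialDesign, n_scenarios: int) -> None:
    if len(design) > MAX_PARAMS_SOFT:
        warnings.warn(
            f"{len(design)} parameters on a single axis; beyond about "
            f"{MAX_PARAMS_SOFT} the plot becomes hard to read",
            stacklevel=3,
        )
    if n_scenarios > MAX_SCENARIOS_SOFT:
        warnings.warn(
            f"{n_scenarios} scenarios on a single axis; beyond about "
            f"{MAX_SCENARIOS_SOFT} consider a hybrid plot",
            stacklevel=3,
        )


def _data_envelope(table: ResultsTable, methods: list[str],
                   config: PlotConfig) -> tuple[float, float]:
    cols = [table.values(config.criterion, m) for m in methods]
    if config.truth_column:
        cols.append(table.data[config.truth_column].to_numpy(dtype=float))
    stacked = np.concatenate(cols)
    finite = stacked[np.isfinite(stacked)]
    if finite.size == 0:
        raise ValueError("nothing to plot: all values missing")
    lo, hi = float(finite.min()), float(finite.max())
    if lo == hi:  # degenerate: flat data
        lo, hi = lo - 0.5, hi + 0.5
    return lo, hi


def _draw_panel(ax, table: ResultsTable, layout: NestedLoopLayout,
                config: PlotConfig, methods: list[str],
                y_lo: float, y_hi: float, x_offset: int = 0,
                draw_refs: bool = True, label_refs: bool = True,
                ) -> tuple[dict, dict]:
    """Draw one nested-loop panel; return (points per method, ref counts)."""
    n = layout.n_scenarios
    x = layout.x_positions + x_offset
    points: dict[str, int] = {}
    for i, m in enumerate(methods):
        y = table.values(config.criterion, m)
        # NaN cells break the line (gap), never interpolated
        ax.plot(x, y, color=config.color_for(m, i), linewidth=0.9, label=m)
        points[m] = int(np.sum(~np.isnan(y)))

    if config.truth_column:
        truth = table.data[config.truth_column].to_numpy(dtype=float)
        ax.step(x, truth, where="post", color="black", linewidth=1.2,
                label="true value")

    ref_counts: dict[str, int] = {}
    if draw_refs:
        data_range = y_hi - y_lo
        total = data_range / (1.0 - config.band_fraction)
        band_h = total - data_range
        band_bottom = y_lo - band_h
        for name, band in layout.bands.items():
            segs = layout.param_steps[name]
            ref_counts[name] = len(segs)
            b_lo = band_bottom + band.y_low * band_h
            b_hi = band_bottom + band.y_high * band_h
            xs, ys = [], []
            for seg in segs:
                h = b_lo + band.level_fractions[seg.level_index] * (b_hi - b_lo)
                xs.extend([seg.start + x_offset, seg.end + x_offset])
                ys.extend([h, h])
            ax.plot(xs, ys, color="0.55", linewidth=0.8)
            if label_refs:
                p = layout.design[name]
                lo_lev, hi_lev = p.ordered_levels()[0], p.ordered_levels()[-1]
                ax.annotate(
                    f"{p.label}: {lo_lev} → {hi_lev}",
                    xy=(x_offset, (b_lo + b_hi) / 2), xycoords="data",
                    fontsize=6, va="center", ha="left", color="0.35",
                    annotation_clip=False,
                )
    else:
        for name, segs in layout.param_steps.items():
            ref_counts[name] = len(segs)

    ax.set_xlim(x_offset - 0.5, x_offset + n - 0.5)
    return points, ref_counts


def _save(fig, out: str | Path | None) -> None:
    if out is None:
        return
    out = Path(out)
    kwargs = {}
    if out.suffix == ".svg":
        kwargs["metadata"] = {"Date": None}  # reproducible bytes
    elif out.suffix == ".pdf":
        kwargs["metadata"] = {"CreationDate": None}
    fig.savefig(out, **kwargs)


def nested_loop_plot(table: ResultsTable, layout: NestedLoopLayout,
                     config: PlotConfig, out: str | Path | None = None,
                     ) -> tuple[plt.Figure, RenderSummary]:
    """Render a single-axis nested loop plot.

    ``table`` must already be in nested-loop order (as returned by
    :func:`nestedloop.ordering.nestedloop_reorder` together with
    ``layout``).  One polyline per method is drawn over x = 0 … N−1,
    the optional truth column as a black step function, and one gray
    reference step line per parameter in the lower band.
    """
    if table.n_rows == 0:
        raise ValueError("empty table: nothing to plot")
    if table.n_rows != layout.n_scenarios:
        raise ValueError(
            f"table has {table.n_rows} rows but layout describes "
            f"{layout.n_scenarios} scenarios"
        )
    methods = config.resolve_methods(table)
    _soft_guardrails(layout.design, table.n_rows)
    y_lo, y_hi = _data_envelope(table, methods, config)

    with plt.rc_context(_STYLE):
        fig, ax = plt.subplots(figsize=(10, 4.5))
        points, ref_counts = _draw_panel(
            ax, table, layout, config, methods, y_lo, y_hi)
        ax.set_xlabel(f"simulation scenarios (n = {table.n_rows})")
        ax.set_ylabel(config.ylabel or config.criterion)
        if config.title:
            ax.set_title(config.title)
        ax.legend(loc="upper right", fontsize=7, frameon=False)
        fig.tight_layout()
        _save(fig, out)

    summary = RenderSummary(
        kind="nested-loop",
        n_panels=1,
        n_scenarios=table.n_rows,
        n_polylines=len(methods),
        points_per_polyline=points,
        ref_segments=ref_counts,
        x_range=(0, table.n_rows - 1),
        y_limits=tuple(float(v) for v in ax.get_ylim()),
        truth_drawn=bool(config.truth_column),
    )
    return fig, summary


def hybrid_plot(table: ResultsTable, panels: PanelSpec, config: PlotConfig,
                out: str | Path | None = None,
                ) -> tuple[plt.Figure, RenderSummary]:
    """Render a Trellis × nested-loop hybrid.

    The table is split into one panel per (row_param, col_param) level
    pair; within each panel the matching scenarios appear in nested-loop
    order of ``panels.inner_order``.  All panels share the y-axis.
    """
    design = table.design
    panels.validate(design)
    methods = config.resolve_methods(table)
    row_p = design[panels.row_param]
    col_p = design[panels.col_param]
    n_rows, n_cols = row_p.n_levels, col_p.n_levels

    inner_tables: dict[tuple[int, int], tuple[ResultsTable, NestedLoopLayout]] = {}
    inner_design = None
    for ri, r_level in enumerate(row_p.ordered_levels()):
        for ci, c_level in enumerate(col_p.ordered_levels()):
            mask = np.array([
                row_p.level_index(v) == row_p.level_index(r_level)
                for v in table.data[panels.row_param]
            ]) & np.array([
                col_p.level_index(v) == col_p.level_index(c_level)
                for v in table.data[panels.col_param]
            ])
            sub = table.data.loc[mask].drop(
                columns=[panels.row_param, panels.col_param])
            sub_design = FactorialDesign(
                [design[n] for n in panels.inner_order])
            sub_table = ResultsTable(sub_design, sub, table.criteria,
                                     table.methods)
            ordered, layout = nestedloop_reorder(
                sub_table, list(panels.inner_order),
                list(panels.inner_directions)
                if panels.inner_directions else None,
            )
            inner_tables[(ri, ci)] = (ordered, layout)
            inner_design = layout.design

    per_panel = next(iter(inner_tables.values()))[0].n_rows
    y_lo = np.inf
    y_hi = -np.inf
    for ordered, _ in inner_tables.values():
        lo, hi = _data_envelope(ordered, methods, config)
        y_lo, y_hi = min(y_lo, lo), max(y_hi, hi)

    points: dict[str, int] = {}
    ref_counts: dict[str, int] = {}
    with plt.rc_context(_STYLE):
        fig, axes = plt.subplots(
            n_rows, n_cols, figsize=(2.2 * n_cols + 1, 1.8 * n_rows + 1),
            sharey=True, squeeze=False,
        )
        for (ri, ci), (ordered, layout) in inner_tables.items():
            ax = axes[ri][ci]
            p, rc = _draw_panel(ax, ordered, layout, config, methods,
                                y_lo, y_hi, label_refs=False)
            for m, cnt in p.items():
                points[f"{ri},{ci}/{m}"] = cnt
            if not ref_counts:
                ref_counts.update(rc)
            ax.tick_params(labelsize=6)
            if ri == 0:
                ax.set_title(f"{col_p.label} = {col_p.ordered_levels()[ci]}",
                             fontsize=7)
            if ci == n_cols - 1:
                ax.annotate(
                    f"{row_p.label}\n= {row_p.ordered_levels()[ri]}",
                    xy=(1.04, 0.5), xycoords="axes fraction", fontsize=7,
                    va="center", ha="left", annotation_clip=False,
                )
        if config.title:
            fig.suptitle(config.title, fontsize=10)
        handles, labels = axes[0][0].get_legend_handles_labels()
        fig.legend(handles, labels, loc="lower center", ncol=len(labels),
                   fontsize=7, frameon=False)
        fig.tight_layout(rect=(0, 0.05, 1, 1))
        _save(fig, out)

    summary = RenderSummary(
        kind="hybrid",
        n_panels=n_rows * n_cols,
        n_scenarios=table.n_rows,
        n_polylines=len(methods) * n_rows * n_cols,
        points_per_polyline=points,
        ref_segments=ref_counts,
        x_range=(0, per_panel - 1),
        y_limits=tuple(float(v) for v in axes[0][0].get_ylim()),
        panel_shape=(n_rows, n_cols),
        scenarios_per_panel=per_panel,
        truth_drawn=bool(config.truth_column),
    )
    return fig, summary
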