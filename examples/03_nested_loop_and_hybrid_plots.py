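"""Render the full 768-scenario nested loop plot and its hybrid variant.

Simulates the bundled grid at a reduced repetition count, draws the
single-axis nested loop plot (one curve for the Peto method, the true
log odds ratio as a black benchmark step function, one gray reference
step line per parameter) and the 4×4-panel hybrid, and prints the render
summaries the plots return.
"""

from pathlib import Path

from nestedloop import (
    PanelSpec,
    PlotConfig,
    example_config,
    hybrid_plot,
    nested_loop_plot,
    nestedloop_reorder,
    run_simulation_study,
)

out = Path("scratch")
out.mkdir(exist_ok=True)

config = example_config(replications=100, seed=7)
print(f"simulating {config.design().n_scenarios} scenarios, "
      f"R={config.replications} ...")
table = run_simulation_study(config)

plot_config = PlotConfig("est", methods=["peto"],
                         truth_column="true_log_or",
                         ylabel="pooled log odds ratio")

ordered, layout = nestedloop_reorder(table)
_, summary = nested_loop_plot(ordered, layout, plot_config,
                              out=out / "nested_loop.svg")
print(f"nested loop plot: {summary.n_scenarios} scenarios on one axis, "
      f"x ∈ [0, {summary.x_range[1]}], "
      f"reference segments per parameter: {summary.ref_segments}")

panels = PanelSpec("or", "selection", ["p_c", "tau2", "k"])
_, hsummary = hybrid_plot(table, panels, plot_config,
                          out=out / "hybrid.svg")
print(f"hybrid plot: {hsummary.n_panels} panels of "
      f"{hsummary.scenarios_per_panel} scenarios each "
      f"(shape {hsummary.panel_shape})")
print(f"figures written to {out}/")
# The outermost parameter (odds ratio) has 4 segments of width 192; the
# innermost (number of studies) turns every scenario.
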