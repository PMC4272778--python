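"""Reorder a factorial results table into nested-loop order.

Builds a small deterministic results table (three parameters, one
method), brings the scenarios into nested-loop order, and prints the loop
geometry: each parameter's period is the number of consecutive scenarios
over which its level stays constant, and its step series is what the gray
reference line at the bottom of the plot draws.
"""

from nestedloop import (
    FactorialDesign,
    ParameterSpec,
    nestedloop_reorder,
    step_series,
    synth_factorial_results,
)

design = FactorialDesign([
    ParameterSpec("effect", [0.0, -0.3, -0.7], label="True effect"),
    ParameterSpec("k", [20, 10, 5], label="Number of studies"),
    ParameterSpec("tau2", [0.0, 0.1], label="Heterogeneity"),
])

table = synth_factorial_results(
    design,
    main_effects={"effect": [0.0, -0.3, -0.7], "k": [0.0, 0.02, 0.05]},
    criteria=["est"], methods=["peto"],
)

ordered, layout = nestedloop_reorder(table)

print(f"{design.n_scenarios} scenarios, outer→inner order: {design.names}")
for name in design.names:
    segs = step_series(layout, name)
    print(f"  {name}: period {layout.periods[name]:>2} "
          f"→ {len(segs)} reference-line segments")
print("first scenarios in plotted order:")
print(ordered.data.head(4).to_string(index=False))
# The period of a parameter is the product of the level counts of all
# parameters inner to it; the outermost parameter changes most slowly.
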