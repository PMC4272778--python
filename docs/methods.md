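# Methods

## The nested-loop ordering

A factorial simulation study with parameters `p = 1…P`, each with `n_p`
ordered levels, has `N = ∏ n_p` scenarios. The nested-loop order is the
lexicographic order of the scenarios under a chosen outer→inner parameter
permutation, where each parameter contributes the *rank* of its level —
its position in the declared level list, reversed when the parameter's
direction is `reversed`. Ranks, not raw values, are the sort keys: this
treats categorical levels ("none < weak < moderate < strong") and
deliberately decreasing numeric orders (20, 10, 5 studies) uniformly, and
no hidden numeric re-sorting ever happens. The sort is stable
(`numpy.lexsort`), so invalid duplicate scenarios keep their input order
and are caught by validation rather than scrambled.

In this order, the level of the parameter at depth `d` is constant over
runs of length `period = ∏ n_q` over all parameters strictly inner to it;
the innermost parameter has period 1. The step series of a parameter is
its sequence of `(start, end, level)` segments. For a complete factorial
we cut a segment at *every* period boundary, not only where the level
changes: segments then number exactly `N / period` and mark the periodic
loop turns even for a single-level parameter. For an incomplete table
(missing scenarios) the layout falls back to run-length encoding of the
observed levels and warns.

Choosing the parameter order is the user's job. `influence_ranking`
offers an advisory heuristic — the influence score of a parameter is the
range of the per-level means of a chosen criterion column — but it is
never applied automatically, because scores of parameters on different
scales are not strictly comparable. A sensible convention: put the
estimand itself outermost, then parameters by decreasing influence, and
order levels "from simple to difficult" scenarios.

## Plot geometry

One polyline per method is drawn over x = 0…N−1 (consecutive integers,
no gaps between loop blocks). Missing cells break the polyline rather
than being interpolated — interpolation would fabricate scenario results.
If a truth column is given it is drawn as a black step function on the
criterion's own scale, so bias is read as the vertical distance between
curve and benchmark. The lower `band_fraction` (default 0.3, must be in
(0, 0.5)) of the vertical extent holds the gray reference lines: it is
split into P equal sub-bands, outermost parameter at the bottom, and
within a sub-band the `n_p` levels map to evenly spaced heights (15%
inner margin) ascending with the direction-adjusted rank. The hybrid
plot splits the table by two panel parameters (panels in direction-
adjusted level order) and applies the same machinery to the remaining
parameters inside each panel, with a shared y-axis.

Plots return a `RenderSummary` (polyline, point, segment and panel
counts, axis ranges) so tests assert geometry, never pixels. SVG/PDF
output is byte-deterministic (fixed hash salt, dates stripped). The
renderer warns — but does not fail — beyond 6 parameters or 1000
scenarios on one axis, where the plot stops being readable; the hybrid
layout is the escape hatch.

## The meta-analysis simulator

The bundled generator emulates a study of selection (publication) bias in
binary-outcome meta-analysis. Its defaults define the 768-scenario grid:

| parameter | levels | direction of ordering |
|---|---|---|
| true odds ratio OR | 1, 0.75, 0.67, 0.50 | effect increasing (OR decreasing from 1) |
| selection strength | none, weak, moderate, strong | increasing |
| control event proportion p_c | 0.30, 0.20, 0.10, 0.05 | decreasing |
| heterogeneity τ² of true log OR | 0, 0.05, 0.10, 0.20 | increasing |
| studies per meta-analysis k | 20, 10, 5 | decreasing |

Per candidate study: a true effect `θ_i ~ N(ln OR, τ²)`; a per-arm sample
size drawn log-uniformly from [25, 400] (one size for both arms), giving
the sample-size spread that makes funnel plots — and selection on
significance — meaningful; control events `~ Binomial(n, p_c)`; treatment
events `~ Binomial(n, p_t)` with `p_t` from the odds transform
`odds_t = e^{θ_i} p_c/(1−p_c)`. Selection: a study whose one-sided
p-value favouring treatment (normal test on the log OR, 0.5 added to all
cells of a table with a zero cell) is below 0.05 is always retained;
otherwise it is retained with probability 1 / 0.75 / 0.5 / 0.25 for
none/weak/moderate/strong. Studies are drawn until k are retained, so k
is controlled by design. Because candidate studies are i.i.d., the
implementation fills R·k retained slots from one vectorized candidate
stream, which is distributionally identical to per-meta-analysis
rejection sampling and orders of magnitude faster.

Retained 2×2 tables are pooled with the Peto one-step method: per study
`O` is the observed treatment-arm event count, `E = n_t m / n` and
`V = n_t n_c m (n−m) / (n² (n−1))` its hypergeometric mean and variance
given the margins, and the pooled log OR is `Σ(O−E)/ΣV` with standard
error `1/√(ΣV)`. Zero cells need no correction here; pooling fails only
if every study's event margin is degenerate (ΣV = 0), which is flagged as
a missing cell, never an abort of the grid.

Per scenario, R repetitions (default 1000) give: mean estimate, bias
(mean − ln OR), variance and MSE with denominator R — so
`mse = bias² + variance` holds to machine precision — coverage of the
nominal 95% Wald interval, and the Monte Carlo standard error
`sd/√R` (sd with denominator R−1). Seeding is hierarchical: the master
seed and the scenario's grid index form a `numpy` seed sequence, so any
scenario is reproducible in isolation and in any order.

### What the simulator does and does not emulate

It reproduces the *structure* and qualitative behaviour of a selection-
bias simulation — unbiasedness of Peto pooling in benign scenarios,
growing bias and collapsing coverage with selection strength, worse
behaviour with rare events — not any specific published data file. The
selection mechanism and sample-size distribution are stylized choices
(exposed in `MetaSimConfig` so other conventions can be matched); real
meta-analyses also feature correlated study designs, non-binomial
outcome processes and selection on effect size rather than significance.
Passing tests therefore certify the plotting and ordering machinery and
the qualitative simulator properties, not quantitative agreement with any
particular real study.

## Problem sizes and tolerances

The test suite and acceptance script use: the full 768-scenario grid at
R = 1000 (about ten seconds, vectorized); targeted benign scenarios
(no selection, τ² = 0, k = 20, p_c = 0.30) at R = 2000 for recovery,
coverage and selection-contrast checks with a 3·MCSE margin; and
R = 25–100 grids for end-to-end pipeline runs where only geometry is
asserted. The coverage band [0.93, 0.97] at R = 2000 is the binomial
tolerance around the nominal 0.95. Ordering is verified against a
brute-force enumerate-and-sort oracle on 100 random designs (≤ 4
parameters, ≤ 4 levels); Peto moments are verified against
`scipy.stats.hypergeom` rather than a re-derivation.

## Known limitations

- Only rectangular (full-factorial) designs are first-class; missing
  scenarios degrade gracefully (warning + observed-level geometry) but
  nested/conditional designs are out of scope.
- The simulator bundles a single pooling method (Peto); the results-table
  format and plots handle any number of methods, and adjusted estimators
  can be supplied as additional `<criterion>__<method>` columns.
- Axis tick labelling of hybrid panels is a configuration choice;
  the package does not infer a "correct" labelling.
- No interactive output; no golden-image tests by design.
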