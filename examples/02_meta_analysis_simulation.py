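"""Simulate selection bias in binary-outcome meta-analysis.

Runs a reduced grid of the bundled simulation — true odds ratio 1 (no
effect), four selection strengths, 500 meta-analyses per scenario — and
prints how the Peto estimate of the pooled log odds ratio degrades as
publication selection strengthens.  Without selection the estimate is
essentially unbiased; when mostly significant studies survive, the pooled
estimate drifts away from zero.
"""

from nestedloop import example_config, run_simulation_study

config = example_config(
    or_levels=(1.0,),
    p_c_levels=(0.30,),
    tau2_levels=(0.0,),
    k_levels=(10,),
    replications=500,
    seed=42,
)
table = run_simulation_study(config)

print("true log OR = 0; Peto pooled estimate per selection strength:")
print(f"{'selection':>10} {'bias':>9} {'mcse':>8} {'coverage':>9}")
for _, row in table.data.iterrows():
    print(f"{row['selection']:>10} {row['bias__peto']:>9.4f} "
          f"{row['mcse__peto']:>8.4f} {row['coverage__peto']:>9.3f}")
# Bias grows (and CI coverage collapses) with selection strength: the
# retained studies over-represent significant, treatment-favouring results.
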