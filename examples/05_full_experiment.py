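"""The full simulated experiment, end to end.

Draws a 14 + 14 cohort, runs one adaptive staircase per participant and
continuum (order counterbalanced), converts thresholds to Relative
Threshold Indices, and runs the group statistics: a 2x3 mixed ANOVA,
one-tailed group comparisons per continuum, paired continuum contrasts and
practice correlations, all FDR-controlled.
"""

from syldiscrim import RunConfig, run_experiment

bundle = run_experiment(RunConfig(master_seed=1, outdir="example_output/run"))

print(bundle["stats"].summary())
print()
table = bundle["rti_table"]
print(table.groupby(["continuum", "group"])["rti"].mean().round(3))
print("\nExpected pattern: musicians lead on /ba/-/wa/ and /ga/-/ka/ but not"
      "\n/ba/-/da/ — the simulated cohort encodes a temporal-only advantage"
      "\nand the pipeline recovers it from the adaptive tracks alone.")
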