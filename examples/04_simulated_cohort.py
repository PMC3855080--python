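"""Sample a simulated musician / non-musician cohort.

The generator draws, per participant and continuum, a latent relative
threshold index (RTI): musicians get a mean advantage on the two temporal
continua only, and training years add a small within-group slope, so the
pooled years-vs-RTI correlation on /ba/-/wa/ lands near 0.5.
"""

from scipy.stats import pearsonr

from syldiscrim import CohortSpec, build_continuum, sample_cohort

continua = {n: build_continuum(n) for n in ("ba_da", "ba_wa", "ga_ka")}
cohort = sample_cohort(CohortSpec(), continua, seed=3)

print(cohort.groupby(["continuum", "group"])["true_rti"].mean().round(3))
print()
years = cohort.query("continuum == 'ba_wa'")
r, p = pearsonr(years["years"], years["true_rti"])
print(f"pooled years vs /ba/-/wa/ RTI: r = {r:.2f} (p = {p:.3g})")
print("\nTemporal continua show the musician advantage; the spectral one"
      "\ndoes not, and training years track the temporal thresholds.")
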