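"""Between-platform agreement statistics on a synthetic cohort.

Replicate-averaged frequencies from the two platforms are compared per
donor: Bland-Altman bias and 95% limits of agreement (with the log-scale
percent-bias reading for multiplicative effects), a normality-gated paired
test against the Bonferroni-corrected threshold 0.05/24, intra-assay CV
over triplicates, and the stain index of a marker's intensity separation.
"""

import numpy as np

import cytoscreen as cs

spec = cs.CohortSpec(n_donors=12, n_replicates=3, n_events_per_sample=3000,
                     seed=5)
samples, metadata, truth = cs.generate_cohort(spec)
res = cs.run_screen(samples, metadata, cs.default_pregate_config(spec),
                    spec.panel)

donors = sorted(metadata["donor"].unique())
il10_cfp = [res.averaged.loc["IL10+", f"{d}/CFP"] for d in donors]
il10_lfp = [res.averaged.loc["IL10+", f"{d}/LFP"] for d in donors]

ba = cs.bland_altman(il10_cfp, il10_lfp, scale="log")
print(f"IL-10+ Bland-Altman (log scale, CFP - LFP, n={ba.n} donors):")
print(f"  bias {ba.bias:+.3f}, 95% LoA [{ba.loa_lower:+.3f}, {ba.loa_upper:+.3f}]")
print(f"  percent bias: CFP reads {ba.percent_bias:.1f}% lower than LFP "
      "(programmed: 44%)")

pt = cs.paired_test(il10_cfp, il10_lfp)
print(f"\npaired test: {pt.test}, p = {pt.p:.2e}, "
      f"threshold 0.05/24 = {pt.threshold:.4f}, significant = {pt.significant}")

# intra-assay CV of CD4+ over the triplicates of one platform
cfp = metadata[metadata["group"] == "CFP"]
freq = res.table.frequencies.loc["CD4+"]
values = [freq[s] for s in cfp["sample_id"]]
cv = cs.cv_triplicates(values, list(cfp["donor"]))
print(f"\nCD4+ intra-assay CV over triplicates (CFP): "
      f"median {cv['cv_percent'].median():.1f}% across {len(cv)} donors")

# stain index of Foxp3 using ground-truth component membership
em = samples[0]
states = truth.events[em.sample_id]["Foxp3"].to_numpy()
vals = em.marker_values("Foxp3")
si = cs.stain_index(vals[states], vals[~states])
print(f"\nFoxp3 stain index: D={si.d:.2f}, W={si.w:.2f}, SI={si.si:.2f} "
      f"(model target {spec.intensity['Foxp3'].target_stain_index:.1f})")
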