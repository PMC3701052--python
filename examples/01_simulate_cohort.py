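"""Simulate a paired two-platform cohort with known ground truth.

Builds the default study design scaled down (4 donors, triplicate, both
platforms), prints the sample grid and a few ground-truth population
frequencies.  The printed frequencies are exact recounts of the generated
event labels, so they are what every downstream stage should recover.
"""

import cytoscreen as cs
from cytoscreen.lattice import POS, Phenotype

spec = cs.CohortSpec(n_donors=4, n_replicates=3, n_events_per_sample=3000,
                     seed=42)
samples, metadata, truth = cs.generate_cohort(spec)

print(f"{len(samples)} samples "
      f"({spec.n_donors} donors x 2 platforms x {spec.n_replicates} replicates), "
      f"{spec.n_events_per_sample} events each")
print(metadata.head(6).to_string(index=False))

print("\nGround-truth frequencies (per live singlet T cell), sample", samples[0].sample_id)
sid = samples[0].sample_id
root = Phenotype.root(spec.panel)
for marker in ("CD4", "CD8", "IL10", "IFNg"):
    f = truth.truth_frequency(sid, root.with_state(marker, POS))
    print(f"  {marker}+ : {f:.4f}")

il10 = root.with_state("IL10", POS)
cfp = [truth.truth_frequency(s, il10)
       for s in metadata.loc[metadata.group == "CFP", "sample_id"]]
lfp = [truth.truth_frequency(s, il10)
       for s in metadata.loc[metadata.group == "LFP", "sample_id"]]
ratio = (sum(cfp) / len(cfp)) / (sum(lfp) / len(lfp))
print(f"\nIL-10+ mean frequency ratio CFP/LFP = {ratio:.3f} "
      f"(programmed: 0.56 — the conventional platform reads IL-10 44% lower)")
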