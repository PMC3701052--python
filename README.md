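# cytoscreen

Exhaustive immunophenotype screening for two-group flow cytometry studies.

`cytoscreen` is for immunologists and cytometry analysts who want to replace
manual biomarker hunting across bivariate dot plots with an unbiased screen:
given event-level data from two groups of samples (two clinical groups, two
staining platforms, treated vs untreated), it enumerates **every**
marker-combination phenotype a panel can express, scores each one as a
group discriminator, organises the winners into an optimized gating
hierarchy, and quantifies between-platform agreement. A bundled synthetic
cohort generator with full ground truth makes every stage testable without
access to real data.

## The method

**Phenotype lattice.** Each of the *k* panel markers is assigned one of
three states — positive (`+`), negative (`−`), or neutral (unconstrained) —
so a panel spans 3^k phenotypes; excluding the all-neutral root leaves
3^k − 1 (6560 for the default 8-marker T-cell panel CD4, CD8, CD45RO, CD25,
Foxp3, IFN-γ, IL-10, IL-17A; restricting to fully specified `+/−`
combinations gives the familiar 2^k, e.g. 1024 for a ten-colour panel).
Events are first pre-gated to live, singlet, CD3⁺ T cells; frequencies are
counts over that denominator. Per-marker positivity thresholds come from an
exact 1-D two-means partition, fitted per sample for well-separated markers
and on all samples pooled (a static gate) for rare markers such as IL-10,
IL-17A and Foxp3.

**Discrimination.** A phenotype's per-sample frequency is treated as a
classifier score for the binary group label. Its AUC is the Mann–Whitney
rank statistic

&nbsp;&nbsp;AUC = P(X_B > X_A) + ½·P(X_B = X_A),

folded to [0.5, 1] with the kept orientation recorded; sensitivity,
specificity and accuracy are reported at the Youden-optimal threshold.
Phenotypes with AUC strictly above 0.9 become candidates (plus any
force-included single-marker populations), and candidates must clear the
same cutoff on an independent replication cohort to be confirmed.

**Hierarchy.** For a selected terminal with *m* specified markers, the
space of gating orders is the 2^m subset lattice of its constraints. A
dynamic program finds the marker-addition path from the root maximising the
cumulative AUC of visited populations — exactly, without enumerating the
*m*! orders. Paths are merged into a DAG whose edge weights are the AUC
gained per added marker (they telescope to AUC(terminal) − AUC(root)),
exported as Graphviz DOT.

**Platform agreement.** Paired per-donor frequencies from the two platforms
are compared with Bland–Altman 95% limits of agreement (bias ± 1.96·SD of
the differences; on the log scale the bias is also reported as a percent
difference), a paired t test gated by the D'Agostino–Pearson normality test
(Wilcoxon signed-rank otherwise) at the Bonferroni-corrected threshold
0.05/24 ≈ 0.002, intra-assay CV over experimental triplicates, and the
stain index SI = D/W with D the positive–negative median difference and
W = 2 × robust SD (1.4826·MAD) of the negatives.

## Worked example

```python
import cytoscreen as cs

spec = cs.CohortSpec(n_donors=8, n_replicates=3,
                     n_events_per_sample=3000, seed=7)
samples, metadata, truth = cs.generate_cohort(spec)
res = cs.run_screen(samples, metadata,
                    cs.default_pregate_config(spec), spec.panel)

for marker in spec.panel:
    best = res.scores.loc[[f"{marker}+", f"{marker}-"], "auc"].max()
    print(f"{marker:7s} {best:.3f}")
```

prints the best single-marker AUC per panel marker:

```
CD4     0.500
CD8     0.531
CD45RO  0.578
CD25    1.000
Foxp3   1.000
IFNg    1.000
IL10    1.000
IL17A   0.516
```

The generator programs platform effects on exactly four markers — IL-10
(the conventional platform reads 44% lower), IFN-γ (20% lower), CD25 and
Foxp3 (elevated on the plate platform) — and the screen ranks precisely
those four at AUC 1.0 while the untouched markers stay near the 0.5 chance
level. Running the Bland–Altman comparison on the replicate-averaged IL-10⁺
frequencies of a 12-donor cohort (`examples/04_platform_agreement.py`):

```
IL-10+ Bland-Altman (log scale, CFP - LFP, n=12 donors):
  bias -0.547, 95% LoA [-0.684, -0.411]
  percent bias: CFP reads 42.1% lower than LFP (programmed: 44%)
paired test: paired-t, p = 1.23e-09, threshold 0.05/24 = 0.0021, significant = True
```

i.e. the log-scale percent bias recovers the programmed 44% reduction and
the paired test flags it far below the corrected threshold.

The `examples/` directory holds one short script per capability
(simulation, the exhaustive screen, hierarchy building, agreement
statistics); each prints what it computes and what the numbers mean. A
`cytoscreen` command-line interface runs the same stages as subcommands
(`simulate`, `pregate`, `partition`, `phenotype`, `score`, `hierarchy`,
`agree`, `all`) from one TOML config, with byte-reproducible artifacts
under a fixed seed.

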