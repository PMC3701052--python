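# Methods

This note documents the models, conventions and numerical choices behind
`cytoscreen`, in the spirit of a statistical software methods appendix: what
is computed, under which assumptions, and where the open design choices
landed.

## Data model and transforms

An `EventMatrix` holds one physical sample: events × channels, each channel
tagged with a role (scatter-area, scatter-height, viability, marker).
Fluorescence and viability channels are analysed on the arcsinh scale,
x ↦ asinh(x / c), with a default cofactor c = 150 — the conventional choice
for organic-dye cytometry — configurable per channel. The transform state
is recorded on the matrix and applying it twice is an error; thresholds are
always expressed on the transformed scale. Because asinh is strictly
monotone, threshold gates commute with the transform when thresholds are
co-transformed, which is tested as a property.

FCS support is deliberately minimal: single-dataset FCS 3.0/3.1 files with
float list-mode data are read, and FCS 3.1 (float32, little-endian) is
written, with channel roles and cofactors carried in vendor keywords.
Channel-to-marker mapping is taken from an explicit channel map rather than
guessed from `$PnS`, since keyword conventions vary by instrument. A plain
TSV event format exists for fixtures and diffable artifacts.

## Pre-gating

Samples are reduced to live, singlet, CD3⁺ T cells in a fixed order:
debris (scatter-area box) → doublets (area/height ratio) → live (viability
dye strictly below threshold, since amine-reactive dyes stain dead cells
bright) → CD3⁺. Boundary conventions are explicit: the live gate is strict
(<); interval and positivity gates are closed at the lower edge and open at
the upper. The order of the viability and CD3 gates is a package
convention; retention counts are reported per gate so either convention can
be audited. A sample-level QC rule mirrors an acquisition stopping gate:
samples with fewer than `min_live_cd4` live CD4⁺ events (default 40 000;
"reaching" the gate reads as ≥) fail QC and are excluded. Pre-gating is a
pure row subset and idempotent, both tested.

## Marker partitioning

Each marker receives one positivity threshold on the transformed scale; an
event is positive strictly above it. The partition is a 1-D two-means
solved **exactly**: optimal 1-D clusters are contiguous in sorted order, so
scanning every split of the sorted values with prefix sums finds the global
within-cluster-sum-of-squares optimum in O(n log n), deterministically and
with no seeding. (A seeded Lloyd iteration with quantile restarts was
considered and rejected: it is not guaranteed to reach the optimum that the
brute-force oracle demands, and exactness costs nothing at these sizes.)
The threshold is the midpoint of the two cluster means.

This marker-wise 1-D partition is a deliberate simplification of
multivariate clustering tools used for the same purpose: the downstream
phenotype space is defined marker-wise (+/−), so one axis at a time is what
is consumed. Fits are flagged low-confidence when Ashman's
D = |μ₁ − μ₂| / √((σ₁² + σ₂²)/2) falls below 2 or the minority cluster
holds under 0.5% of events; the threshold is still returned.

Rare populations (IL-10⁺, IL-17A⁺, Foxp3⁺ by default, plus any marker whose
per-sample positive fraction falls below 1% in a majority of samples) are
invisible to per-sample fits, so those markers use a pooled static gate:
the same two-means on the concatenation of all samples, yielding one shared
threshold — order-invariant by construction. Manual per-marker overrides
take precedence over both.

## The phenotype lattice

With marker states {positive, negative, neutral}, a k-marker panel spans
3^k phenotypes (6560 excluding the root for the 8-marker default panel;
2^k = 1024 fully specified combinations for ten markers). CD3 is not a
lattice dimension: it is consumed by pre-gating and frequencies are defined
per live T cell, which is also what makes 3^8 − 1 the natural phenotype
count for this panel.

Counting does not scan the event matrix 3^k times. The 2^k fully-specified
contingency table is tallied once per sample (`bincount` over base-2 event
codes), and neutral states are obtained marker by marker as sibling sums —
each parent count reuses its children. Correctness is defined by the
brute-force per-event filter and by exact sibling-sum conservation
(freq(parent) = freq(parent∧M⁺) + freq(parent∧M⁻)), both enforced in tests
over the full lattice of small panels.

Frequencies are exact count/denominator ratios; the root row is 1 in every
sample. Replicate averaging (per donor × group) is an explicit aggregation
step applied before scoring, on by default, matching the triplicate design.

## Discrimination and replication

The AUC is the Mann–Whitney statistic computed from midranks, so ties are
credited ½ exactly; the package value must equal the all-pairs brute-force
count, which the tests assert for group sizes up to 50 including heavy
ties. The reported AUC is folded to [0.5, 1] and the orientation
(higher/lower in group B) recorded. Sensitivity TP/(TP+FN), specificity
TN/(TN+FP) and accuracy (TP+TN)/(TP+TN+FP+FN) are evaluated at the Youden
threshold, taken over midpoints of adjacent observed frequencies (ties in
the Youden index break toward the lower threshold). Constant-frequency
phenotypes score 0.5 and are flagged degenerate rather than aborting a
whole screen.

Selection is strict: AUC > cutoff (default 0.9), plus a configurable
force-include list defaulting to the single-marker populations CD4⁺,
Foxp3⁺, IL-17A⁺ and CD8⁺ so that every single-marker phenotype of interest
appears in the hierarchy regardless of score. No multiple-testing
correction is applied to the AUC screen — selection is a pure cutoff — but
a seeded label-permutation null is available as a diagnostic. Replication
re-scores chosen phenotypes on an independent cohort and confirms only
those again strictly above the cutoff.

## Hierarchy optimization

For a terminal with m specified markers, a path is an order in which the
constraints are added from the root. The path score is the cumulative AUC
of the visited populations (root excluded, terminal included), favouring
routes through strong intermediate gates; terminal-only and min-node scores
are available behind the same interface. The optimum is found by dynamic
programming over the 2^m subset lattice, keeping the top-n partial paths
per subset with deterministic code-based tie-breaking; tests require exact
agreement with full m! enumeration for m ≤ 5. Merged hierarchies attach
AUC to nodes and ΔAUC to edges, so weights telescope along every path;
negative-gain edges are rendered at hairline width rather than dropped,
preserving path validity. DOT output is byte-deterministic (sorted nodes
and edges, fixed colour buckets over AUC).

## Agreement statistics

* **Bland–Altman**: differences are method A − method B; bias is their mean
  and the 95% limits of agreement are bias ± 1.96·SD with the sample (n−1)
  SD — the denominator choice is a documented package convention. On the
  log scale (natural log; base is a package choice), the bias is also
  reported as 100·(1 − exp(bias)): the average percent by which method A
  reads below method B, the natural summary when the bias is proportional
  to the frequency.
* **Paired tests**: the D'Agostino–Pearson omnibus test on the differences
  gates the branch at α = 0.05 — paired two-tailed t if normality is not
  rejected, Wilcoxon signed-rank otherwise (exact distribution for n ≤ 25
  without ties/zeros, normal approximation with continuity correction
  above). The omnibus test is undefined below 8 observations; such inputs
  take the Wilcoxon branch and are flagged. Significance is declared at
  the Bonferroni-corrected threshold α/m (default 0.05/24 ≈ 0.002).
* **Intra-assay CV**: 100·sd/mean per donor over experimental triplicates,
  sample SD; zero-mean donors are flagged rather than given an infinite CV.
* **Stain index**: SI = D/W, D = median(pos) − median(neg),
  W = 2·rSD(neg) with rSD = 1.4826·MAD — a robust, distribution-consistent
  spread estimate; the definition is tagged in the result so alternative
  rSD conventions can be compared.

## The synthetic cohort generator

The generator emulates a paired platform-comparison study: the same donors
(default 12, as in a typical healthy-volunteer comparison cohort) measured
on two platforms (groups "CFP" and "LFP"), in experimental triplicate, with
a 9-marker T-cell panel plus viability and forward-scatter area/height.

* **Composition**: events are a small CD3⁻ fraction (5%), plus live T cells
  split among a CD4⁺CD8⁻ population (60%), a CD8⁺CD4⁻ population (28%) and
  a double-negative background (remainder). Memory, activation and
  cytokine markers are Bernoulli within each population (e.g. CD45RO 45%
  and IL-10 2% of CD4 T cells) — fixture values approximating a healthy
  stimulated T-cell compartment, not claims about any dataset.
* **Variability**: donor effects and replicate noise act additively on the
  log-ratio of each population to the background (a logistic-normal
  composition — the multivariate form of a logit-scale effect), which
  keeps every draw on the simplex; marginal logit shifts were rejected
  because independent draws can push a near-full composition past total
  frequency 1. Marker rates get donor logit shifts (SD 0.10) and
  multiplicative replicate noise (CV 5%); donor effects are shared between
  the platforms, making the design genuinely paired. The modest
  between-donor SD emulates a standardized cohort in which the platform
  effect dominates donor-to-donor spread — the regime in which a
  cutoff-based AUC screen is the appropriate instrument.
* **Platform effects**: group-B/group-A frequency ratios, default IL-10
  1/0.56 (the conventional platform reads 44% lower), IFN-γ 1.25 (20%
  lower, inside the 15–26% range the design emulates), CD25 1.6 and Foxp3
  1.8 (elevated on the plate platform). Ratios apply to marker rates and
  to any population whose pattern fixes that marker positive; a
  composition exceeding 1 after multipliers is rejected with the offending
  sample named.
* **Intensities** are drawn directly on the arcsinh scale from
  two-component normal mixtures; separation is parameterized as a target
  stain index (pos − neg location) / (2 × neg scale), defaults per marker
  in the 2.3–8 range (Foxp3 at 5.1). Dead events stain bright on the
  viability channel; doublets double scatter area at constant height.
  Raw-scale FCS output applies the inverse transform, decoupling
  generation from the analysis transform.
* **Ground truth** keeps every event's population label, realized marker
  states and dead/doublet flags, so per-sample truth frequencies are exact
  recounts of labels — the oracle for pre-gating retention, pooled-gate
  recovery, effect-ratio recovery and stain-index recovery tests.

What the generator does **not** emulate: spectral spillover and
compensation error, acquisition-time drift, non-Gaussian intensity tails,
correlated marker expression beyond the population structure, or donor
demographics. Passing tests therefore demonstrate the correctness of the
analysis machinery under a clean mixture model, not robustness to every
artefact of real cytometry data.

## Problem sizes and determinism

Tests and the acceptance script run the full design at 3000 events per
sample (12 donors × 2 platforms × 3 replicates = 72 samples, plus a
6-donor validation cohort), chosen so that counting the 6561-row lattice,
scoring and hierarchy construction complete in seconds while Monte-Carlo
tolerances (±0.05 on the 0.56 ratio, ±6 points on the 44% bias, ±15% on
stain-index recovery) hold with comfortable margin. Stain-index recovery
uses a 45 000-event sample so the rare-component median is stable. All
randomness flows through `numpy.random.default_rng` seeds carried in the
cohort spec or derived from a single CLI seed; identical spec + seed gives
bit-identical events and byte-identical CSV/DOT artifacts.

## Known limitations

* CD25^high-style "bright" gating is handled as plain positivity with a
  manually raised threshold, not as a third intensity level.
* The two-means partition assumes an approximately two-component 1-D
  intensity distribution; trimodal markers will be cut at the dominant gap.
* The replication verdict is a hard cutoff, inheriting the instability of
  cutoff rules near AUC ≈ 0.9 at small cohort sizes.
* Reading integer-type or multi-dataset FCS files is out of scope.
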