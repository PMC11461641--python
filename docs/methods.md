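# Methods

## The imaging model

The left ventricle is represented on the standard AHA 17-segment polar map
(6 basal, 6 mid, 4 apical segments plus the apex). Per animal and imaging
timepoint (`day3`, `month1`) a `SegmentProfile` holds four quantities:

- **transmurality** — percent of wall thickness showing late gadolinium
  enhancement, in [0, 100];
- **uptake** — FDG tracer signal, stored raw (arbitrary units) and
  normalized to percent of the hottest segment (`U_s = 100·raw_s/max`),
  so the maximum of the normalized vector is exactly 100. Normalizing to
  the hottest segment is the percent-of-peak display convention; it makes
  the quantity scale-free (invariant to injected dose and scanner gain),
  which the property suite asserts directly;
- **contractility** — percent systolic wall thickening; dyskinetic
  segments may be negative, floored at −50%. Any monotone contractility
  score would satisfy the pipeline's contracts;
- **MVO extent** — microvascular obstruction as percent of LV mass (a
  global day-3 CMR finding, carried unchanged on month-1 profiles).

All percentages live on the 0–100 scale throughout the package.

The mid-LAD infarct territory used for territory means is segments
{7, 8, 9, 13, 14}: mid anterior, mid antero- and inferoseptal, apical
anterior and apical septal.

## The classifier

A segment is mismatched iff transmurality ≥ 75 **and** normalized uptake
≥ 75, both comparisons inclusive; an animal is Mismatch iff at least 3 of
17 segments qualify. Thresholds and the segment count are configurable
(`MismatchThresholds`) with those operating values as defaults so
sensitivity analyses are possible. The classifier is monotone in both
inputs, and animals lacking a day-3 profile are excluded from cohort
assignment with a logged warning rather than imputed; incomplete
17-vectors are rejected outright.

## The synthetic cohort: a stated world

No animal-level data are deposited, so the generator *is* the test bed.
Its defaults encode the published group structure:

| quantity | Match | Mismatch | source |
|---|---|---|---|
| EF day 3 (%) | 42.0 ± 5.2 | 34.0 ± 8.7 | printed |
| EF 1 month (%) | 43.0 ± 6.3 | 35.8 ± 9.5 | printed |
| infarct day 3 (% LV) | 22.1 ± 4.4 | 26.6 ± 6.6 | printed |
| infarct 1 month (% LV) | 20.3 ± 7.2 | 28.0 ± 10.4 | printed |
| territory uptake 1 month (%) | 64.7 ± 13.2 | 56.0 ± 23.1 | printed |
| fasting glucose (mg/dL) | 105 ± 8 | 105 ± 8 | printed |
| TIMI-2 share | 3/25 | 1/12 | printed |
| territory uptake day 3 (%) | 45 ± 12 | 85 ± 7 | placeholder |
| territory transmurality (%) | 85 ± 7 | 85 ± 7 | placeholder |

Quantities marked *placeholder* are never printed numerically; their
values were chosen once to reproduce the qualitative phenotype (high
day-3 uptake on the same scar in Mismatch only, yielding ≥ 95% label
recovery by the classifier) and are flagged in `CohortConfig`'s
docstring. EDV, biomarker panels (IL-6 higher in Mismatch at day 3 only),
qPCR Ct levels (CD68 most induced in the Mismatch infarct, CD45 slightly
reduced, TNF-α flat) and the nucleus/bulk generator parameters are
placeholders of the same kind.

**Truncated draws and mean matching.** Continuous percents are drawn from
normals truncated to [0, 100]. Truncation biases the realized mean away
from the nominal location, by about −1.1 points for the strongly truncated
month-1 Mismatch uptake (56.0 ± 23.1). The generator therefore solves for
the location parameter whose *truncated* mean equals the configured mean
(Brent root finding on the scipy truncated-normal moment), so sample means
converge to the configured values. The realized SD still shrinks slightly
under truncation; moment-recovery tests assert SDs only for quantities
whose bounds sit ≥ 3.5σ from the mean.

**Structure of a profile.** Territory segments draw from the group's
territory distribution; remote segments draw from a common remote
distribution, with one fixed remote reference segment (basal
anterolateral) pinned to 100% as the normalization peak. Raw uptake is
reconstructed as the normalized vector times a log-normal per-animal scale
so that `normalize_uptake` round-trips. Month-1 contractility is generated
as `−20 + 0.6·uptake + N(0, 8)` (clipped to [−50, 100]), encoding the
reported positive month-1 uptake–contractility association; day-3
contractility is low in the territory regardless of uptake (that is the
mismatch). MVO is independent of uptake by default (`mvo_uptake_coupling
= 0`), matching the reported null correlation; the coupling knob exists
for sensitivity analyses.

**Seeding.** One seed feeds a `SeedSequence` hierarchy with named children
(globals, day-3 segments, month-1 segments, biomarkers, qPCR), so blocks
can be regenerated independently and generation is a pure function of
(config, seed).

**What the generator does not emulate.** Spatial correlation between
neighbouring segments, paired day-3/month-1 noise (timepoints are drawn
independently given the group), measurement error models, drop-out or
death, batch effects, and any read-level sequencing artefacts. A green
test therefore establishes that the *methods* behave correctly on data
with the stated group structure — not that the biological effect sizes are
re-estimated from real data.

## Bulk and single-nucleus generators

Bulk counts are gamma–Poisson (negative binomial, dispersion 10) draws per
gene × sample around a log-normal gene baseline shared across arms (seeded
separately, so different arms live in one gene universe), with log-normal
library factors. Marker genes of cell type *t* have their mean multiplied
by `1 + effect[t][(group, region)]`; monocyte/macrophage effects are
largest in Mismatch-AMI (2.0), echoing the reported abundance pattern.

Nuclei draw a latent cell type from (region, group) proportions shaped
after the published count table (border-zone monocytes 5% in Mismatch vs
1% in Match); counts are multinomial over gene weights with the type's
markers up-weighted ×160 relative to their background weight, the 13
mitochondrial genes (ND1–ND6, ND4L, COX1–3, CYTB, ATP6, ATP8) receiving
the mass implied by a region-specific Beta-distributed mitochondrial
fraction (heavier tail in the infarct core), and a log-normal library size
(smaller in the infarct region) that deliberately spans the 200-gene QC
boundary. Hashtag counts are log-normal background (mean 8) with one
log-normal signal tag (mean 300).

## Analysis stages: numerical choices

- **QC**: retain iff detected genes ≥ 200 **and** mitochondrial fraction
  ≤ 0.20 — "more than 20%" is read literally, so exactly 20% is retained.
- **Demultiplexing**: per tag, a 2-component Gaussian mixture by EM
  (scikit-learn, 3 restarts, `reg_covar=1e-4`) on log1p counts; the
  higher-mean component is signal; positive iff posterior > 0.5; one
  positive tag → that sample, none → negative, several → doublet. A
  non-converged fit falls back to the midpoint of a 2-means split and is
  flagged on the returned fit record.
- **Signature score**: CPM → log1p; within each signature, genes whose
  Pearson correlation with the signature's per-sample median profile is
  below 0.3 are dropped (the co-expression-coherence idea of
  signature-based deconvolution, without its network machinery); genes
  with undefined correlation (zero variance) are retained. Types with
  fewer than 3 surviving genes are reported as not-scorable rather than
  silently dropped. The score is the mean transformed expression of
  surviving genes; relative abundance is the score standardized across
  samples within type. CPM makes the score invariant to library rescaling.
- **Annotation**: per-cell mean log1p raw count over each type's markers;
  assign the argmax type only if it beats the runner-up by ≥ 0.25
  log-units, else `unassigned` (ties are never broken arbitrarily).
- **Differential expression**: counts-per-10k + log1p (the common
  single-cell convention; no variance-stabilizing regression is
  reimplemented), two-sided Wilcoxon rank-sum per gene (asymptotic,
  tie-corrected), log2 fold change of arm means with pseudocount 1,
  Benjamini–Hochberg across all tested genes, DEG = adjusted p < 0.05.
  All-zero and constant genes get p = 1; arms below 10 cells are errors.
  The rank test replaces the original hurdle-model testing as a
  deliberate, simpler substitution with controlled type-I error (verified
  at 0.05 ± 0.02 on a 2,000-gene null in the acceptance suite).
- **Enrichment**: plain upper-tail hypergeometric over-representation of
  user-supplied gene sets with BH adjustment; no active-subnetwork search
  or term clustering.
- **Statistics**: classical equal-variance one-way ANOVA; the Bonferroni
  family is one outcome × all group pairs; significance at two-sided
  p < 0.05; OLS with Pearson r and a t-test on n−2 df (constant y returns
  slope 0, r = 0, p = 1; constant x is an error). ΔΔCt combines the two
  reference genes (HPRT, ACTB) by arithmetic Ct mean — the combination
  rule is a package choice — making the fold invariant to per-sample
  constant Ct shifts; day-3 and month-1 contrasts are treated as separate
  (unpaired) families.

## Known limitations

- Placeholder distributions are plausibility choices, not estimates; only
  the printed group means/SDs are authoritative.
- Published per-region nuclei percentages cannot be recomputed exactly
  (region totals are not printed); only their ordering is testable, and
  the generator encodes that ordering.
- The polar-map renderer is a convenience; the tabular polar map is the
  tested artifact.
- No probabilistic segment classification, no repeated-measures
  modelling, and no pixel-level image processing of any kind.
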