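# Methods

This note documents the statistical procedures implemented in `paa`, the
conventions and defaults they use, what the synthetic generators do and do
not emulate, and the numerical choices made where the design was open.

## Data model

Three containers cover the toolkit's inputs:

- **ScreenMatrix** — one screen's substrate × condition summary (n × k),
  with a measurement kind (`raw_intensity`, `fold_change`,
  `initial_rate`). Labels are trimmed and matched case-insensitively but
  displayed in their original case; raw intensities and fold changes must
  be nonnegative; missing cells are NaN and are excluded from statistics,
  never zero-filled.
- **KineticRaw** — per-well fluorescence time courses (n × t), minutes on
  the time axis, replicate indices contiguous from 1 per
  (substrate, condition).
- **ReporterDataset** — sample × reporter concentrations with a class
  label per sample and an optional group label (e.g. time point).

## Substrate database queries

A `SubstrateDatabase` aggregates screens by normalized label without
cross-screen averaging: every indexed value is exactly one cell of exactly
one input screen. Ranked queries score each (substrate, protease) pair
within each screen by two standard scores of the same cell:

- *efficiency z*: z-score within the protease's column, across substrates
  — how strongly this substrate is cleaved relative to the panel;
- *specificity z*: z-score within the substrate's row, across proteases —
  how exclusively this protease cleaves it.

The combined score is the mean of the two z's per screen, averaged over
all screens where both are defined. Standard scores use the sample
standard deviation (ddof = 1); a constant (or singleton) row/column gets
z = 0 rather than NaN so rankings stay total. Ties are broken by label,
lexicographically, so output order is deterministic. The published ranking
statistic behind this kind of query is not printed anywhere we could
verify against, so the combined-z definition is this package's own
declared choice; it reproduces the qualitative behavior expected of such
queries (a dominant cell ranks first in both directions, constant columns
are uninformative, rankings are invariant to row/column permutation).

### Sequence similarity

- `levenshtein_distance` is the classic O(nm) two-row dynamic program.
- `similarity_ratio(a, b) = 1 − d(a, b) / max(|a|, |b|)`, on [0, 1];
  1 iff identical; two empty sequences are defined identical. This is the
  simplest monotone normalization of the edit distance; the alternative
  `(|a|+|b|−d)/(|a|+|b|)` used by some fuzzy-matching libraries is a
  monotone transform of the same distance at fixed lengths and is not
  exposed.
- `partial_ratio(a, b)` is the maximum of `similarity_ratio` between the
  shorter sequence and every contiguous equal-length window of the longer
  one; it is 1 whenever the shorter is a substring of the longer, which
  makes it robust to flanking spacers (GG/GS termini around a shared
  cleavage motif). Scores are reported on [0, 1].
- k-mer search is exact, case-insensitive substring matching; positions
  are 0-based and overlapping occurrences are all reported.
- The similarity matrix is clustered with scipy average linkage on
  distance 1 − similarity; the returned row order is the dendrogram leaf
  order.

Cross-species mapping uses an ortholog table with columns
human/chimpanzee/mouse/rat, an empty cell meaning "no ortholog". The
packaged table (`data/orthologs_synthetic.csv`) is a small synthetic
fixture covering the proteases used in examples; real analyses should
supply a degradome-scale table. "Gene absent from the table" raises a
not-found error (with near-miss suggestions at similarity ≥ 0.8), distinct
from "gene present, no ortholog", which returns None.

## Kinetic analysis

**Initial rate** is the ordinary-least-squares slope of intensity vs time
(intensity/min) over the rate window. The default window takes points
within the first 30 minutes, or the first 5 points if fewer qualify —
wide enough for plate reads every few minutes, narrow enough to stay in
the roughly linear phase of typical screens. Replicates are averaged
pointwise before fitting (for OLS this equals averaging per-replicate
slopes when all series share the time grid; the per-replicate option
exists for unbalanced designs).

Note an inherent property of slope fitting on a saturating curve
F(t) = F0 + A(1 − e^(−kt)): over a window of length T the OLS slope
underestimates the true initial rate A·k by a relative factor ≈ kT/2.
Accurate per-cell recovery therefore needs kT ≪ 1 (dense early sampling);
with additive read noise σ, the per-cell random error is
≈ σ/(A·kT·√R) for R replicates, so bias and variance pull the window in
opposite directions. At σ = 0.05·A and 10 time points, per-cell errors of
10–30% are unavoidable for slow substrates; the parameter-recovery tests
accordingly check the noiseless case per cell (max error < 1% with dense
early sampling) and the noisy case at screen level, as the signal-weighted
regression slope of estimated on true rates (error < 10%; triplicate
wells, 10 points over 3 min, averaged over 5 seeds).

**Fold change** is intensity at the evaluation time over the first-point
baseline (default evaluation: last common time point), after the chosen
background policy: none (default), blank-well subtraction, or first-point
subtraction floored at ε = 1e−6 so the ratio stays defined. Fold change
is invariant to rescaling the whole series.

**SvE records** pair the two standard scores of each cell (efficiency
across substrates, specificity across proteases), with the same ddof = 1
and zero-variance conventions as the database queries, plus the raw value
so absolute cleavage magnitude is never lost behind relative scores.

**Clustering** of rows and columns is independent agglomerative
clustering (scipy), default average linkage on Euclidean distance, with
an option to z-score rows first (the usual convention for activity
heatmaps). **Spearman correlation** between conditions uses average ranks
for ties; a constant column's correlations are undefined and reported as
NaN with a warning, while the diagonal is fixed at 1. **Class summaries**
count, per substrate, the proteases of each catalytic class (metallo,
serine, cysteine, aspartic, other) whose fold change meets the threshold
(default 1.5 — a modest but clearly-above-baseline signal; the threshold
is a user parameter, not a biological constant).

Plotting functions (line plots, clustered heatmap, SvE scatter,
susceptibility pie, correlation heatmap) are presentation-only: every
number they draw comes from the operations above.

## Reporter (in vivo) analysis

**Normalization.** `sample_relative` (default) divides each sample's
reporters by that sample's total, making rows sum to 1; this removes
per-animal scale differences (urine concentration, injected dose) and is
a declared convention, since published pipelines vary. `reporter_mean`
additionally divides each reporter by its across-sample mean. Note that
relative normalization makes the data compositional: a strong increase in
one reporter depresses the relative values of all others, which can make
unaffected reporters appear differentially *de*-enriched. Interpret
volcano plots of normalized data with that in mind, or run the
differential test on unnormalized concentrations when absolute levels are
comparable across samples.

**Differential enrichment** runs a two-sided test per reporter: by
default the Mann–Whitney U — exact null when both groups have ≤ 8 samples
and no ties, otherwise the normal approximation with tie correction and
*without* continuity correction. The continuity-corrected (and the exact)
test attains P(p < 0.05) ≈ 0.043 at n = 10 per group, noticeably
conservative; without the correction the attained level is ≈ 0.052,
closest to nominal (verified by exact enumeration of the U distribution).
Welch's t-test is available as an option. Adjustment is
Benjamini–Hochberg (Bonferroni optional) at the stated FDR (default
0.05). Fold change is the ratio of class means. The volcano table reports
log2 fold change, −log10 adjusted p and the significance flag,
consistently with the differential result.

**PCA** uses the full SVD (deterministic) with the sign fixed per
component so the largest-magnitude loading is positive; optional
per-reporter standardization gives correlation PCA.

**Classification.** Binary: stratified k-fold CV (default k = 5,
shuffled, seeded), held-out ROC AUC per fold, mean AUC reported. SVM
(linear kernel by default — interpretable weights enable feature
elimination; RBF optional) and the linear model are standardized inside
each training fold; the random forest is scale-free and is not. The
"linear model" is a regularized logistic-loss classifier: a
least-squares line is not a classifier, and logistic loss is its natural
classification analogue. Multiclass: out-of-fold predictions aggregated
into a confusion matrix (rows = true class) with per-class
precision/recall. All randomness flows from the seed; identical inputs
and seed give identical reports.

**Recursive feature elimination** refits after removing the single
lowest-importance reporter (|linear weight| averaged over classes, or
impurity importance for forests), recording the cross-validated AUC at
each panel size. The ranking is the reverse elimination order; surviving
reporters are ordered by final-model importance. Ties in importance are
resolved by column order (stable argmin), keeping runs reproducible.

## Synthetic generators

All generators are pure functions of (spec, seed); one seed fans out to
per-generator substreams via `SeedSequence` spawn keys, so adding one
generator call never shifts another's draws.

- **Kinetic screens**: F(t) = F0 + A(1 − e^(−kt)) + N(0, σ), truncated at
  0, with per-cell A ~ U(200, 1000) intensity units, k ~ U(0.005, 0.05)
  min⁻¹ (half-times ≈ 15–140 min, typical of fluorogenic substrate
  cleavage over a 1–2 h read), baseline 100, σ expressed as a fraction of
  each cell's amplitude. Not modeled: inner-filter effects, substrate
  depletion coupling, photobleaching, well position effects.
- **Reporter matrices**: concentrations are lognormal,
  exp(N(log(class mean), σ_log)), default σ_log = 0.2 (≈ 20% CV, typical
  of quantified urinary reporters); planted class effects multiply the
  class mean of chosen reporters. Not modeled: reporter–reporter
  correlation, batch effects, heavy-tailed outliers.
- **Substrate libraries**: uniform random peptides over the 20 standard
  residues; for each (motif, count), exactly `count` sequences carry the
  motif at a random position and no other sequence contains any listed
  motif (rejection sampling), so k-mer search has construction-level
  ground truth.

Because the generators are simple by design, passing recovery tests shows
the estimators are correct under the stated model, not that they are
robust to every artifact of real instrument data.

## Problem sizes and determinism

Validation suites run at desk scale: oracle comparisons use 1,000 random
peptide pairs; rate recovery a 10 × 10 screen; null calibration 20 seeds
× 1,000 reporters at 10 vs 10 samples; classifier checks n = 40 with a
14-plex panel and 100 label permutations; RFE recovery 50 seeded reruns of
a 10-reporter panel. These sizes give the binomial/simulation margins the
tests assert while keeping a full run in well under a minute each. Every
stochastic step is seeded, and identical inputs plus seed produce
bit-identical tables and reports.

## Known limitations

- No Michaelis–Menten (k_cat/K_M) fitting, saturation-time modeling,
  peptide competition, or protease mixture deconvolution.
- Query ranking is validated against constructed ground truth and
  invariance properties, not against an external reference ranking.
- The packaged ortholog table is a synthetic fixture, not a curated
  degradome resource.
- Classifier evaluation uses cross-validation on the provided cohort; no
  distribution-shift or calibration assessment is performed.
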