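# Methods

`exofoot` reimplements, as a tested pipeline, the supernatant-metabolomics
("exometabolome footprinting") analysis of paired short-term and long-term
microgravity experiments on primary human macrophages: a suborbital-rocket
layout (`TEXUS54`) and an ISS layout (`CELLBOX`). This note documents the
model, the rules, the numerical choices, and what the synthetic validation
does and does not show.

## Data model

Raw input is a metabolite × measurement table of relative metabolite
abundance (RMA): GC-MS peak signal normalized to spiked internal standards,
dimensionless and non-negative. A measurement is one technical replicate of
one compartment of one biological sample, or a cell-free medium blank.
Missing entries are `NaN` in memory and an empty cell or `NA` on disk; zero
is a real measurement, never missing — the pipeline distinguishes censored
low signals from true zeros throughout.

After preprocessing, a table holds one signed value per metabolite and
biological sample: net production (+) or net consumption (−) relative to
the medium blank.

## Preprocessing ladder

The stages run in a fixed order; every removal and imputation is recorded
in a `PreprocessReport`:

1. **Unannotated removal** — compounds never matched to a reference
   spectrum are dropped (the pipeline consumes an annotation flag; peak
   annotation itself is upstream).
2. **Technical-pair imputation** — in a replicate pair with one missing
   value: if the surviving replicate is below the limit of detection
   (LOD = 50 RMA units), the gap gets 1/5 of the lowest observed signal in
   the whole platform dataset (the signal was plausibly censored);
   otherwise the surviving value is carried over. The dataset minimum is
   computed once per platform over all observed raw values including
   blanks, after unannotated-compound removal (unknown spectra are not
   metabolite signals).
3. **Replicate collapsing** — arithmetic mean over technical replicates per
   (biological sample, compartment); a collapsed cell is missing only if
   every replicate was missing.
4. **Compartment combination** — volume-weighted mean Σ(vᵢxᵢ)/Σvᵢ over a
   sample's compartments (supernatant recovered from several hardware
   chambers is combined in silico).
5. **Missingness filter** (two independent rules, per metabolite):
   *Rule A*: removed when a group's missing count reaches its threshold —
   2 of 5 flight samples or 1 of 3 ground samples, generalized as
   ⌈2n/5⌉ and ⌈n/3⌉ — **and** every observed value in that same group is
   strictly above the LOD; an observed low value blocks the rule, because
   it makes censoring (rather than absence) the plausible cause.
   *Rule B*: removed when strictly more than half the values are missing in
   both groups.
6. **Residual mean imputation** — remaining single gaps get the
   within-group mean of the metabolite. The group-wise (not grand) mean is
   used so imputation cannot leak the flight/ground contrast into imputed
   cells.
7. **Blank preparation and subtraction** — the per-metabolite blank is the
   mean of observed blank replicates (an all-missing blank falls back to
   dataset-min/5); subtracting it converts abundances into signed net
   uptake/secretion values.
8. **Inter-dataset scaling** — the long-duration table is divided by the
   scalar k = mean(target)/mean(reference) so both platforms share a grand
   mean; k is recorded and every scale-free statistic (fold change,
   correlation, quadrant) is asserted invariant to it.
9. **Problematic-metabolite removal** — a fixed exclusion list (fixative
   component, reference-mixture alkane, ubiquitously involved acids,
   compounds undocumented in human metabolite databases); the fixative
   sucrose is excluded only on the platform that used a sucrose-containing
   fixative.

Blank subtraction is placed *after* the missingness filter so the "below
50" clauses operate on raw signals, where an LOD of 50 RMA units is
meaningful; on blank-subtracted values the comparison would be
uninterpretable.

## Unsupervised QC

PCA runs on centered, unscaled data (samples as observations). Component
signs follow a fixed convention (largest-magnitude loading positive) so
results are deterministic. Heatmap matrices are standard-scaled per
metabolite and rescaled into [−1, 1] by the *global* maximum absolute
standardized value — a per-row maximum would force every row to touch ±1
and erase between-metabolite contrast; rows/columns are ordered by
complete-linkage hierarchical clustering of Euclidean distances.

Leakage outliers are flagged by the fraction of metabolites for which a
sample holds the panel maximum (ties split their weight); samples at or
above 0.8 are reported. Removal is never silent: it requires an explicit
confirmation (config list or CLI flag) and is logged, after which
preprocessing is re-run without the sample.

## Differential analysis

Fold change is the ratio of blank-subtracted means, FC = x̄_flight/x̄_ground.
It is negative exactly when the metabolite flips between net production and
net consumption ("inverted behaviour"); "effect size" denotes the magnitude
|net RMA|. Two designs:

* **two-sample** (long-duration platform): Welch's unequal-variance t-test
  of flight vs ground biological samples;
* **single-sample** (rocket platform, one biological sample per condition):
  one-sample t-test of that sample's technical replicates against the
  pooled ground mean as µ₀. "Unequal variance" is vacuous for a one-sample
  test and is ignored.

Both tests are two-sided. When both groups have zero variance, p = 1 for
equal means and p = 0 otherwise, by convention. Raw p-values are adjusted
across the metabolite panel with Benjamini–Hochberg; BH was chosen because
the two-band scheme needs a monotone adjustment. Bands: "++" for FDR <
0.35, "+" for 0.35 ≤ FDR ≤ 0.50 (both boundaries in the lower band),
not significant above. The deliberately permissive second tier admits
weakly powered members of metabolite networks for the cluster analysis.

Significant records are classified into volcano regions with open
boundaries: strong increase (FC > 2), weak or inverted decrease
(−0.5 < FC < 0.5), strong inversion (FC < −1, i.e. sign flip with
equal-or-larger effect).

## Correlation clusters

Inter-metabolite Pearson correlation is computed over all samples of a
dataset, ignoring gravity conditions. Zero-variance metabolites get r = 0
(not undefined) so clustering stays total. The shared-metabolite submatrix
of dataset 1 is ordered by average-linkage clustering (Euclidean distance
on correlation-matrix rows); dataset 2 is re-indexed to the identical
order so the two heatmaps align row by row.

Conserved clusters are found by evaluating every dataset-1 dendrogram
subtree (equivalently, every group produced by cutting the dendrogram at
successive heights): a group is accepted when its mean pairwise |r| reaches
the threshold (default 0.8) in **both** datasets and has at least
`min_size` (default 2) members; maximal accepted groups are returned.
|r| is used because strong anticorrelation is as informative as strong
correlation. This rule is a reproducible operationalization of what was
originally a visual judgement; the 0.8 threshold is a package default, not
a measured constant.

## Cross-platform projection

Shared metabolites are placed on a plane: long-duration FC horizontal,
short-term (µg vs ground) FC vertical. Quadrants are defined on effect
strength s = |FC|: center when both strengths lie in [0.5, 2.0] (the same
halving/doubling thresholds as the volcano regions; the center extent is a
package default), otherwise upper/lower by s_short vs 1 and right/left by
s_long vs 1. Negative-FC metabolites invert their direction of change and
are an exception to the plain quadrant reading, so inversion is carried as
per-axis flags instead of discarding those records. Concordance means the
sign of (flight − ground) agrees and is nonzero on both platforms. The
band summary lists the "++"/"+" marks per contrast, grouped by conserved
cluster.

## Synthetic data generator

The generator is first-class, tested code; it defines the study conditions
under which the pipeline is validated.

Raw signal for metabolite m in sample s is

    gain_platform × ( blank_mean[m] + base_net[m] × effect(m, condition(s)) )

multiplied by log-normal noise with CV = 0.1 (GC-MS intensities are
positive and heteroscedastic; the magnitude is a calibration choice, not a
measured constant), clipped at zero, censored below 50 RMA units with
probability 0.8 (missing-not-at-random), with one flight sample's raw
values inflated ×3 to emulate a hardware-leakage outlier. The platform
gain (2.5 vs 1.0) emulates the non-similar scaling of RMA values between
instruments that mean scaling later undoes.

Replicate layouts mirror the two campaigns: the rocket layout has 1 flight
sample per condition (hypergravity, microgravity) × 3 technical replicates
plus 2 ground samples × 3 replicates and 3 blank replicates; the ISS layout
has 5 flight samples (1 replicate, two compartments), 3 ground samples ×
2 replicates, and 6 blank replicates. Panels are 63 and 61 metabolites
with exactly 32 shared ids. Planted effects are multiplicative on the net
value and include strong sign inversions (−60, −41, −12, −4, −2), a >95%
decrease, ~2–4-fold increases, and near-null metabolites; effect
magnitudes echo the phenomenology the pipeline must resolve.

Correlated blocks (one of 5 metabolites at ρ = 0.95, one of 4 at ρ = 0.85,
both inside the shared panel) are induced by a per-sample latent factor
z_s shared within the block: the net value gains
`scale × |base_net| × (√ρ z_s + √(1−ρ) ε)`. Block members' blanks carry a
2σ allowance so consumption swings do not clip at zero. The latent is
sample-level *biological* covariation, so the zero-noise exact-recovery
check runs with blocks (and censoring and the outlier) disabled — with a
live latent the planted fold change is only recovered in expectation.

What the generator does **not** emulate: retention-time drift,
annotation errors, batch effects, heavy-tailed contamination, or any
departure from log-normal noise. Passing recovery tests therefore shows
the pipeline's rules are implemented correctly and are statistically
calibrated under these conditions; it does not certify performance on real
chromatographic pathologies.

## Validation experiments and problem sizes

The calibration module re-runs the pipeline on planted truth:

* **Null calibration** — Welch test on two groups from the same
  log-normal (5 vs 3 samples), 10,000 repetitions; rejection at α = 0.05
  must be 5% ± 1.5 points.
* **Fold-change recovery** — zero-noise pair: worst relative FC error
  < 10⁻⁹ across all three contrasts; at CV = 0.1, median relative FC error
  over 200 repetitions of the ISS design < 15%.
* **Cluster recovery** — two 8-sample single-condition layouts (5 + 3,
  3 technical replicates, no planted condition effects so background
  r ≈ 0) carrying the same ρ = 0.95 block; power to return exactly that
  block and the count of non-planted groups over 100 repetitions at
  threshold 0.8. At this sample size the acceptance rule has an intrinsic
  statistical ceiling: a background metabolite's chance correlation with
  the block latent (|r| ≥ ~0.54 at n = 8) lets a diluted superset subtree
  pass the mean-|r| rule in both datasets often enough that exact-recovery
  power saturates near 0.8 and spurious groups appear at ~0.1 per
  repetition even for an error-free generator. The package reports the
  measured values rather than masking them; with more samples (n ≥ 20)
  both failure modes vanish.
* **Outlier flagging** — ×3 leakage sample flagged in ≥ 95% of 200
  repetitions (measured: 100%).
* **Structure** — PCA variance fractions agree with a direct covariance
  eigendecomposition to 10⁻⁹; fold changes, correlations and quadrants are
  invariant under the inter-dataset scalar; the quadrant rule partitions
  the plane; two runs with one seed are byte-identical.

All experiments derive per-repetition seeds from a single base seed and
run on one CPU in about a minute.

## Numerical choices and degenerate inputs

* Sample standard deviations use n−1 throughout (bar exports, z-scores).
* Zero-variance rows: heatmap rows become 0 with a warning; correlations
  become 0 with a warning.
* Ground mean exactly 0 makes FC undefined: the record is kept, marked
  unclassified, with FC = NaN.
* Scaling by a non-positive or zero factor (grand means of opposite sign
  or a zero target mean) raises a validation error rather than silently
  flipping signs.
* Band boundaries: FDR = 0.35 and 0.50 both fall in the lower ("+") band;
  effect-region boundaries (2, ±0.5, −1) are open.
* Ties in the outlier score split their weight evenly, so duplicated
  columns are never flagged.

## Known limitations

* The single-sample design tests technical replicates against a point
  null; with one biological flight sample, biological variance is not
  identifiable and p-values understate uncertainty — a faithful property
  of the rocket design, not a fixable flaw.
* The conserved-cluster rule is threshold-based and visual-surrogate by
  construction; at small sample counts its false-positive floor is
  nonzero (see above).
* No moderated variance estimation, batch correction, or enrichment
  analysis; these are out of scope.
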