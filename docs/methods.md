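# Methods

## The procedure and its assumptions

`depselect` targets two-group label-free DIA protein matrices with very few
biological replicates (the design it is built around is n = 5 per group).
At that sample size parametric tests are fragile and any single feature-
selection criterion is noisy, so the procedure stacks three safeguards:
an ensemble of heterogeneous relevance criteria over three normalization
views of the data, a wrapper-style elimination stage under three different
classifiers, and a final nonparametric gate with an exact null. The
working assumptions are: intensities are approximately log-normal;
missingness is dominated by low-intensity censoring (MNAR) with a small
random component; technical variation is additive per sample on the log
scale; and exactly two groups are compared, each with at least two samples.

All analysis happens on log2 intensities (`log2_transform: true` by
default). The raw-scale reader treats zeros as missing because a DIA zero
means "not quantified", not zero abundance; a flag disables this.

## Preprocessing

**Completeness filter.** Proteins observed in fewer than 50% of the
samples of *both* groups are dropped before imputation
(`min_observed_fraction`, default 0.5). A protein absent in one group but
solid in the other is kept — one-sided presence is itself a strong
differential signal. The dropped count is reported in the manifest so the
filter is auditable.

**Imputation.** Missing cells of protein *p* become
min(observed of *p*) − ε with ε = 0.05 (log2 units). The offset places
imputed values just below the protein's own detection floor, preserving
rank structure without inventing spread. Imputation runs before
normalization (config-switchable); proteins with no observed value at all
cannot be imputed and are dropped with a log entry. Note one consequence
at small n: all imputed cells of a protein share one value, so when
dropout hits both groups the resulting cross-group ties blunt the rank
test — visible in the spike-in benchmark as sensitivity loss for
low-abundance spiked proteins.

**Normalization branches.** Three views are computed from the imputed
matrix and feed three independent weighting runs:

- *mean*: every sample (column) centered so its mean equals the grand
  mean; removes per-sample loading/acquisition offsets, preserves the
  overall level.
- *ratio*: per-protein subtraction of a reference profile on the log scale
  (log-ratio). The default reference is the per-protein grand mean over all
  retained samples; a reference group or single reference sample can be
  configured (`ratio_reference`).
- *binomial*: dichotomization at the per-protein median, "over" strictly
  above, ties to "under" (deterministic, label-free, invariant under any
  strictly monotone per-protein transform).

**Batch handling.** Batches are excluded, not corrected: `batches_keep`
restricts the sample set (groups re-validated afterwards), and `batch_qc`
reports per-batch median intensity, missingness rate and median
within-batch pairwise correlation, flagging a batch whose missingness
exceeds the median of the others by `qc_missingness_margin` (default
0.15). This supports the manual exclusion decision this design anticipates;
no empirical-Bayes correction is attempted.

## Attribute weighting

Continuous features are reduced to their best binary split: candidate
thresholds are the midpoints between consecutive distinct sorted values
and each criterion keeps the split maximizing itself. This makes the
entropy, χ², Gini, rule and uncertainty criteria deterministic, invariant
under strictly monotone transforms, and checkable against small
enumeration oracles. Definitions (Y = class, S = split indicator):

- information gain: H(Y) − H(Y|S), bits;
- information-gain ratio: IG/H(S) (0 when no admissible split);
- χ²: the 2×2 split-vs-class statistic, no continuity correction;
- Gini index: impurity reduction of the best split;
- rule: best single-threshold rule accuracy minus majority baseline;
- symmetric uncertainty: 2·IG/(H(S)+H(Y)) ∈ [0, 1];
- deviation: sample sd of the min-max-scaled feature;
- Relief: one nearest hit and one nearest miss per instance, every
  instance used, Manhattan distance on min-max-scaled features,
  neighbour ties to the lowest sample index;
- SVM: |coefficient| of one linear max-margin classifier (C = 1) trained
  on all standardized features jointly;
- PCA: |loading| on the first principal component of the standardized
  matrix. PC1 tracks *shared* variance, so this criterion surfaces the
  class axis only when several correlated features carry it — which is
  exactly the situation in a matrix with many co-regulated DEPs, but it
  cannot find an isolated separator among uncorrelated features.

The binomial branch uses the seven criteria that accept categorical
features (IG, IG-ratio, χ², rule, Gini, Relief — where Manhattan on 0/1
codes equals the overlap metric — and uncertainty); deviation, SVM and PCA
need continuous geometry and are excluded.

**Votes and selection.** Per algorithm, weights are min-max scaled to
[0, 1] and a vote of 1 is cast at scaled weight ≥ `vote_threshold`
(default 0.5); an all-equal weight vector casts no votes. Votes are summed
across the 10 + 10 + 7 branch-algorithm pairs into one cumulative score
(0–27) and the `top_k` = 200 highest-scoring proteins proceed. Boundary
ties break by higher mean raw weight, then lexicographic id, so selection
is a deterministic function of the data.

## Recursive feature elimination

Three rankers refine the candidate set: L2 logistic regression and a
linear SVM (C = 1) rank by |coefficient| on standardized inputs; a random
forest ranks by impurity importance. One feature is removed per iteration
at the library level (`step` ≥ 1 exposed; equal importances break
lexicographically), and the pipeline uses an automatic step that visits
~12 subset sizes at k = 200 to keep the leave-one-out evaluation
affordable. Accuracy at each visited size is leave-one-out over samples —
with 10 samples, k-fold estimates are too unstable to rank subset sizes.
The optimal subset is the smallest size attaining the curve's maximum
(parsimony tie-break). The forest uses 100 trees by default in `ModelRFE`
and 50 in the pipeline configuration; at n ≈ 10 samples the importance
ranking is saturated well below that, and the smaller forest keeps a full
multi-seed benchmark on one CPU in minutes. Both the intersection and the
union of the three optimal subsets are persisted; the union flows
downstream by default (recall-maximizing, with the statistical gate left
to control false positives), and an empty intersection in intersection
mode falls back to the union with a warning.

## Statistical validation

The Mann-Whitney U test is two-sided throughout. For n1 + n2 ≤
`exact_limit` (default 12) the p-value is exact: a dynamic-programming
count of the rank-sum distribution when the pooled values are tie-free,
and full enumeration of the C(n1+n2, n1) group assignments with mid-ranks
when ties are present (imputation routinely creates ties). Beyond the
limit, the normal approximation with tie and continuity corrections is
used. At n = 5 vs 5 the exact null is coarse: p < 0.05 requires U ≤ 2 and
the smallest attainable two-sided p is 2/252 ≈ 0.0079, so the test is
conservative (attained size ≈ 0.032 at nominal 0.05).

The first pass tests the top-200 candidates (`first_pass_scope`
switchable to all proteins); the merged list is the union of the RFE
subset and the first-pass significant set, with provenance flags; the
second pass re-tests the merged list and `final` means p_second < α. On
unchanged data the second pass reproduces the first-pass p for proteins in
both — it is a re-test of a merged list, not a new statistic. No
multiple-testing correction is applied by default, mirroring the raw
p < 0.05 gating this procedure reproduces; a Benjamini–Hochberg flag
(`bh_correct`) is available. Both the RFE stage and the U tests run on the
mean-normalized branch: leaving per-sample offsets in the data both blunts
true differences and lets sample-level artifacts leak into the test.

Effects are reported as the difference of group medians on the analysis
scale (robust, consistent with the rank test), with groups taken in
sorted label order.

## Synthetic data: what it emulates, what it does not

Per protein, baseline μ_p ~ N(20, 3) on log2; each sample value is
μ_p ± fc/2 (spiked proteins only, sign random per protein) + batch shift
(N(0, 0.5) per batch) + N(0, 0.3) replicate noise; export is raw-scale
2^x so the full ingest path, including the log2 decision, is exercised.
Spiked effects are split symmetrically across groups so sample-level
normalization cannot absorb them. Missingness: logistic MNAR dropout with
midpoint 16 and slope 1 — about 10% overall, concentrated in the
low-intensity tail, matching typical DIA completeness — plus 2% MCAR, and
an optional corrupted batch with a flat missingness boost (default 0.3) as
a positive control for batch QC. Defaults are 2,000 proteins, 5 per group,
three batches, 5% spiked at |log2FC| = 2.

Not emulated: protein–protein correlation beyond batch structure,
peptide-level rollup, retention-time or spectral artifacts, and
heavy-tailed replicate noise. Passing spike-in benchmarks therefore shows
the machinery recovers well-separated effects under censoring at this
design size; it does not certify behavior on correlated proteomes or
outlier-prone real data.

**Calibration note.** With uncorrected exact tests at n = 5 vs 5, any null
protein passes p < 0.05 with probability 8/252 ≈ 0.032 regardless of the
noise model. In a 2,000-protein run ~50 nulls are chance-significant, and
because the ensemble ranks by class separation these are preferentially
pulled into the top-200 and confirmed by the second pass on the same data.
The spike-in false-discovery proportion of the full default pipeline
therefore sits near 0.4 (sensitivity ≈ 0.7); this is a property of the
procedure being reproduced — selection and testing on the same small
sample without correction — not of its implementation. Enabling
`bh_correct` trades sensitivity for FDP control.

## Numerical choices and degenerate inputs

- Constant features score 0 under every criterion (not an error).
- All-equal weight vectors cast no votes; min-max scaling of a constant
  vector is defined as all-zero.
- Exact-test comparisons use a 1e-9 tolerance on |U − n1·n2/2| so
  mid-rank floating-point noise cannot flip the "at least as extreme"
  predicate.
- Constant protein rows standardize to all-zero with a warning; z-scores
  use the n−1 denominator.
- Ranked-list scores clip p at 1e-300 before −log10.
- Stage seeds derive from the root seed as
  (seed·1000003 + crc32(stage)) mod 2³¹, so each stochastic stage is
  individually reproducible and the whole run is byte-deterministic given
  the config and seed.
- Problem sizes in the shipped benchmarks (full-scale runs at 2,000
  proteins; oracle checks at n ≤ 10; multi-seed repeats of 5–20) were
  chosen to characterize the method on a single CPU in minutes.

## Known limitations

- The two-group restriction is structural; time-course designs are
  handled as separate pairwise comparisons.
- The shared imputation floor produces cross-group ties that cost rank-
  test power exactly where MNAR censoring is strongest.
- Leave-one-out accuracy on 10 samples has high variance; RFE optimal
  subsets are often very small and should be read as a core signature,
  not an exhaustive list.
- Without multiple-testing correction the final DEP list has the
  selection-bias FDP described above; treat it as a candidate list for
  orthogonal validation, or enable `bh_correct`.
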