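# Methods

This note documents the models and procedures implemented in
`immunomodules`, the assumptions behind them, the defaults and why they
were chosen, and what the synthetic-cohort tests do and do not demonstrate.

## Feature assembly

Three omic blocks are harmonized into one subjects × features table per
timepoint parameter (BL, C2, Δ = C2 − BL).

**Serum panels.** Measurements below an analyte's limit of detection are
replaced by the LOD threshold (left-censoring made explicit rather than
imputed); quality-warned measurements are replaced by the assay median over
non-warned measurements of that analyte; finally each analyte is shifted so
its baseline medians agree across clinical trials, removing a batch offset
between trial cohorts. The shift reference is the first trial in sorted
order (configurable); the operation is idempotent, which the tests verify.

**Transcriptomics.** Counts become log2(count + 1); the pseudocount of 1
avoids log 0 and is the platform convention. Each sample is shifted by the
arithmetic mean of its log2 housekeeping values — geometric-mean scaling on
the count scale — then genes get the same inter-trial baseline median
alignment as serum analytes. The normalization method is configurable; the
geometric-mean convention is the default because it is standard for
housekeeping-normalized count panels.

**Single-cell summaries.** Per sample and cluster: abundance (cluster cell
count over the parent population), percent-positive per activation marker
(fraction of cells above a configured threshold), and mean expression per
metabolic marker. Clusters with fewer than 15 cells in a sample contribute
only their abundance; their marker statistics are emitted as missing so
that no summary is ever computed from a subsample small enough to be
dominated by counting noise. The parent population for abundances is
configurable (e.g. all cells vs non-neoplastic T cells), because different
analyses legitimately use different denominators. Positivity thresholds
are configuration inputs; deriving gates is upstream of this package.

**Compilation.** Δ features are computed before imputation so that imputed
endpoint values can never fabricate a change. Remaining missing entries are
replaced by the column mean — which leaves each column's mean invariant —
and every imputed cell is recorded in a mask. Constant columns are retained
but flagged; they carry no information and are neutralized downstream.

## Module discovery

Spearman correlation (mid-rank ties) is computed over subjects for all
feature pairs; constant features get correlation 0 and a flag. The
correlation maps to the dissimilarity d = 1 − ρ⁴. The fourth power removes
the sign — anticorrelated features are treated as co-regulated and
co-cluster — and shrinks moderate correlations toward distance 1, so only
strong dependencies bind features together.

Ward agglomeration runs directly on these dissimilarities via the
Lance–Williams update ("Ward on dissimilarities"); the custom distance is
not embedded in a Euclidean space first. The tree is cut at every k in
2..min(n_features − 1, 100) — wide enough to span under- and
over-clustering without quadratic blowup — and the cut maximizing the mean
silhouette (computed on the same distance matrix; singleton clusters score
0, the standard convention) is selected, ties broken toward the smallest k
for parsimony and determinism.

Each module is summarized per subject by PC1 of its Z-scored member
features (sample SD, constant features → 0). The PC1 sign is oriented so
the score correlates non-negatively with the mean member Z-score, with a
non-negative loading-sum fallback when that mean is flat; this makes
summaries reproducible across runs, platforms, and BLAS builds. Variance
explained is PC1's share of the Z-block variance; for an m-feature module
it is at least 1/m, and for an equicorrelated module with correlation ρ it
approaches (1 + (m − 1)ρ)/m, which the tests verify empirically.

A caveat documented deliberately: because iid noise features are roughly
equidistant from everything, the silhouette-optimal partition isolates them
in their own cluster(s) rather than absorbing them into real modules. On
cohorts containing pure-noise features the selected k therefore counts the
planted modules plus one or more noise clusters, and the silhouette curve
is nearly flat beyond that point, so the exact k among the flat region is
unstable even though the partition restricted to genuinely correlated
features is essentially exact (ARI ≥ 0.98 in the tested regime). Users
should read k as "modules plus background clusters", not as the number of
biological modules.

## Classifier

A random forest (500 trees by default; configurable) classifies two
patient groups from module scores. Tuning minimizes OOB classification
error over a small grid — variables-per-split ∈ ⌈√p⌉·{0.5, 1, 2}, minimum
node size ∈ {1, 3, 5} — with a fixed tuning seed; ties prefer smaller
variables-per-split, then smaller node size. The tree count of 500 keeps
each sample out of bag in ~180 trees, which stabilizes OOB estimates at
the cohort sizes this package targets while keeping the ten-seed stability
procedure fast on a single CPU.

Stability: the tuned model is rerun over ten seeds; per seed, the top ten
features by Gini importance get rank weights 11 − rank (10 down to 1);
weights are summed across seeds into a consensus score per feature; the
representative seed maximizes the total consensus score of its own top-ten
list (ties → lowest seed value). The representative seed's Gini vector
drives module selection: modules strictly above a threshold, either
explicit or "auto" = the midpoint of the largest gap in the descending
Gini sequence. The rank-weight and overlap formulas are the simplest
schemes consistent with the procedure's intent and are configurable.

Class imbalance is not reweighted (none of the targeted analyses do), but
a flag is emitted when imbalance exceeds 2:1. Timepoint comparison runs
the module + tuning pipeline per timepoint table and flags the minimum
OOB error; downstream analyses then focus on that timepoint parameter.

Two calibration facts worth knowing. First, the tuned OOB error is a
minimum over grid points and is therefore biased slightly below the
per-fit OOB error; under label permutation the per-seed OOB is centered at
0.5 but the tuned value sits around 0.45 with spread ~0.1. Second, with
one module shifted by 1.5σ on its latent factor, the module-score group
separation is ~1.2σ (the feature-level shift is √ρ·Δ), i.e. a Bayes error
near 0.27 — tuned OOB values of 0.1–0.4 across replicates are the expected
range, not a defect.

## Differential statistics

Unpaired comparisons use the Wilcoxon rank-sum test; paired comparisons the
Wilcoxon signed-rank test on subject-matched differences; count data use
the two-sided Fisher's exact test. Exact p-values are used when the
combined sample is ≤ 20 without ties; otherwise the normal approximation
with tie correction. BH correction runs over all features tested in one
comparison. A feature is significant when q < 0.1 or (p < 0.05 and
|ES| > 1). The effect size is Cohen's d (pooled SD) for unpaired and mean
difference over SD of differences for paired comparisons — an |ES| > 1
rule is only coherent for an unbounded standardized-difference measure;
log2 fold change remains available as a configurable alternative. Tests
are two-sided throughout. Constant features get p = 1, ES = 0, and a flag.

Z-score stratification Z-scores selected features per column, Ward-clusters
subjects on Euclidean distances between Z rows, and reports the dendrogram
order plus per-group mean Z per feature; a kinetics change is flagged as
substantial when |mean Z difference between timepoints| > 0.5.

Mahalanobis attribution is univariate per feature: for an outlying subject
x and groups A and B (outlier excluded), d_G = |x − mean_G| / sd_G and
Δ = d_A − d_B; features with Δ above 0.3 mark where the outlier resembles
group B more than its nominal group A. The univariate form is used because
the attribution is reported per feature and the multivariate covariance is
singular when features outnumber subjects. Zero-SD features are skipped
and flagged; swapping the groups negates Δ exactly.

## TCR metrics

Clones are (V gene, J gene, CDR3 amino acid) families with template
counts. The neoplastic clone is the single most abundant clone with ≥ 75
templates; a tie at the maximum is treated as an error rather than broken
arbitrarily, because the malignant identity must be unambiguous.
Gini–Simpson diversity is 1 − Σp_i², optionally after excluding named
clones (e.g. the neoplastic clone) and renormalizing. Morisita–Horn
similarity uses the standard abundance-weighted overlap over the clone
union and is invariant to proportional scaling. Differential clone
abundance tests each union clone's 2×2 table (clone vs remaining
templates, per sample) with Fisher's exact test under BH correction
(q < 0.05 by default; configurable, as some analyses use 0.1). Clones of
interest are the union of neoplastic, tumor-present, abundant (> 0.01% of
templates in at least one sample — evaluated per sample, the permissive
reading of an ambiguous rule), and differentially abundant clones, each
tagged with every criterion it satisfies.

## Synthetic cohorts

Features in module m follow x = √ρ·f_m + √(1 − ρ)·ε with f_m, ε standard
normal, so within-module correlation is exactly ρ in expectation and
between-module correlation 0; a discriminative module shifts its factor
mean by Δ between groups (feature-level shift √ρ·Δ). Generation is on the
Gaussian scale; Spearman and Pearson differ there only by a known monotone
map, negligible at the tolerances used. Missingness is injected completely
at random — the column-mean imputation being tested assumes no particular
mechanism — and LOD censoring floors the lowest configured fraction of
each feature at its empirical quantile. Repertoires draw Zipf-like clone
counts with an optional exactly-sized dominant clone; single-cell fixtures
have exact cluster sizes with Gaussian marker intensities. One integer
seed drives all sub-generators through independent spawned streams; equal
spec + seed reproduces outputs bit for bit.

What the generator does not emulate: feature-scale heterogeneity across
omics, heavy tails and skew of real panel data, informative missingness,
correlated noise between modules, batch structure beyond the trial median
offset, and sequencing error in repertoires. Passing tests therefore
demonstrate correctness of the algorithms under their stated statistical
model, not robustness to every artifact of real cohorts.

## Problem sizes and numerical choices

Simulation-based tests use cohorts of 40 subjects (20 per group), 8
modules × 6 features with ρ = 0.8, 12 noise features, and 10–20 replicates
per property; the acceptance script uses 10 replicates per quantity. These
sizes give stable averages for the reported rates while keeping runs quick
on a single CPU. Silhouette ties and Gini ties break deterministically
(smallest k; stable sort order); correlations are clipped to [−1, 1]
before the ρ⁴ transform; all-zero distance matrices, single-class labels,
all-flagged analytes, and all-missing columns raise errors rather than
propagate NaNs.

## Known limitations

- Ward on dissimilarities is not variance-minimizing in any embedded
  space; it is the customary adaptation for a non-Euclidean distance and
  is documented as such.
- OOB error is the only generalization estimate; no cross-validation or
  probability calibration is provided.
- Module membership is hard; no soft/overlapping assignment.
- The Mahalanobis attribution ignores feature covariance by design (see
  above).
- The synthetic generator's simplifications listed above bound what the
  test suite can claim about real data.
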