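# Methods

This note documents the statistical procedures `icpipe` implements, the
defaults it ships, the design choices that were genuinely open, and what
the synthetic-cohort tests do and do not demonstrate about real data.

## Data model

Copy-number calls are gene-level categorical states (LOSS, NEUTRAL, GAIN)
with an independent boolean LOH flag; gain and loss are mutually exclusive
but LOH may co-occur with any state (copy-neutral LOH is real and common).
Burden totals are therefore exact sums of the three per-type counts, and a
gene with loss + LOH contributes to both the loss and LOH columns.
Expression is log2-scale, one row per gene, probe-level processing assumed
done upstream. Gene matching between matrices is by exact identifier
string; genes present in only one matrix are dropped with a logged count.
Missing values are rejected by the readers — the pipeline consumes complete
post-call / post-normalisation matrices and does not impute.

## Driver selection

For each gene the dominant aberration direction is the more frequent of
GAIN/LOSS among its non-neutral states (ties go to GAIN and are logged).
The Mann–Whitney U test compares expression in samples carrying that
directional state against copy-neutral samples — mixing gains and losses
into one "aberrant" group would cancel opposite dosage effects. The exact
permutation null is enumerated when the pooled size is ≤ 20 and tie-free;
otherwise the normal approximation with tie and continuity correction is
used. Spearman ρ is computed between the numeric dose (−1/0/+1) and
expression over all shared samples, so concordance is positive for both
gain-driven and loss-driven genes and a single ρ > 0.6 threshold enforces
directionality; LOH carries no dose because copy-neutral LOH has no
expected dosage effect (a documented limitation). Selection is the
conjunction p < 0.05 ∧ ρ > 0.6 with no multiple-testing correction — the
correlation filter, not the p-value, carries the specificity (measured
false-positive rate on planted-null genes is ~0 at cohort scale).
Genes with fewer than `min_group_size = 3` samples in either group are
reported as untestable with a reason code rather than dropped.

## Consensus clustering

The inner clusterer is UPGMA on 1 − Spearman correlation between sample
profiles. 500 resamples each draw ⌈0.8·n⌉ samples without replacement
(method defaults of the consensus-clustering literature; the gene list is
fixed, so the distance matrix is computed once and subsampling is a
submatrix operation). Consensus entries are co-cluster counts divided by
co-sample counts; final labels come from average-linkage clustering of
1 − consensus cut at k.

Two design points deserve emphasis:

* **Gene median-centering (default on).** Raw log2 profiles share a large
  per-gene baseline component, which drives every sample–sample rank
  correlation toward ~0.95 and makes even structureless cohorts cluster
  deceptively stably (the k = 2 split locks onto a few global-outlier
  samples). Subtracting each gene's median across samples — the standard
  preprocessing of correlation-based sample clustering — removes that
  shared component; null cohorts then show the expected instability
  (within-minus-between consensus gap ≈ 0.2) while planted clusters are
  still recovered exactly.
* **Choice of k.** The per-k statistic is the area under the empirical CDF
  of the consensus entries, A(k) (equivalently 1 − mean consensus), with
  the relative gain Δ(k) = (A(k) − A(k−1))/A(k−1) and Δ(k₁) = A(k₁).
  A fixed cut-off on Δ (e.g. "stop when Δ < 0.1") proved brittle on clean
  data, where the residual gains beyond the true k fluctuate around any
  fixed threshold; the implementation instead returns the k with the
  sharpest flattening, argmax Δ(k)/Δ(k+1), which is an order of magnitude
  larger at the true k (ratios ~4–14 vs ~1 elsewhere in simulations).
  Consequences: the largest candidate k carries no flattening evidence and
  cannot be selected (extend `k_range` one beyond the k of interest, as
  with any elbow criterion), and the statistic is *advisory* — all per-k
  values are reported, and the pipeline clusters at the configured
  `n_clusters` (default 2) regardless, because the cluster count is
  normally fixed by inspection.
* A sample whose profile is constant over the clustered gene list has no
  rank correlation; since the gene list is fixed, every subsample
  containing it would fail, so this is raised as an error up front rather
  than handled by redrawing resamples.

Cluster names IC1/IC2 are semantic, not algorithmic: when an enrichment
matrix and reference gene sets (e.g. oxidative-phosphorylation /
mitochondrial sets) are supplied, IC1 is the cluster with the higher mean
reference enrichment; otherwise IC1 is anchored to the alphabetically
first sample, and the anchoring is logged.

## SAM

The two-class unpaired statistic is dᵢ = (x̄₁ᵢ − x̄₂ᵢ)/(sᵢ + s₀) with the
pooled scatter sᵢ = √[(1/n₁ + 1/n₂)(SS₁ᵢ + SS₂ᵢ)/(n₁ + n₂ − 2)]. The fudge
factor s₀ is chosen among the percentiles of the s distribution (0–100 in
steps of 5, plus 0 itself) to minimise the coefficient of variation of the
median |d| across ten s-quantile windows; for pure scale-family data with
well-estimated scatter the optimum is genuinely s₀ = 0 and is returned.
q-values permute the class labels: all C(n, n₁) distinct assignments are
enumerated when at most `sam_n_permutations` (default 1000) exist —
making the result seed-independent — otherwise that many distinct
assignments are sampled. For every threshold equal to an observed |d|,
FDR(t) = median over permutations of #{|d*| ≥ t}, divided by the observed
count; a feature's q is the minimum FDR over thresholds at or below its
|d|, capped at 1, which also makes q monotone non-increasing in |d|.

The median convention has a knife-edge consequence worth knowing: under a
global null the FDR at the single top feature is the median of a roughly
Bernoulli(½) permutation count, so individual null runs show 0 or ~1
false call at q < 0.05 with nearly equal probability; the median false-call
count across repeated simulations is 0, but a given seed stream can
legitimately show 0.5–1.

The subtype signature is the q < 0.02 features (a 2% FDR), each tagged
with the class it is up-regulated in; new samples are assigned by the
higher Spearman correlation with the two per-class signature centroids,
requiring ≥ 50% signature coverage. Nearest-centroid with rank correlation
was chosen to stay consistent with the pipeline's rank-based distances.

## ssGSEA

For one sample, genes are ordered by decreasing expression (ties broken by
gene ID, deterministically) and given descending ranks r (top = N). With
weights r^α (α = 0.25, the single-sample enrichment convention) the score
is ES = Σᵢ (P_in(i) − P_out(i)), the running in-set weighted CDF minus the
running out-of-set uniform CDF, summed along the whole list — the sum
variant, not the max-deviation statistic of two-group GSEA. ES depends
only on ranks and is invariant to strictly monotone transforms of the
profile. Scores are normalised to [0, 1] by one global min–max over the
whole matrix (order-preserving; a per-set variant is deliberately not the
default, matching the subtype-analysis convention).

Subtype-specific pathways are called by SAM on the normalised set × sample
matrix plus a fold-change filter: UP iff q < 0.2 ∧ mean₁/mean₂ > 2, DOWN
iff q < 0.2 ∧ mean₁/mean₂ < 0.5 (denominator floored at 1e−6). Note that
a ratio threshold on min–max-normalised scores is harsh and asymmetric —
normalised values are affine, not ratio-scaled, and positive enrichment
stretches further from the mid-range than negative enrichment — so planted
differential sets occasionally land just inside the (0.5, 2) dead zone
with q ≈ 0; across default synthetic cohorts 8–10 of 10 planted sets are
called, with misses attributable to the fold-change filter, never to q.

## Drug sensitivity

Dose–response curves use final assay concentrations (stock serial dilution
times the in-well dilution, e.g. 200 µM stock, 1:4 steps, halved on
addition to cells; 9 points by default). The 4PL refit
v(c) = bottom + (top − bottom)/(1 + (c/IC50)^hill) runs on log
concentration with multi-start initialisation (5 IC50 × 3 Hill starts,
bounded parameters); non-convergence from every start is flagged, never
silently replaced. A fit is censored — reported at the top tested dose
with a flag — when the fitted IC50 exceeds that dose, the curve stays
above 50% viability at the top dose, or the fitted dynamic range is
negligible; censored values are *retained* in comparisons (dropping
non-responders would bias a cohort toward apparent sensitivity).
Per drug, the two clusters are compared by the two-sided Mann–Whitney U
test on log10 IC50 (identical to the raw-scale rank test), summarised by
cluster medians, their ratio as the fold difference, and the lower-median
cluster named sensitive; no multiple-testing correction across drugs is
applied (p-values are reported per drug and ranked).

## Synthetic cohorts

Defaults: 60 samples in two equiprobable clusters; 2000 genes = 100
drivers + 400 cluster markers + 1500 nulls; driver copy states follow the
cluster at purity 0.9 (gain-driven and loss-driven alternating) with
expression = baseline + β·dose + N(0, σ²), β = 1 log2 unit per dose unit,
σ = 0.5; markers shift ±1 log2 unit between clusters (a 4σ separation);
null genes carry cluster-independent states (15% gain, 15% loss) and pure
noise expression — they are what makes the measured driver false-positive
rate meaningful. Gene baselines are uniform on [4, 10] log2 units, LOH is
an independent 5% mask, gene sets are 50 sets of 15–40 genes with 10
differential sets drawn 80% from one cluster's markers, and IC50s are
log-normal around 1 µM (σ_log10 = 0.25) with an 8-fold shift on 5 of 20
drugs — within the 2–10-fold range typical of subtype-level
chemosensitivity differences. `noise_sd = 0` is allowed as the exact
noise-free limit (where dose–expression rank concordance is exactly 1).
The null generator keeps all marginal rates but removes every dependence
(β = 0, no marker shift, purity 0.5, fold 1).

What the generator does *not* emulate: probe-level noise and GC waves,
segmentation artifacts, gene–gene correlation beyond the planted block
structure, batch effects, aneuploidy-scale events spanning chromosome
arms, or censored IC50s. Passing recovery tests therefore demonstrates
the pipeline's correctness and calibration under its own model
assumptions, not robustness to those real-data complications.

## Problem sizes and numerics

The shipped tests and the acceptance script run at the scale the defaults
describe: 10 cohorts for driver/consensus recovery, 20 simulations each
for SAM null and planted calibration (200–220 features, 10 vs 10, 1000
permutations), 100 random cases for the ssGSEA oracle, and one end-to-end
default cohort; the whole suite completes in about a minute on one CPU.
Tolerances: oracle comparisons at 1e−12; exact 4PL recovery at 1e−6
relative; everything stochastic is asserted on the aggregate (mean or
median across seeds). Degenerate inputs (constant vectors, empty groups,
zero scatter with equal means, constant enrichment matrices) raise typed
errors or are defined to 0 where the limit is unambiguous. All randomness
flows from explicit seeds: the generator from `CohortSpec.seed`, each
pipeline stage from a fixed offset of `PipelineConfig.rng_seed`, so
`run-all` equals the stages run separately and repeated runs are
bit-identical.
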