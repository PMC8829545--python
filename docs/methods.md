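# Methods

This note documents the models and procedures the package implements,
the defaults it ships, the numerical choices behind them, and what the
synthetic cohorts do and do not establish.

## Data model and preprocessing

An `EventTable` is a dense cells × markers matrix with per-cell
annotations (subject, clinical group, compartment, and — for synthetic
data — the latent population). Raw intensities are variance-stabilized
with `asinh(x / cofactor)`; the cofactor defaults to 5, the usual
choice for mass cytometry (flow cytometry conventionally uses ~150).
All gating thresholds, clustering distances and MSI values live on the
transformed scale. The transform is strictly monotone per channel, so
it commutes with any threshold-based gate up to re-expressing the
threshold.

Files are FCS 3.0/3.1 or TSV. The FCS layer implements the list-mode
float subset of the standard directly (header, delimited TEXT segment,
`$DATATYPE F/D`, `$MODE L`); no compensation or spillover handling is
applied, which matches mass-cytometry practice where spillover is
minimal and usually corrected upstream if at all. Written FCS is 3.1
little-endian float32, so values round-trip to ~1e-7 relative error.

Downsampling (used when a compartment yields hundreds of thousands of
cells) is uniform without replacement, seeded; an optional per-subject
stratified mode draws proportionally from each donor with
largest-remainder rounding. Unstratified is the default because a
uniform subsample preserves cohort-level composition in expectation.

## Synthetic cohorts

The generator is the package's ground-truth instrument. Cells arise
from a finite set of population archetypes; each archetype has a
per-marker normal profile on the arcsinh scale (negatives at 0.3,
positives at 3.5, CD56-dim 2.5 / CD56-bright 5.0, SD 0.35 by default),
so every informative marker is bimodal across the cohort — the shape
manual gating assumes. Membership follows a multinomial-logit model:

    P(cell of subject i, group g, compartment c in population p)
      = softmax_p(base_p + u_i [p enrichable] + enrich[g, p] + shift[c, p])

* `enrich` holds the planted group effects; because a binarized
  enrichable population follows exactly a logistic mixed model, these
  log odds ratios are what the enrichment fitter must recover.
* `u_i ~ N(0, subject_sd²)` is a per-subject random intercept, drawn
  once per donor and shared across that donor's compartments, so
  paired blood/LN samples are correlated the way real donors are.
  By default one scalar applies to the designated "enrichable"
  populations (a constant added to *all* logits would cancel in the
  softmax). The alternative `subject_effect="per_population"` draws an
  independent intercept per subject × population, giving every
  cluster's abundance its own subject-level dispersion — the structure
  the per-cluster GLMM assumes; it is the right null model for
  calibration studies, and the shared scalar the right minimal model
  for single-effect recovery.
* `shift` plants compartment effects (the replica default: more
  Tfh-like CD4 T and CD56-bright NK cells in LN, fewer activated
  effector CD8 and CD56-dim NK), so paired tests have known targets.

The shipped replica cohort has 19 subjects (5 controllers, 8
acute-treated, 6 chronic-treated), two compartments, 42 markers and 8
populations; the population count is a fixture choice, not an estimate
of any real cohort's structure. Enriching one population necessarily
depletes the others (composition sums to one); the compositional
log-odds ripple on other populations is small only when the enriched
population is rare, which the examples and tests exploit deliberately.

What the generator does **not** emulate: instrument artifacts (bead
normalization drift, doublets, barcode crosstalk), marker correlations
within a population (profiles are independent normals), heavy-tailed or
zero-inflated intensity distributions, and batch effects. Passing tests
therefore demonstrate correctness of the algorithms under a clean
mixture model, not robustness to real-data pathologies.

## Gating

Gate trees are declarative configs: nodes with a parent and a
conjunction of atoms; a cell is in a gate iff it is in the parent and
satisfies every atom. Sign atoms `M+`/`M−` split on a threshold with
`+` closed (value ≥ t), so a +/− pair partitions the parent exactly;
interval atoms `M in [lo, hi)` implement bright/dim/negative strata
with boundary values assigned to the higher stratum. Thresholds are
config values, not code: real gates are dataset-specific manual
decisions, and the shipped defaults (midpoints between the synthetic
archetype levels: 1.9 for ±, 1.4/3.75 for CD56) are only correct for
the synthetic cohorts. The auxiliary Tdp/Tdn quadrant gates exist so
declared CD45RA × CD45RO partitions are provably exhaustive.

Frequencies are percentages of a denominator gate per subject ×
compartment, with an empty denominator yielding a missing value rather
than zero. MSI is the arithmetic mean of the transformed marker over
the donor's gated cells.

## SNN clustering

Neighbors are exact k nearest (k = 20 default) by Euclidean distance on
the clustering channels, self excluded, distance ties broken toward the
lower cell index; the implementation widens its candidate window until
the boundary is unambiguous, so it equals a brute-force scan even with
duplicated points. Edge weights are the Jaccard similarity of the two
kNN sets (`|∩| / (2k − |∩|)` for equal-size sets), pruned at 1/15.
Communities come from Leiden optimization of resolution-scaled
modularity with a fixed seed; Leiden rather than classic Louvain
because it exposes seeded determinism and never produces disconnected
communities, while optimizing the same objective with the same
resolution semantics. Clusters are relabeled by descending size and
clusters under `min_cells = 50` are unassigned; a cluster of exactly 50
is retained. Unassigned cells count in neither numerators nor
denominators downstream.

## Resolution selection

For each grid resolution (20 points on [0.01, 0.2] by default) the full
data set is clustered and filtered, then cross-validated subject-wise:
each donor is held out in turn, a random forest (500 trees, √p feature
subsampling, seeded; training rows canonicalized by lexicographic sort
so the fold is invariant to cell order) is trained on the remaining
donors' assigned cells and predicts cluster labels for the held-out
cells, whose silhouette values are computed under the predicted labels.
Silhouettes use the standard `(b − a)/max(a, b)` with the singleton
convention s = 0; folds exceeding 5000 held-out cells are scored on a
seeded uniform subsample to bound the O(n²) distance cost, and a
`train_cap` option similarly bounds forest training. Held-out
silhouettes are pooled across folds, averaged within each predicted
cluster, and the unweighted mean over clusters is the score — held-out
cells only, never pooled with training cells. Folds whose training
labels cover fewer than two clusters are skipped with a warning; a
resolution whose folds all skip gets a missing score.

Identical partitions at different resolutions necessarily share a
score, so scores are memoized on the label vector; on well-separated
data the whole grid often collapses to one evaluated partition.

The elbow is the grid point with the most negative discrete second
difference of score vs. grid index (ties toward the smaller
resolution, curvature below float noise ignored); score curves with no
concave corner fall back to the maximum score. This formalizes "the
elbow" reproducibly; a kneedle-style detector was considered and
rejected as needlessly parametric for 20-point grids.

## Differential abundance (GLMM)

Per cluster and per two-group contrast (controller vs. acute, chronic
vs. acute, controller vs. chronic by default), cell membership is
aggregated to per-subject binomial counts — the likelihood is identical
to the per-cell Bernoulli model — and fit as

    y_i ~ Binomial(n_i, p_i),  logit p_i = β0 + β1·group_i + u_i,
    u_i ~ N(0, σ²)

by maximizing the Laplace-approximated marginal likelihood (inner
1-D Newton for each subject's conditional mode; outer L-BFGS-B over
(β, σ) with σ bounded below by 1e-6, at which the model collapses
smoothly to the ordinary GLM). Against lme4's `glmer` on the same data
the coefficients, SEs and σ agree to ~1e-3.

Wald SEs come from the observed information of the fixed effects with
σ held at its estimate. Two-sided p-values use a t reference with
between-subject degrees of freedom (subjects − parameters): group
effects are identified across donors, and with 10–20 donors the normal
reference was measurably anticonservative (≈13% type-I at nominal 5% in
simulation; the t reference restores ≈5%). Non-convergence and
(quasi-)separation (|log-OR| ≥ 8 or non-finite SE) are flagged in the
output row, never silently dropped; flagged rows are excluded from the
BH family because their p-values are not interpretable. BH runs jointly
over all cluster × contrast tests of a scan, threshold 0.05.

## Subset-level statistics

Paired and unpaired Student t tests operate on per-donor summaries
(frequencies, MSI), matching arms by donor id for paired comparisons —
never on cells, which would pseudoreplicate. Zero-variance inputs raise
rather than returning NaN; within a scan such undefined rows are kept
with missing p-values. Donor exclusions are explicit arguments and are
logged, never automatic. The marker-quantile linear model summarizes
each donor by a quantile (default median) of the transformed marker
within a gate and regresses it on group indicators by OLS; BH runs
across all marker × group coefficients.

## Problem sizes

Validation runs use deliberately desk-scale designs: resolution
recovery on 8 subjects × 2000 cells × 10 markers with 5 populations
≥ 6 SDs apart (10 seeds); GLMM recovery and null calibration on 5
subjects/group × 2000 cells over 50 replicates; oracle comparisons on
200–500 cells where O(n²) references are exact. These sizes make every
property checkable in minutes while keeping each statistical design at
the scale the estimators actually face (donor counts of 10–19).

## Known limitations

* The GLMM uses Laplace (one quadrature point); with very small
  per-subject cell counts (tens of cells) adaptive quadrature would be
  more accurate.
* Silhouette subsampling above 5000 cells per fold introduces seed
  dependence of order 1/√n in the score; the cap is configurable.
* Gate thresholds must be supplied for real data; no density-based
  automatic gating is included.
* tSNE/UMAP visualization is out of scope; cluster labels and edge
  lists can be exported for external tools.
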