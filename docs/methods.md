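# Methods

This note documents the models and procedures implemented in `ecatlas`,
their assumptions, the parameters that matter, and the numerical choices
made where the design was genuinely open. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Synthetic data (`ecatlas.syndata`)

The generators exist so that every analysis stage has a ground-truth test
surface; they emulate the *statistical* structure of an EC-enriched breast
atlas, not its biology.

**Count model.** Counts are negative binomial with the mean/dispersion
parameterization Var = μ + μ²/φ, realised as a gamma–Poisson mixture
(`φ = nb_dispersion`; `φ = inf` gives the Poisson limit used by the null
calibration tests). The mean of gene *g* in cell *i* is

    μ_ig = baseline_mean × fold^(1{g is a marker of cluster(i)}) × ℓ_i

with ℓ_i a unit-mean log-normal library factor (`library_size_log_sd`,
default 0.35). Defaults: 2000 genes, 12 clusters × 200 cells, 20 disjoint
marker genes per cluster at fold 8, dispersion 2, 9 patients, 5% of genes
flagged mitochondrial. `baseline_mean` defaults to 0.5 so that a typical
simulated cell detects comfortably more than the 300-gene cell-QC cutoff;
at much lower baselines whole simulations would be discarded by QC designed
for ~14k-gene real data. Doublets (off by default) are formed by adding a
second random cell's counts to a fraction of cells and are flagged in the
truth object so the QC doublet rule's sensitivity is measurable. An
optional per-patient log-normal multiplier (off by default) lets covariate
handling in DE be exercised.

**Trajectory.** Cells draw a latent t ~ U(0,1); ≥ 3 ordered programs have
triangular weight bumps centred at equispaced positions with half-width
equal to the spacing, so expression blends smoothly between neighbouring
programs (an artery → capillary → vein-style gradient). Labels are the
argmax-weight program; the truth stores t.

**Interactome.** Plants multiply the ligand gene's mean in the source
cluster and the receptor gene's mean in the target cluster by a stated
fold; all other ligand/receptor genes stay at baseline everywhere.

**Cohorts.** Exponential cause-specific hazards (defaults: 0.02/yr for the
breast-cancer-specific event, 0.015/yr competing), treated-arm hazards
multiplied by the planted ratios, administrative censoring at 14 years.
Covariates for matching: age ~ N(60, 10), BMI ~ N(26, 4), categorical
stage/grade with fixed probabilities — arbitrary but fixed, so matching
tests are reproducible. `simulate_registry` additionally produces a
pre-inclusion screening table (4924 patients, 265 missing a covariate, 11
early discontinuers, 358 continuously exposed > 1 year) for exercising the
inclusion arithmetic.

**What the generators do not model:** gene–gene correlation beyond cluster
programs, ambient RNA, batch effects beyond the optional patient
multiplier, non-proportional hazards. Passing tests therefore demonstrate
correctness of the *procedures* under a faithful null/planted-signal model,
not robustness to every artefact of real data.

## QC and normalization (`ecatlas.qc`)

Genes are kept when expressed (count > 0) in at least `min_cells_per_gene`
(10) cells *and* the raw row mean is at least `min_gene_row_mean` (0.003)
counts per cell; removal is by strict inequality, so exact-boundary genes
survive. The row mean is computed as sum/n in float64 so an exactly-0.003
gene is not lost to rounding. Cells are removed when they detect fewer
than 300 genes, more genes than mean + 2 SD (doublet suspects; the
statistics are computed over cells that already pass the 300-gene rule so a
low-quality tail cannot drag the cutoff), or derive > 10% of UMIs from
mitochondrial genes. Genes are filtered before cells; the order is a
documented choice. The per-cell report attributes each removal to the
first failing rule in that order. The mean + k·SD rule is idempotent only
when the doublet mode is separated from the singlet bulk (each pass
otherwise clips a fresh upper tail); this is the regime the rule targets
and the regime in which the property is tested.

Normalization: per-cell depth scaling to `target_sum` (default 10,000;
`None` = median depth), natural-log log1p, then a per-gene z-scored copy in
`layers["scaled"]` (population SD; zero-variance genes map to 0, not NaN).
The choice of target sum and log base is recorded in
`.uns["normalization"]`.

## Marker discovery (`ecatlas.markers`)

For every ordered cluster pair, the per-gene test is an ordinary
two-sample linear-model t on log-normalized values, optionally with the
patient as an additive covariate (vectorized OLS; equal-variance two-sample
t when no covariate). Empirical-Bayes variance moderation is deliberately
omitted: the marker ordering is driven by the rank-product combination
across all pairwise contrasts, not by any single pair's p-value, and the
test choice is recorded in the result metadata.

log₂FC is the log₂ ratio of depth-normalized linear means (pseudocount
1e-9). A difference of log1p means would compress a planted k-fold change
toward zero at low counts; the ratio form recovers log₂(k) unbiasedly and
is exactly antisymmetric under pair swap.

Within each pair, genes are ranked by log₂FC (rank 1 = most upregulated;
ties by smaller p, then gene id). The combined score per target cluster is
Σ log(rank) over its pairs — monotone-equivalent to the rank product
without overflow. Final-score ties break by larger mean log₂FC, then gene
id. Because the published semantics of restricting to "uniquely
upregulated" genes before ranking are not fully specified, all genes are
ranked and a `uniquely_up` flag (log₂FC > 0 in every pair) is emitted so
both readings are available. Benjamini–Hochberg adjustment is applied
within each pair (and in condition DE, where discoveries require adjusted
p < 0.05 and the sign convention — positive = higher in peri-tumoral — is
recorded in the output).

## Taxonomy (`ecatlas.taxonomy`)

Clustering is a pluggable contract; the shipped default is deterministic
k-means on the leading principal components of the scaled layer, adequate
for well-separated planted programs and reproducible under a fixed seed
(graph-based community detection can be supplied as a backend callable).

Centroids are per-cluster means (optionally medians) of normalized log
expression. Trees use Euclidean distance and complete linkage over
centroid rows.

**Branch support.** For each scale r ∈ {0.5, …, 1.4} (10 values), gene
columns are resampled with replacement to ⌈r·F⌉ columns, `n_boot` (1000)
times, the tree is rebuilt, and each observed branch's presence frequency
BP_r is recorded. Frequencies are clamped to (0.5/n_boot, 1 − 0.5/n_boot),
probit-transformed z_r = Φ⁻¹(1 − BP_r), and fitted by weighted least
squares to z(r) = v√r + c/√r with delta-method binomial weights; the
approximately unbiased value is AU = 1 − Φ(v − c) and BP is the plain
frequency at r = 1. Branches present in every resample at every scale
short-circuit to AU = BP = 1; branches never observed get AU = 0 and a
flag. The root is reported (trivially AU = BP = 1). Features, not cells,
are resampled because the tree's units are cluster profiles. A reporting
cutoff of AU ≥ 0.4 is the default in `supported_branches`.

**Projection.** On the shared feature set (≥ 10 features required), each
query cell's cosine similarity, Pearson and Spearman correlation to every
reference centroid are computed; the cell is assigned to the cosine argmax
when at least two measures agree on that cluster and the cosine reaches the
threshold (default 0.5), else "unassigned". The reported similarity index
is the cosine (choice documented; the consensus rule is configurable in
spirit — it mirrors the cited cluster-projection algorithm's default
behaviour).

**Congruency.** Jaccard coefficients over marker gene sets (empty sets
give 0 with a warning); the pooled square Jaccard matrix is row-centred and
embedded by 3-component PCA; `shared_top_n` counts genes ranking in both
clusters' top-n (default 50).

## Trajectory (`ecatlas.trajectory`)

Highly variable genes: mean depth-normalized expression strictly inside
(0.05, 8), ranked by dispersion (variance/mean), top 50% kept. The band is
defined on a raw-count-like scale, so median-depth normalization
(`target_sum=None`) is the natural companion.

Pseudotime: PCA to 8 components, k-means with k = 3 waypoints, waypoint
order chosen exhaustively (k ≤ 6) to minimize polyline length, cells
projected to their nearest polyline point, arc length min-max rescaled to
[0, 1]. The first and last segments extend beyond their terminal waypoints
so boundary cells keep distinct positions. This is a deliberate,
documented stand-in capturing the essential mechanism of linear trajectory
inference; the module accepts any externally computed pseudotime series
for the smoothing and regression steps.

Cluster smoothing: per-cluster 0.25/0.75 pseudotime quantiles (type-7
linear interpolation, recorded in the result), clusters ordered by lower
quantile (ties by upper quantile, then label), boundary between neighbours
= mean of the earlier upper and later lower quantile; the outer ends are
pinned to 0 and 1 (the smoothing rule does not define them), so ranges tile
[0, 1] exactly. Reversing t reverses the order and maps boundaries to
1 − boundary whenever the lower- and upper-quantile orders agree (always
true for separated clusters).

Expression curves: for each of 100 grid points, the span-fraction (0.2)
nearest cells receive tricube weights and a weighted linear fit is
evaluated at the grid point; windows below 3 cells are widened to 3 and
flagged. Local linear fitting is exact for linear signals and constant for
constant genes.

## Interactome (`ecatlas.interactome`)

A partner (ligand or receptor, possibly multi-subunit) is expressed in a
cluster when *each* component gene is detected in ≥ 25% of the cluster's
cells (the threshold is a fraction of cells, the cited framework's
convention); the partner's cluster-level expression is the minimum over
components of the cluster mean of log-normalized expression, and the
interaction mean of a (pair, source, target) row is the average of the two
sides. The null shuffles cluster labels over all cells (500 iterations)
and p = (1 + #{null ≥ observed}) / (iterations + 1), so p is never 0 and
the floor is 1/501. Filters: EC-self rows excluded; rows touching clusters
below 100 cells excluded; EC-side genes must be enriched at log₂FC ≥ 0.25
against *all* other EC subclusters (the pairwise minimum, supplied as a
genes × clusters table from `min_pairwise_lfc`); for the venous analysis a
(pair, partner, direction) is kept only when significant in ≥ 3 of the 4
venous subclusters, with the mean averaged over the four. Flags are
computed independently, so the outcome does not depend on application
order. A minimal bundled pair table covers well-known EC–immune axes; real
analyses should supply a full database as TSV.

## Composition (`ecatlas.abundance`)

Fractions are computed within each (patient, condition) sample (absent
clusters get 0; empty samples are omitted with a warning). The paired
t-test uses only patients contributing both conditions; optional pooling
sums fractions over a cluster group before testing, which by linearity
equals testing the summed fractions. Per-subcluster p-values are reported
without multiplicity correction by default (a BH option exists), matching
the per-subcluster reporting convention of paired atlas comparisons.

## Cohort (`ecatlas.cohort`)

Exposure: a patient joins the treated group only with a *continuous*
intake interval strictly longer than 1 year; patients with shorter
exposure are excluded (not controls), as are patients missing any matching
covariate; an exclusion report is emitted. Deaths of unknown cause become
disease-specific in the presence of relapse and other-cause in its
absence; unknown cause on a censored record is an error.

Cumulative incidence is the Aalen–Johansen estimator
CIF(t) = Σ_{t_i ≤ t} S(t_i⁻) · d_event(t_i)/n(t_i) with S the all-cause
Kaplan–Meier; it is hand-implemented (the step function and at-risk counts
at 5/8/10/14 years are needed exactly) and cross-checked in the tests
against `lifelines.AalenJohansenFitter` as an independent estimator. The
identity CIF₁ + CIF₂ + S_all-cause = 1 holds at every event time to 1e-9.
With no competing events CIF = 1 − KM exactly. Log-rank compares two
groups on the event of interest with competing events censored for the
test (documented convention; delegated to lifelines), and Kaplan–Meier
summaries use lifelines' product-limit estimator with log-log confidence
intervals. Cox regression (and the robust sandwich variance used with
matched data) is out of scope; `hazard_reduction` converts an externally
estimated hazard ratio to a signed percent reduction, (1 − HR) × 100.

Matching is greedy nearest-neighbour without replacement: exact on stage
and grade, minimal standardized Euclidean distance on (age, BMI), up to 2
controls per treated patient, ties and processing order broken by patient
id for determinism; under-matched patients are reported rather than
silently dropped.

## Pipeline and CLI

`ecatlas.pipeline` sequences the stages from a plain config mapping
(YAML-loadable); every report embeds the seed, a SHA-256 config hash and
the versions of the numerical libraries of record. Stage failures abort
with the stage name. The `ecatlas` CLI exposes `simulate`, `atlas`,
`congruency`, `interactome` and `cohort` subcommands with `--config`,
`--seed`, `--outdir`, `--log-level`.

## Problem sizes and determinism

The validation suite and the acceptance script work at deliberately modest
scales chosen as the package's own test conditions: the default 12-cluster
× 200-cell simulation for marker recall, 5-cluster simulations for
projection and pseudotime, 500 null ligand–receptor pairs at 500
permutation iterations for calibration, and 2000 patients per arm for
hazard-ratio recovery. Every stochastic step takes an explicit seed
(NumPy `default_rng`); identical seeds give bit-identical outputs.

## Known limitations

- The per-gene DE test has no variance moderation; at very small cluster
  sizes (< ~10 cells) its p-values are noisier than a moderated test,
  although the rank-product ordering is robust to this.
- The k-means clustering fallback assumes roughly spherical, comparable-
  size clusters; real atlases should plug in a graph-based backend.
- The polyline pseudotime is linear by construction and cannot represent
  branching trajectories.
- AU values inherit the usual small-sample noise of the multiscale
  bootstrap extrapolation when branch frequencies sit near 0 or 1 at every
  scale.
- The exposure rule treats intake intervals as exact; no immortal-time
  adjustment is applied beyond the continuous-intake requirement.
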