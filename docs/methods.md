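# Methods

This note documents the models and procedures implemented in `spatialtme`,
the parameters that matter, the design choices made where the design was
genuinely open, and the limits of what the synthetic cohorts can show.

## Data model

A cohort is two tables.  The *cell table* has one row per segmented cell:
`cell_id, sample_id, patient_id, x, y[, area]` plus one intensity column
per marker of the panel (default 11 markers: CD20, CD3, CD4, CD8, Foxp3,
CD68, CD163, PD-1, PD-L1, CD96, CD45; Tbet is excluded because its
immunofluorescence signal is too weak to use).  Coordinates are continuous
pixel centroids; all geometry is Euclidean in pixels, and micrometres
appear only in reports.  The conversion default is 1/3 µm/px — the
convention under which the reporting thresholds used throughout round
exactly (60 px ↔ 20 µm, 400 px ↔ 133 µm, 800 px ↔ 267 µm) — and is
overridable per panel (e.g. to an imaging-true 0.325).  The *clinical
table* has one row per patient with `pfs_time/pfs_event`,
`os_time/os_event` (months, 0/1) and arbitrary categorical labels.

Quality control keeps cells with segmented area ≥ 100 px (the rule is
"area < 100 removed", so exactly 100 survives).  Whether that area is the
nuclear or expanded-cell mask is upstream's concern; the filter is generic.

## Phenotyping

1. **Clustering.** Intensities are min-max normalized per marker (the
   normalization is configurable; min-max is the default because the
   pipeline's accuracy is carried by the mapping step, not the scaling).
   A kNN graph (k = 100) is built in marker space, edges weighted by the
   Jaccard overlap of neighbor sets, and partitioned by Leiden modularity
   (seeded; Louvain available).  Rows are canonicalized by `cell_id`
   before graph construction so results are independent of input order.
   Modularity maximization oversplits dense homogeneous populations — a
   well-known property, and the reason cohort pipelines of this kind
   report ~30 clusters for ~8 cell types.  That is harmless here and the
   default resolution (1.0) accepts it; `resolution ≈ 0.1` merges to the
   population level when the true number of types is small.
2. **Cluster→type mapping.** Per lineage marker, log cluster means are
   min-max scaled across clusters and called positive at ≥ 0.5; each
   cluster gets the main type whose signature (e.g. CD3⁺CD4⁺ for CD4
   T cells, CD68⁺CD163⁺ for M2-like macrophages, all-negative for
   nonimmune) matches its positivity pattern on the most markers.  The log
   scale makes the midpoint a stable positivity call even when clustering
   subdivides a population by intensity magnitude.  The auto-map is a
   plain dict intended to be reviewed and edited — in real cohorts this
   step is a curated artifact, and keeping it as an explicit object makes
   the curation reproducible.
3. **Gating.** Mixed clusters can be re-assigned by ordered threshold
   rules (first match wins; unmatched cells fall back to a configured
   residual class).  Thresholds are inclusive (≥).
4. **Checkpoint calls.** Main types split by checkpoint positivity into
   17 final labels: PD-L1/CD96 on B cells, PD-1/CD96 on CD4 and CD8
   T cells, PD-1 on Tregs, PD-L1 on both macrophage subsets, plus the
   "other immune" and "nonimmune" residual classes.  This composition of
   the 17-label set is an inferred artifact default (no published
   enumeration exists), as are the numeric thresholds (default 3.0 raw
   units = the geometric midpoint of the synthetic negative ≈ 1 and
   positive ≈ 8 populations; real cohorts must recalibrate).

## Interaction testing

Within one sample, the statistic for the ordered pair (a, b) is the mean
count of type-b cells within radius r of each type-a anchor (r = 60 px,
radius inclusive; anchor-normalized so the statistic is insensitive to
anchor abundance).  The null preserves geometry and composition exactly:
all phenotype labels are shuffled jointly over cell positions (default
1,000 permutations, one shared permutation stream for all pairs of a
sample).  Reported per pair: observed, permutation mean/sd, z, direction,
and a **two-sided** permutation p — the observed-direction tail
probability `(1 + #extreme)/(n_perm + 1)` doubled and capped at 1.  The
doubling matters: the tail is chosen after seeing the data, and without it
the false-positive rate at α is 2α.  Measured on 200 neutral
(complete-spatial-randomness) pair tests the rate at α = 0.05 is
0.025–0.05 (the cap makes the test slightly conservative).  Pairs with no
anchor cells are reported missing, never zero.  Cohort summaries are
available-case means of z; per-sample profiles over selected pairs (both
anchor directions of each T–B pair by default) are clustered with
Ward/Euclidean after dropping samples with no defined entries and imputing
remaining missing entries at the neutral value 0.

## RCN discovery

Neighborhood documents count phenotypes over a cell and its 19 nearest
within-sample neighbors (documents sum to 20; distance ties at the 19th
neighbor break by lowest `cell_id` for determinism; samples smaller than
20 cells are excluded with a warning).  A 10-motif LDA is fit jointly
across all samples — motifs are meant to be shared, and a joint fit is
what makes the labels comparable across cores — with symmetric priors
α = 1/n_topics on document–motif and β = 0.01 on motif–phenotype
(variational Bayes, 30 iterations).  The variational objective has local
optima in which two motifs merge; the fit therefore runs 4 restarts and
keeps the best evidence bound, the same restart policy K-means uses and
decided entirely on the model's own objective.  K-means (k = 10, 10
restarts, rows canonicalized by `cell_id`) clusters the motif weights into
RCNs, relabeled RCN1…RCN10 by descending cohort abundance so names are
stable.  A scree curve over candidate k with an elbow suggestion (argmax
of the discrete second difference) supports choosing k; the suggestion is
advisory.  An RCN counts as *present* in a sample if it holds ≥ 1% of the
sample's labeled cells (configurable; no published rule exists).

## Spatial organization and outcome statistics

D[x→y] is the mean over RCN-x cells of the distance to the nearest RCN-y
cell (asymmetric; diagonal fixed at 0 by convention; missing when either
RCN is absent).  S = (D + Dᵀ)/2 is averaged available-case across samples;
each RCN's single outgoing "closest" edge goes to its argmin-S partner
(ties to the lower RCN index), weighted 1/S.  Patient-level pair distances
aggregate S over the patient's 2–3 cores where both RCNs occur (mean by
default; min/max for sensitivity).  Dichotomization is *near* strictly
below the cutoff; patients whose cores never contain the pair join the
*far-or-absent* group by design — absence of a neighborhood is treated as
the same exposure as distance.

Survival machinery: Kaplan–Meier and log-rank via lifelines; Cox
proportional hazards with Efron tie handling (duplicating a dataset
preserves the estimate only to the tie-correction's accuracy, ~1e-3).
The maximally-selected cutoff search evaluates the standardized two-group
log-rank statistic at every candidate cutoff — observed feature values in
the 10th–90th percentile band leaving ≥ 10 patients per side, or an
explicit candidate list — and selects the argmax of |z|.  Its p-value is
the permutation tail of the *maximum* statistic (default 1,000 feature
permutations), which corrects the selection; the naive minimum p is also
reported and is, as expected, anti-conservative (measured: ~4× the nominal
rate under the null).  The multi-cutoff log-rank core is vectorized over
cutoffs (one pass over distinct event times with cumulative risk sets) and
validated against the ordinary log-rank test at single splits to 1e-8.
Group comparisons use Mann–Whitney U / Kruskal–Wallis H with BH correction
within one scan-family.

## Synthetic cohorts

The generator emulates a TMA cohort: each patient contributes 2–3
1-mm-core samples (disc radius 1540 px), cells placed on the disc,
phenotypes drawn from a 17-label mixture whose defaults reflect a B-cell
lymphoma TME (B cells ≈ 55%, CD4 T ≈ 14%, CD8 T ≈ 10%, M2-like ≈ 8%,
M1-like ≈ 5%, Tregs ≈ 4%; PD-1⁺ fractions of 21%/11% among CD4/CD8 T,
PD-L1⁺ fractions of 37%/12%/4% among M2/M1/B; CD96⁺ fractions set to 5% as
a generator choice), with mild per-sample Dirichlet heterogeneity
(concentration 150).  Marker intensities are log-normal per (phenotype,
marker): signature markers at 8-fold separation, σ = 0.3 — near-perfect
Bayes separability, chosen so that phenotyping failures indicate pipeline
bugs; lower the separation for stress tests.

Planted structure uses mechanisms with closed-form expectations:
*attraction* is Thomas-type parent–offspring placement (offspring at
Gaussian offsets, s.d. = strength px, around uniform parents — the excess
neighbor count within r is 1 − exp(−r²/2s²)); *avoidance* is hard-core
rejection within an exclusion radius (infeasible configurations error
after bounded attempts); *neutral* is uniform on the disc.  By default the
cohort's two patient groups carry opposite plans for the (B cell, PD-1⁺
CD4 T cell) pair — avoidance (60 px exclusion) in group 0, attraction
(30 px dispersion) in group 1 — which is what the interaction-profile
clustering stage is expected to recover.  Motif regions for RCN truth are
Voronoi cells of seed points (default: 10 sunflower-layout seeds, each
region's mixture dominated 0.7 by a distinct phenotype echoing recurring
neighborhood themes: tumor-B-rich, CD8-rich, CD4-rich, PD-1⁺-rich,
nonimmune, macrophage-subset-rich, PD-L1⁺-rich).  Survival is exponential
proportional hazards on patient features (default log-HR = log 3 on the
planted group, baseline 0.008/month ≈ 7-year median, administrative
censoring at 120 months).  One RNG stream per (patient, core) derived from
the master seed keeps cohorts reproducible under partial regeneration.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: intensity spillover between adjacent cells
("signal leakage"), staining artifacts and batch effects, irregular tissue
boundaries and holes, continuous phenotype gradients (labels are
categorical truth), spatial autocorrelation of intensity noise, and
informative censoring.  Recovery rates measured here are upper bounds for
real cohorts, where gates and cluster maps require curation.

## Problem sizes and numerical choices

The recovery suites run at deliberately chosen scales: phenotyping and RCN
recovery on 10 cores × 2,000 cells (20,000 cells — large enough that
k = 100 graphs and 20-cell documents behave as in cohort data);
permutation calibration on 50 cores of 500 cells at 1,000 permutations;
survival recovery at n = 300–400 patients.  Degenerate inputs are defined,
not errors, wherever a convention exists: identical intensities give one
cluster; identical documents give identical motif weights; a flat scree
curve returns the lowest k with a warning; a permutation-invariant
statistic gives z = 0, p = 1; absent phenotypes/RCNs propagate as missing
values rather than zeros.  Known limitations: the elbow suggestion is a
heuristic; LDA restarts trade a ~4× fit cost for escaping topic-merging
optima; the auto phenotype map assumes each main type's signature is
attainable from the panel; and the proximity graph is a nearest-neighbor
summary, not a spatial model.
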