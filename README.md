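# spatialtme

Spatial single-cell analysis of the tumor microenvironment (TME) for
multiplex-immunofluorescence (mIF) cohorts, built around the analysis
pattern used in diffuse large B-cell lymphoma (DLBCL) tissue-microarray
studies: per-cell marker intensities from 1-mm cores are phenotyped,
cell–cell attraction/avoidance is scored against permutation nulls,
recurrent cellular neighborhoods (RCNs) are discovered with topic models,
and the spatial organization of those neighborhoods is tied to patient
survival.

The package is a library: you import it from Python (like scanpy or
scimap), and `examples/` contains one short script per capability.  A
synthetic-cohort generator with planted ground truth stands in for imaging
data, so every stage is testable end to end.

## What it computes

**Phenotyping.** Cells are clustered PhenoGraph-style — a k-nearest-neighbor
graph (k = 100) in min-max–normalized marker space, Jaccard edge weights,
Leiden modularity communities — then clusters are mapped to eight main cell
types (B cells, CD4⁺/CD8⁺ T cells, Tregs, CD163⁻/CD163⁺ macrophages, other
immune, nonimmune) by marker-signature agreement, refined by optional
threshold gates, and split by inclusive PD-1/PD-L1/CD96 positivity
thresholds into a 17-label phenotype set.

**Interactions.** For an ordered phenotype pair (a, b) in one sample, the
observed statistic is the mean number of b-cells within r = 60 px (20 µm)
of an a-cell.  The null shuffles phenotype labels over fixed positions
(1,000 permutations), giving z = (obs − mean)/sd and a two-sided
permutation p.  Per-sample z-profiles over T-cell–B-cell pairs are
Ward/Euclidean clustered into cohort groups.

**RCNs.** Each cell's neighborhood document is the phenotype histogram of
itself plus its 19 nearest neighbors (counts sum to 20).  A 10-motif
latent Dirichlet allocation is fit jointly across samples (variational
Bayes, best of 4 restarts by evidence bound) and K-means (k = 10) on the
motif weights yields RCN labels, canonically numbered by cohort abundance.

**Organization & outcome.** D[x→y] = mean distance from a cell in RCN x to
the nearest cell in RCN y; symmetrized distances define a closest-RCN
proximity graph and per-patient RCN-pair distances.  Patients split into
*near* (< cutoff) vs *far-or-absent* groups; cutoffs come from maximally
selected rank statistics (standardized log-rank over candidate cutoffs,
selection-adjusted p by permutation of the maximum).  Kaplan–Meier,
log-rank, Cox (Efron ties), Mann–Whitney/Kruskal–Wallis and
Benjamini–Hochberg round out the statistics.

## Worked example

```python
from spatialtme import SyntheticConfig, generate_cohort
from spatialtme.phenotyping import assign_phenotypes

cfg = SyntheticConfig(n_patients=3, cores_per_patient=2, cells_per_core=1500)
cells, clinical, truth = generate_cohort(cfg, seed=2)
labeled = assign_phenotypes(cells, seed=0)
t = truth.cells.set_index("cell_id")["phenotype"]
acc = (labeled["phenotype"].to_numpy() == t.loc[labeled["cell_id"]].to_numpy()).mean()
print(f"phenotype accuracy vs planted truth: {100 * acc:.2f}%")
```

prints

```
phenotype accuracy vs planted truth: 98.26%
```

i.e. on a 9,000-cell cohort at the generator's default 8-fold marker
separation, the full cluster → map → gate → checkpoint pipeline reassigns
98.3% of cells their planted 17-way label.  `examples/03_interactions.py`
shows the corresponding interaction stage: with B cells planted to avoid
PD-1⁺ CD4 T cells in one core it prints

```
type_a           type_b            observed  perm_mean      z      p  direction
B cell           PD-1+ CD4 T cell     0.0      0.068    -9.058  0.002  avoidance
```

an observed neighbor count of zero against a permutation mean of 0.068 —
the planted avoidance, recovered with the correct sign and a small
two-sided permutation p.  The other examples cover cohort simulation, RCN
discovery (adjusted Rand index ≈ 0.9 against planted motif regions), and
the proximity-to-survival stage.

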