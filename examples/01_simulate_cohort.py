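"""Generate a synthetic TMA cohort with planted ground truth.

Builds a small cohort (6 patients x 2 one-millimetre cores, 1,000 cells per
core), prints the table shapes, the cohort-level phenotype frequencies next
to the generator's targets, and the planted patient groups that carry
opposite B-cell/PD-1+ T-cell interaction structure.
"""

import pandas as pd

from spatialtme import SyntheticConfig, generate_cohort
from spatialtme.synthetic_cohort import default_phenotype_mixture

cfg = SyntheticConfig(n_patients=6, cores_per_patient=2, cells_per_core=1000)
cells, clinical, truth = generate_cohort(cfg, seed=1)

print(f"cells: {cells.shape[0]} rows x {cells.shape[1]} cols "
      f"({cells['sample_id'].nunique()} cores)")
print(f"clinical: one row per patient -> {len(clinical)} rows\n")

observed = truth.cells["phenotype"].value_counts(normalize=True)
target = default_phenotype_mixture()
top = pd.DataFrame({"target": target, "observed": observed}).fillna(0.0)
print("phenotype frequencies (top 6 by target):")
print(top.sort_values("target", ascending=False).head(6).round(3))

print("\nplanted patient groups (0 = B cells avoid PD-1+ CD4 T cells, "
      "1 = attract):")
print(truth.patients.groupby("group").size().rename("patients").to_string())
# The observed column should track the target within multinomial noise;
# downstream stages are expected to recover these labels and groups.
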