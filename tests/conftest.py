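"""Shared fixtures: small hand fixtures plus session-scoped synthetic cohorts.

All synthetic data is generated at test time from fixed seeds; the heavier
cohorts are session-scoped so the phenotyping/RCN recovery tests and the
acceptance suite share one computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from spatialtme import synthetic_cohort as sc


def make_cells(xy, phenotypes, sample_id="s0", patient_id="p0"):
    """Minimal cell table from coordinates + labels (helper, not a fixture)."""
    xy = np.asarray(xy, float)
    return pd.DataFrame(
        {
            "cell_id": [f"{sample_id}_{i}" for i in range(len(xy))],
            "sample_id": sample_id,
            "patient_id": patient_id,
            "x": xy[:, 0],
            "y": xy[:, 1],
            "phenotype": list(phenotypes),
        }
    )


@pytest.fixture(scope="session")
def random_core():
    """One 300-cell core under complete spatial randomness, 3 phenotypes."""
    rng = np.random.default_rng(42)
    xy = sc.place_uniform_disc(300, 800.0, rng, center=(800, 800))
    phen = rng.choice(["B cell", "CD8 T cell", "M2 macrophage"], size=300,
                      p=[0.6, 0.3, 0.1])
    return make_cells(xy, phen)


@pytest.fixture(scope="session")
def default_cohort():
    """Default interaction-planted cohort (10 cores x 2,000 cells)."""
    cfg = sc.SyntheticConfig(n_patients=5, cores_per_patient=2,
                             cells_per_core=2000)
    cells, clinical, truth = sc.generate_cohort(cfg, seed=3)
    return cells, clinical, truth


@pytest.fixture(scope="session")
def phenotyped_cohort(default_cohort):
    """End-to-end phenotyping run on the default cohort."""
    from spatialtme.phenotyping import assign_phenotypes

    cells, clinical, truth = default_cohort
    labeled = assign_phenotypes(cells, seed=0)
    return labeled, truth


@pytest.fixture(scope="session")
def motif_cohort():
    """Default RCN cohort: 10 planted motif regions, 10 cores x 2,000 cells."""
    cfg = sc.SyntheticConfig(
        n_patients=5, cores_per_patient=2, cells_per_core=2000,
        motif_map=sc.default_motif_map(), mixture_concentration=None,
    )
    cells, clinical, truth = sc.generate_cohort(cfg, seed=7)
    cells = cells.merge(truth.cells[["cell_id", "phenotype"]], on="cell_id")
    return cells, clinical, truth


@pytest.fixture(scope="session")
def rcn_result(motif_cohort):
    """LDA + K-means RCN discovery on the motif cohort (heavy; shared)."""
    from spatialtme.rcn_discovery import assign_rcns

    cells, clinical, truth = motif_cohort
    labeled, lda, rcn = assign_rcns(cells, seed=0)
    return labeled, lda, rcn, truth
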