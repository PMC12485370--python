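"""End-to-end orchestration: simulate/load -> phenotype -> interactions ->
RCN discovery -> spatial organization -> survival.

Each stage reads and writes plain tabular files inside the run directory so
any stage can be re-run or inspected in isolation, and a JSON manifest
records the seed, the parameter echo, library versions and per-stage row
counts.  The pipeline is a pure function of (inputs, config, seed): a rerun
with the same seed reproduces every table byte for byte.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import cell_data, interactions, outcome_stats, phenotyping
from . import rcn_discovery, rcn_organization, synthetic_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """All stage parameters for one pipeline run.

    Defaults mirror the analysis conventions used throughout the package:
    QC area filter at 100 px, clustering with 100 neighbors, 60-px
    interaction radius with 1,000 permutations, 20-cell neighborhoods
    (self + 19), 10 LDA motifs, 10 RCN clusters, and survival cutoffs
    searched by maximally selected rank statistics.
    """

    min_area: float = 100.0
    knn: int = 100
    resolution: float = 1.0
    radius: float = 60.0
    n_perm: int = 1000
    n_neighbors: int = 19
    n_topics: int = 10
    k_rcn: int = 10
    rcn_pair: tuple[str, str] = ("RCN1", "RCN2")
    endpoint: str = "pfs"
    microns_per_pixel: float = 1.0 / 3.0
    markers: tuple[str, ...] = cell_data.DEFAULT_MARKERS
    checkpoint_thresholds: Mapping[str, float] | None = None
    seed: int = 0

    def validate(self) -> None:
        if not (self.min_area >= 0 and self.radius > 0 and self.n_perm > 0):
            raise ValueError("invalid QC/interaction parameters")
        if not (self.knn > 1 and self.n_neighbors > 0):
            raise ValueError("invalid neighbor counts")
        if not (self.n_topics > 1 and self.k_rcn > 1):
            raise ValueError("invalid RCN parameters")
        if self.endpoint not in {"pfs", "os"}:
            raise ValueError("endpoint must be 'pfs' or 'os'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if isinstance(cfg.rcn_pair, list):
            cfg.rcn_pair = tuple(cfg.rcn_pair)
        if isinstance(cfg.markers, list):
            cfg.markers = tuple(cfg.markers)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["rcn_pair"] = list(self.rcn_pair)
        d["markers"] = list(self.markers)
        if d["checkpoint_thresholds"] is not None:
            d["checkpoint_thresholds"] = dict(d["checkpoint_thresholds"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def _versions() -> dict[str, str]:
    import lifelines
    import scipy
    import sklearn

    return {
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
        "lifelines": lifelines.__version__,
    }


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path,
    cells: pd.DataFrame | None = None,
    clinical: pd.DataFrame | None = None,
    cells_path: str | Path | None = None,
    clinical_path: str | Path | None = None,
    synthetic: synthetic_cohort.SyntheticConfig | None = None,
) -> dict[str, Any]:
    """Run every stage; write tables + manifest under ``out_dir``.

    Inputs come from in-memory tables, file paths, or a synthetic-cohort
    configuration (exactly one source for the cell table).  Returns a dict
    with the labeled cell table, interaction scores, RCN models and
    summaries, distance matrices, and survival results.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = cell_data.MarkerPanel(config.markers, config.microns_per_pixel)
    manifest: dict[str, Any] = {
        "seed": config.seed,
        "parameters": {**asdict(config), "rcn_pair": list(config.rcn_pair),
                       "markers": list(config.markers)},
        "versions": _versions(),
        "stages": {},
    }

    # --- input stage -------------------------------------------------------
    sources = sum(x is not None for x in (cells, cells_path, synthetic))
    if sources != 1:
        raise ValueError("provide exactly one of cells, cells_path, synthetic")
    if synthetic is not None:
        cells, clinical, truth = synthetic_cohort.generate_cohort(
            synthetic, seed=config.seed
        )
        truth.cells.to_csv(out / "truth_cells.csv", index=False)
        truth.patients.to_csv(out / "truth_patients.csv", index=False)
    elif cells_path is not None:
        if not Path(cells_path).exists():
            raise FileNotFoundError(cells_path)
        cells = cell_data.read_cell_table(cells_path, panel)
        if clinical_path is not None:
            clinical = cell_data.read_clinical_table(clinical_path)
    cell_data.validate_cell_table(cells, panel)
    if clinical is not None:
        cell_data.validate_clinical_table(clinical)

    # --- QC ----------------------------------------------------------------
    n0 = len(cells)
    if config.min_area > 0 and "area" in cells.columns:
        cells = cell_data.qc_filter_cells(cells, config.min_area)
    manifest["stages"]["qc"] = {"cells_in": n0, "cells_kept": len(cells)}
    logger.info("qc: %d -> %d cells", n0, len(cells))

    # --- phenotyping -------------------------------------------------------
    labeled = phenotyping.assign_phenotypes(
        cells, panel, k=config.knn, seed=config.seed,
        resolution=config.resolution,
        checkpoint_thresholds=config.checkpoint_thresholds,
    )
    proportions = phenotyping.phenotype_proportions(labeled)
    manifest["stages"]["phenotyping"] = {
        "n_clusters": int(labeled["cluster"].nunique()),
        "n_phenotypes": int(labeled["phenotype"].nunique()),
    }

    # --- interactions ------------------------------------------------------
    scores = interactions.cohort_interaction_test(
        labeled, radius=config.radius, n_perm=config.n_perm, seed=config.seed
    )
    summary = interactions.cohort_interaction_summary(scores)
    manifest["stages"]["interactions"] = {"n_tests": int(scores["p"].notna().sum())}

    # --- RCN discovery -----------------------------------------------------
    labeled, lda, rcn = rcn_discovery.assign_rcns(
        labeled, n_neighbors=config.n_neighbors, n_topics=config.n_topics,
        k=config.k_rcn, seed=config.seed,
    )
    composition = rcn_discovery.rcn_composition(labeled)
    manifest["stages"]["rcn"] = {
        "n_labeled": int(labeled["rcn"].notna().sum()),
        "prevalence": composition["prevalence"].round(4).to_dict(),
    }

    # --- spatial organization ---------------------------------------------
    matrices = rcn_organization.cohort_rcn_distances(labeled)
    S, edges = rcn_organization.build_proximity_graph(matrices)
    sample_to_patient = (
        labeled.drop_duplicates("sample_id").set_index("sample_id")["patient_id"]
    )
    pair_dist = rcn_organization.patient_pair_distance(
        matrices, sample_to_patient.to_dict(), config.rcn_pair
    )
    manifest["stages"]["organization"] = {
        "n_samples": len(matrices),
        "pair": list(config.rcn_pair),
    }

    # --- survival ----------------------------------------------------------
    survival: dict[str, Any] = {}
    if clinical is not None and len(clinical):
        merged = pair_dist.merge(clinical, on="patient_id")
        tcol, ecol = f"{config.endpoint}_time", f"{config.endpoint}_event"
        with_pair = merged[merged["present"]]
        if with_pair["distance"].nunique() >= 2 and len(with_pair) >= 25:
            ms = outcome_stats.maxstat_cutoff(
                with_pair["distance"], with_pair[tcol], with_pair[ecol],
                n_perm=config.n_perm, seed=config.seed,
                feature_name="rcn_pair_distance",
            )
            survival["maxstat"] = ms
            groups = rcn_organization.dichotomize_proximity(
                merged, ms.selected_cutoff
            )
            merged["proximity_group"] = groups.reindex(merged["patient_id"]).to_numpy()
            chi2, p = outcome_stats.logrank_test(
                merged[tcol], merged[ecol], merged["proximity_group"]
            )
            survival["logrank"] = {"statistic": chi2, "p": p}
            merged["near"] = (merged["proximity_group"] == "near").astype(int)
            if 0 < merged["near"].sum() < len(merged):
                survival["cox"] = outcome_stats.cox_fit(
                    merged, tcol, ecol, ["near"]
                )
        survival["km"] = {
            g: outcome_stats.km_estimate(sub[tcol], sub[ecol])[1]
            for g, sub in merged.groupby(
                merged.get("proximity_group", pd.Series("all", index=merged.index))
            )
        }
        manifest["stages"]["survival"] = {
            k: (v if isinstance(v, dict) else "fitted") for k, v in survival.items()
        }

    # --- outputs -----------------------------------------------------------
    cell_data.write_cell_table(labeled, out / "cells_labeled.csv")
    if clinical is not None:
        cell_data.write_clinical_table(clinical, out / "clinical.csv")
    scores.to_csv(out / "interaction_scores.csv", index=False)
    summary.to_csv(out / "interaction_summary.csv")
    proportions.to_csv(out / "phenotype_proportions.csv")
    lda.topic_phenotype.to_csv(out / "lda_topics.csv")
    rcn.centroids.to_csv(out / "rcn_centroids.csv")
    composition["composition"].to_csv(out / "rcn_composition.csv")
    composition["sample_proportions"].to_csv(out / "rcn_sample_proportions.csv")
    S.to_csv(out / "rcn_distance_symmetrized.csv")
    edges.to_csv(out / "rcn_proximity_edges.csv", index=False)
    pair_dist.to_csv(out / "patient_pair_distance.csv", index=False)
    config.to_yaml(out / "config.yaml")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)

    return {
        "cells": labeled,
        "proportions": proportions,
        "interaction_scores": scores,
        "interaction_summary": summary,
        "lda": lda,
        "rcn": rcn,
        "rcn_composition": composition,
        "distance_matrices": matrices,
        "proximity": (S, edges),
        "patient_pair_distance": pair_dist,
        "survival": survival,
        "manifest": manifest,
    }
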