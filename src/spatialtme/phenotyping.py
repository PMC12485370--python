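"""Cell phenotyping: kNN-graph community detection, cluster-to-type mapping,
threshold gating, and checkpoint-positivity calls.

The clustering step is PhenoGraph-style: a k-nearest-neighbor graph (default
k = 100) in min-max-normalized marker-intensity space, Jaccard-weighted by
neighbor-set overlap, partitioned by modularity-maximizing community
detection (Leiden by default, Louvain available).  Communities typically
oversplit true populations; that is harmless because clusters are then
mapped to the eight main cell types (by a marker-signature score over
z-scored cluster mean expression, or by a user-edited map), mixed clusters
can be refined by explicit gate rules, and finally checkpoint positivity
(PD-1, PD-L1, CD96, inclusive thresholds) refines main types into the
17-label phenotype set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .cell_data import DEFAULT_PANEL, MarkerPanel
from .synthetic_cohort import (
    MAIN_OF_PHENOTYPE,
    MAIN_SIGNATURE,
    MAIN_TYPES,
    PHENOTYPES,
    _CHECKPOINT_SPLITS,
)

__all__ = [
    "GateRule",
    "cluster_cells",
    "summarize_cluster_expression",
    "suggest_phenotype_map",
    "apply_gates",
    "call_checkpoints",
    "assign_phenotypes",
    "phenotype_proportions",
    "DEFAULT_CHECKPOINT_THRESHOLDS",
]

#: Lineage (non-checkpoint) markers used for main-type scoring.
LINEAGE_MARKERS = ("CD20", "CD3", "CD4", "CD8", "Foxp3", "CD68", "CD163", "CD45")

#: Default inclusive positivity thresholds in raw intensity units.  The
#: cohorts this package analyzes have no published numeric gates; these are
#: artifact defaults at the geometric midpoint of the synthetic negative
#: (~1) and positive (~8) populations, and must be recalibrated per cohort.
DEFAULT_CHECKPOINT_THRESHOLDS: dict[str, float] = {"PD-1": 3.0, "PD-L1": 3.0, "CD96": 3.0}


@dataclass(frozen=True)
class GateRule:
    """One manual threshold gate: ``marker (>= | <) threshold -> label``."""

    marker: str
    threshold: float
    label: str
    polarity: str = ">="  # ">=" assigns label when intensity >= threshold

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold):
            raise ValueError("gate threshold must be finite")
        if self.polarity not in {">=", "<"}:
            raise ValueError("polarity must be '>=' or '<'")

    def matches(self, intensities: pd.Series) -> np.ndarray:
        v = intensities.to_numpy(dtype=float)
        return v >= self.threshold if self.polarity == ">=" else v < self.threshold


def _minmax(X: np.ndarray) -> np.ndarray:
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    return (X - lo) / span


def _knn_jaccard_graph(X: np.ndarray, k: int):
    """Jaccard-weighted kNN graph (igraph) over rows of X."""
    import igraph as ig
    from sklearn.neighbors import NearestNeighbors

    n = len(X)
    nn = NearestNeighbors(n_neighbors=k).fit(X)
    ind = nn.kneighbors(return_distance=False)  # (n, k), self excluded
    rows = np.repeat(np.arange(n), k)
    A = sp.csr_matrix((np.ones(n * k), (rows, ind.ravel())), shape=(n, n))
    ei, ej = A.nonzero()
    inter = np.empty(len(ei))
    block = 2000  # bounded memory: |N(i) ∩ N(j)| via blockwise A @ A.T
    for s in range(0, n, block):
        e = min(n, s + block)
        P = (A[s:e] @ A.T).tocsr()
        m = (ei >= s) & (ei < e)
        inter[m] = np.asarray(P[ei[m] - s, ej[m]]).ravel()
    jac = inter / (2 * k - inter)
    g = ig.Graph(n=n, edges=np.c_[ei, ej].tolist(), directed=False)
    g.es["weight"] = jac.tolist()
    g.simplify(combine_edges="max")
    return g


def cluster_cells(
    cells: pd.DataFrame,
    panel: MarkerPanel = DEFAULT_PANEL,
    k: int = 100,
    seed: int = 0,
    resolution: float = 1.0,
    flavor: str = "leiden",
) -> pd.Series:
    """Cluster cells in marker-intensity space; returns integer cluster ids.

    Intensities are min-max normalized per marker across the table, rows are
    canonicalized by ``cell_id`` order before graph construction (so the
    result is invariant to input row order), and communities are found on
    the Jaccard-weighted kNN graph.  ``resolution`` < 1 merges aggressively
    (useful when the true number of populations is small); the default 1.0
    behaves like standard PhenoGraph and may oversplit, which the
    cluster-to-type mapping absorbs.
    """
    import leidenalg as la

    if len(cells) <= k:
        raise ValueError(
            f"need more than k={k} cells (got {len(cells)}); reduce k"
        )
    order = np.argsort(cells["cell_id"].to_numpy())
    X = _minmax(cells.iloc[order][list(panel.markers)].to_numpy(dtype=float))
    if not np.isfinite(X).all():
        raise ValueError("marker intensities must be finite")
    if np.ptp(X, axis=0).max() == 0:  # all cells identical
        return pd.Series(np.zeros(len(cells), int), index=cells.index, name="cluster")
    g = _knn_jaccard_graph(X, k)
    if flavor == "leiden":
        part = la.find_partition(
            g,
            la.RBConfigurationVertexPartition,
            weights="weight",
            seed=seed,
            n_iterations=-1,
            resolution_parameter=resolution,
        )
        membership = np.asarray(part.membership)
    elif flavor == "louvain":
        comm = g.community_multilevel(weights="weight")
        membership = np.asarray(comm.membership)
    else:
        raise ValueError(f"unknown flavor {flavor!r}")
    out = np.empty(len(cells), int)
    out[order] = membership
    return pd.Series(out, index=cells.index, name="cluster")


def summarize_cluster_expression(
    cells: pd.DataFrame,
    clusters: pd.Series,
    panel: MarkerPanel = DEFAULT_PANEL,
) -> pd.DataFrame:
    """Mean intensity matrix, one row per (non-empty) cluster."""
    df = cells[list(panel.markers)].copy()
    df["cluster"] = np.asarray(clusters)
    out = df.groupby("cluster").mean()
    out.columns.name = "marker"
    return out


def suggest_phenotype_map(summary: pd.DataFrame) -> dict[int, str]:
    """Auto-map each cluster to a main cell type by signature agreement.

    Per lineage marker, log cluster means are min-max scaled across clusters
    and the cluster is called positive at >= 0.5 — on the log scale the
    positive/negative populations sit symmetrically, so the midpoint is a
    stable positivity call even when clusters subdivide a population by
    intensity magnitude.  Each cluster is assigned the main type whose
    signature agrees with its positivity pattern on the most lineage markers
    (checkpoint markers are ignored — they split phenotypes later, not
    lineages); ties break by main-type declaration order.  The map is a
    plain dict meant to be reviewed and edited by the user.
    """
    markers = [m for m in LINEAGE_MARKERS if m in summary.columns]
    logm = np.log(summary[markers].clip(lower=1e-12))
    lo, hi = logm.min(axis=0), logm.max(axis=0)
    span = (hi - lo).replace(0, 1.0)
    positive = (logm - lo) / span >= 0.5
    mapping: dict[int, str] = {}
    for cluster, row in positive.iterrows():
        best, best_score = None, -np.inf
        for main in MAIN_TYPES:
            sig = {m: (m in MAIN_SIGNATURE[main]) for m in markers}
            score = sum(row[m] == want for m, want in sig.items())
            if score > best_score:
                best, best_score = main, score
        mapping[cluster] = best
    return mapping


def apply_gates(
    cells: pd.DataFrame,
    main_types: pd.Series,
    mixed_clusters: Sequence[int],
    clusters: pd.Series,
    rules: Sequence[GateRule],
    fallback: str = "other immune",
) -> pd.Series:
    """Re-assign cells of mixed clusters by the first matching gate rule.

    Rules are evaluated in declared order; cells matching no rule fall back
    to ``fallback`` ("other immune" or "nonimmune" per configuration).
    With an empty rule list the assignment is returned unchanged.
    """
    for r in rules:
        if r.marker not in cells.columns:
            raise ValueError(f"gate rule references unknown marker {r.marker!r}")
    if fallback not in MAIN_TYPES:
        raise ValueError(f"fallback must be a main type, got {fallback!r}")
    out = main_types.copy()
    if not rules:
        return out
    in_mixed = np.isin(np.asarray(clusters), list(mixed_clusters))
    unassigned = in_mixed.copy()
    for r in rules:
        hit = unassigned & r.matches(cells[r.marker])
        out[hit] = r.label
        unassigned &= ~hit
    out[unassigned] = fallback
    return out


def call_checkpoints(
    cells: pd.DataFrame,
    main_types: pd.Series,
    thresholds: Mapping[str, float] | None = None,
    splits: Sequence[tuple[str, str]] = _CHECKPOINT_SPLITS,
) -> pd.Series:
    """Split main types by checkpoint positivity into the final phenotypes.

    A cell whose intensity is at or above the marker threshold (inclusive)
    for the first applicable checkpoint of its main type — in declared split
    order — gets the ``<marker>+ <main type>`` label; otherwise it keeps the
    main-type label.  Residual classes are never split.
    """
    thresholds = dict(DEFAULT_CHECKPOINT_THRESHOLDS if thresholds is None else thresholds)
    for marker in thresholds:
        if marker not in cells.columns:
            raise ValueError(f"checkpoint threshold for absent marker {marker!r}")
    out = main_types.astype(object).copy()
    assigned = np.zeros(len(cells), bool)
    mt = np.asarray(main_types)
    for main, marker in splits:
        if marker not in thresholds:
            continue
        pos = (
            (mt == main)
            & ~assigned
            & (cells[marker].to_numpy(dtype=float) >= thresholds[marker])
        )
        out[pos] = f"{marker}+ {main}"
        assigned |= pos
    return out.rename("phenotype")


def assign_phenotypes(
    cells: pd.DataFrame,
    panel: MarkerPanel = DEFAULT_PANEL,
    k: int = 100,
    seed: int = 0,
    resolution: float = 1.0,
    phenotype_map: Mapping[int, str] | None = None,
    gate_rules: Sequence[GateRule] = (),
    mixed_clusters: Sequence[int] = (),
    checkpoint_thresholds: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """End-to-end phenotyping: cluster, map, gate, call checkpoints.

    Returns a copy of ``cells`` with ``cluster``, ``main_type`` and
    ``phenotype`` columns.  ``phenotype_map`` overrides the auto-suggested
    cluster-to-type map where provided.
    """
    clusters = cluster_cells(cells, panel, k=k, seed=seed, resolution=resolution)
    summary = summarize_cluster_expression(cells, clusters, panel)
    mapping = suggest_phenotype_map(summary)
    if phenotype_map:
        mapping.update(phenotype_map)
    main = clusters.map(mapping).rename("main_type")
    if gate_rules:
        main = apply_gates(cells, main, mixed_clusters, clusters, gate_rules)
    phenotype = call_checkpoints(cells, main, checkpoint_thresholds)
    out = cells.copy()
    out["cluster"] = clusters
    out["main_type"] = main
    out["phenotype"] = phenotype
    return out


def phenotype_proportions(
    cells: pd.DataFrame, label_col: str = "phenotype"
) -> pd.DataFrame:
    """Per-sample phenotype fractions (rows sum to 1); empty samples dropped."""
    counts = (
        cells.groupby(["sample_id", label_col], observed=True).size().unstack(fill_value=0)
    )
    counts = counts.reindex(columns=sorted(set(counts.columns) | set(PHENOTYPES)),
                            fill_value=0)
    totals = counts.sum(axis=1)
    empty = totals == 0
    if empty.any():
        warnings.warn(f"dropping {int(empty.sum())} empty sample(s)")
        counts, totals = counts[~empty], totals[~empty]
    return counts.div(totals, axis=0)
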