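"""Spatial organization of RCNs: distances, proximity graph, stratification.

Within a sample, the directed distance D[x -> y] is the mean over cells in
RCN x of the Euclidean distance to the nearest cell in RCN y (pixels);
D is asymmetric in general and its diagonal is fixed at 0 by convention.
Symmetrized pair distances S = (D + D^T)/2 feed a "closest-RCN" proximity
graph at cohort level and per-patient pair distances (aggregated over the
patient's cores) for outcome stratification: patients split into *near*
(distance strictly below a pixel cutoff) versus *far-or-absent* (at/above
the cutoff, or the pair never co-occurring in any core).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .interactions import distance_matrix_by_label

__all__ = [
    "rcn_distance_matrix",
    "cohort_rcn_distances",
    "symmetrize",
    "build_proximity_graph",
    "patient_pair_distance",
    "dichotomize_proximity",
]


def rcn_distance_matrix(
    cells: pd.DataFrame, rcn_col: str = "rcn", labels: Sequence[str] | None = None
) -> pd.DataFrame:
    """Directed mean nearest-cell distance matrix for one sample.

    Entry [x, y] = mean over RCN-x cells of the distance to the nearest
    RCN-y cell; NaN where either RCN is absent from the sample; diagonal 0.
    """
    sub = cells.dropna(subset=[rcn_col])
    return distance_matrix_by_label(sub, label_col=rcn_col, labels=labels)


def cohort_rcn_distances(
    cells: pd.DataFrame, rcn_col: str = "rcn", labels: Sequence[str] | None = None
) -> dict[str, pd.DataFrame]:
    """Per-sample directed RCN distance matrices, keyed by sample id."""
    if labels is None:
        labels = sorted(cells[rcn_col].dropna().astype(str).unique())
    return {
        sid: rcn_distance_matrix(sub, rcn_col, labels)
        for sid, sub in cells.groupby("sample_id", sort=True)
    }


def symmetrize(d: pd.DataFrame) -> pd.DataFrame:
    """S = (D + D^T) / 2; NaN wherever either direction is undefined."""
    return (d + d.T) / 2.0


def build_proximity_graph(
    matrices: Mapping[str, pd.DataFrame] | Sequence[pd.DataFrame],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort-level closest-RCN graph.

    Symmetrized distances are averaged over the samples where each pair is
    defined; every RCN with at least one defined pair gets exactly one
    outgoing edge to its nearest RCN (ties break toward the lower canonical
    RCN index), weighted inversely to distance.  Returns ``(S, edges)``
    where edges has columns source/target/distance/weight.  An RCN that
    never co-occurs with any other is an isolated node.
    """
    mats = list(matrices.values()) if isinstance(matrices, Mapping) else list(matrices)
    if not mats:
        raise ValueError("no distance matrices given")
    sym = [symmetrize(m) for m in mats]
    S = pd.concat(sym).groupby(level=0).mean()  # available-case mean
    S = S.loc[sorted(S.index, key=_rcn_sort_key), sorted(S.columns, key=_rcn_sort_key)]
    if len(S) < 2:
        raise ValueError("need at least 2 RCNs")
    edges = []
    for x in S.index:
        row = S.loc[x].drop(labels=[x]).dropna()
        if row.empty:
            import warnings

            warnings.warn(f"RCN {x!r} never co-occurs with another RCN; isolated node")
            continue
        best = row.min()
        target = min(
            (y for y, v in row.items() if v == best), key=_rcn_sort_key
        )
        edges.append(
            {"source": x, "target": target, "distance": best,
             "weight": 1.0 / best if best > 0 else np.inf}
        )
    return S, pd.DataFrame(edges)


def _rcn_sort_key(name: str):
    # "RCN2" sorts before "RCN10"; non-canonical labels sort lexically.
    s = str(name)
    return (0, int(s[3:])) if s.startswith("RCN") and s[3:].isdigit() else (1, s)


def patient_pair_distance(
    matrices: Mapping[str, pd.DataFrame],
    sample_to_patient: Mapping[str, str],
    pair: tuple[str, str],
    aggregation: str = "mean",
) -> pd.DataFrame:
    """Per-patient symmetrized distance for one RCN pair.

    Aggregates over the patient's cores in which both RCNs are present
    (default mean; ``min``/``max`` available for sensitivity analysis).
    Patients with no qualifying core are returned with ``present=False``
    and a missing distance.
    """
    aggfun = {"mean": np.mean, "min": np.min, "max": np.max}.get(aggregation)
    if aggfun is None:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    x, y = pair
    per_patient: dict[str, list[float]] = {}
    for sid, d in matrices.items():
        pid = sample_to_patient[sid]
        per_patient.setdefault(pid, [])
        if x in d.index and y in d.columns:
            v = symmetrize(d).loc[x, y]
            if np.isfinite(v):
                per_patient[pid].append(float(v))
    rows = [
        {
            "patient_id": pid,
            "distance": aggfun(vals) if vals else np.nan,
            "present": bool(vals),
        }
        for pid, vals in sorted(per_patient.items())
    ]
    return pd.DataFrame(rows)


def dichotomize_proximity(
    distances: pd.DataFrame, cutoff: float
) -> pd.Series:
    """Classify patients as ``near`` (distance < cutoff, strict) or
    ``far_or_absent`` (distance >= cutoff, or RCN pair absent from every
    core — absence is grouped with far by design)."""
    if not cutoff > 0:
        raise ValueError("cutoff must be > 0")
    near = distances["present"] & (distances["distance"] < cutoff)
    out = pd.Series(
        np.where(near, "near", "far_or_absent"),
        index=distances["patient_id"].to_numpy(),
        name="proximity_group",
    )
    out.index.name = "patient_id"
    return out
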