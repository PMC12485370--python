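"""Recurrent cellular neighborhood (RCN) discovery.

Each cell's neighborhood is summarized as a *document*: the phenotype count
histogram of the cell itself plus its 19 nearest neighbors within the same
sample (counts sum to exactly 20).  A latent Dirichlet allocation model with
10 motifs is fit jointly across all samples, and the per-cell motif weights
are K-means clustered (default k = 10) into RCN labels shared across the
cohort.  RCN labels are canonicalized by descending cohort abundance
(RCN1 = most abundant) so reported names are stable across runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "build_neighborhood_matrix",
    "LdaModel",
    "fit_lda",
    "RcnModel",
    "cluster_topics",
    "scree_curve",
    "rcn_composition",
    "assign_rcns",
]

DEFAULT_N_NEIGHBORS = 19  # neighborhood = self + 19 nearest neighbors
DEFAULT_N_TOPICS = 10
DEFAULT_K = 10


def _knn_within_sample(
    xy: np.ndarray, cell_ids: np.ndarray, k: int
) -> np.ndarray:
    """Indices (n, k) of each cell's k nearest neighbors, self excluded.

    Distance ties at the k-th neighbor are broken by lowest cell_id for
    determinism.
    """
    from scipy.spatial import cKDTree

    n = len(xy)
    tree = cKDTree(xy)
    m = min(n, k + 2)  # probe a little deeper to expose boundary ties
    d, idx = tree.query(xy, k=m)
    out = np.empty((n, k), dtype=int)
    for i in range(n):
        cand_d, cand_i = d[i, 1:], idx[i, 1:]  # drop self
        cutoff = cand_d[k - 1]
        if cand_d[-1] <= cutoff + 0.0:  # possible hidden ties beyond probe
            ball = tree.query_ball_point(xy[i], r=cutoff)
            ball = [j for j in ball if j != i]
            dd = np.hypot(*(xy[ball] - xy[i]).T)
            order = np.lexsort((cell_ids[ball], dd))
            cand_i = np.asarray(ball)[order]
        else:
            tie = np.isclose(cand_d, cutoff)
            if tie.sum() > 1:
                order = np.lexsort((cell_ids[cand_i], cand_d))
                cand_i = cand_i[order]
        out[i] = cand_i[:k]
    return out


def build_neighborhood_matrix(
    cells: pd.DataFrame,
    n_neighbors: int = DEFAULT_N_NEIGHBORS,
    label_col: str = "phenotype",
    phenotype_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Neighborhood documents: phenotype counts over self + k nearest.

    Neighbor search is Euclidean in pixels and never crosses sample
    boundaries.  Samples with fewer than ``n_neighbors + 1`` cells are
    excluded with a warning.  Returns a DataFrame indexed by ``cell_id``
    with one integer column per phenotype; every row sums to
    ``n_neighbors + 1``.
    """
    types = (
        list(phenotype_order)
        if phenotype_order is not None
        else sorted(cells[label_col].astype(str).unique())
    )
    tindex = {t: c for c, t in enumerate(types)}
    docs = []
    ids = []
    for sid, sub in cells.groupby("sample_id", sort=True):
        if len(sub) < n_neighbors + 1:
            warnings.warn(
                f"sample {sid!r} has {len(sub)} < {n_neighbors + 1} cells; excluded"
            )
            continue
        xy = sub[["x", "y"]].to_numpy(dtype=float)
        cid = sub["cell_id"].to_numpy()
        codes = np.array([tindex[t] for t in sub[label_col].astype(str)])
        nn = _knn_within_sample(xy, cid, n_neighbors)
        counts = np.zeros((len(sub), len(types)), dtype=int)
        counts[np.arange(len(sub)), codes] += 1  # self
        np.add.at(counts, (np.repeat(np.arange(len(sub)), n_neighbors),
                           codes[nn.ravel()]), 1)
        docs.append(counts)
        ids.append(cid)
    if not docs:
        return pd.DataFrame(columns=types)
    out = pd.DataFrame(np.concatenate(docs), columns=types,
                       index=pd.Index(np.concatenate(ids), name="cell_id"))
    return out


@dataclass
class LdaModel:
    """Fitted LDA: motif-phenotype matrix and per-cell motif weights."""

    topic_phenotype: pd.DataFrame  # (n_topics, n_phenotypes), rows sum to 1
    cell_weights: pd.DataFrame  # (n_cells, n_topics), rows sum to 1
    n_topics: int
    seed: int


def fit_lda(
    documents: pd.DataFrame,
    n_topics: int = DEFAULT_N_TOPICS,
    seed: int = 0,
    doc_topic_prior: float | None = None,
    topic_word_prior: float = 0.01,
    n_init: int = 4,
    max_iter: int = 30,
) -> LdaModel:
    """Fit latent Dirichlet allocation to neighborhood documents.

    Variational Bayes (scikit-learn), deterministic given ``seed``.
    Symmetric priors default to alpha = 1/n_topics on document-topic and
    beta = 0.01 on topic-phenotype.  The variational objective has local
    optima in which two motifs merge, so the fit is restarted ``n_init``
    times (sub-seeds derived from ``seed``) and the restart with the best
    evidence bound is kept — the same restart policy K-means uses, decided
    on the model's own objective.  Rows of both returned matrices are
    normalized to the simplex.
    """
    from sklearn.decomposition import LatentDirichletAllocation

    if len(documents) < n_topics:
        raise ValueError("need at least n_topics documents")
    if documents.drop_duplicates().shape[0] == 1:
        warnings.warn("all neighborhood documents are identical; LDA is degenerate")
    X = documents.to_numpy()
    lda, best_score = None, -np.inf
    for sub_seed in np.random.SeedSequence(seed).generate_state(max(n_init, 1)):
        cand = LatentDirichletAllocation(
            n_components=n_topics,
            doc_topic_prior=(
                doc_topic_prior if doc_topic_prior is not None else 1.0 / n_topics
            ),
            topic_word_prior=topic_word_prior,
            random_state=int(sub_seed % (2**31)),
            learning_method="batch",
            max_iter=max_iter,
        )
        cand.fit(X)
        score = cand.score(X)
        if score > best_score:
            lda, best_score = cand, score
    weights = lda.transform(X)
    weights = weights / weights.sum(axis=1, keepdims=True)
    topics = lda.components_ / lda.components_.sum(axis=1, keepdims=True)
    return LdaModel(
        topic_phenotype=pd.DataFrame(
            topics, columns=documents.columns,
            index=pd.RangeIndex(n_topics, name="motif"),
        ),
        cell_weights=pd.DataFrame(
            weights, index=documents.index,
            columns=pd.RangeIndex(n_topics, name="motif"),
        ),
        n_topics=n_topics,
        seed=seed,
    )


@dataclass
class RcnModel:
    """K-means clustering of LDA motif weights into RCN labels.

    ``labels`` maps cell_id -> "RCN1".."RCNk", canonically ordered by
    descending cohort abundance; ``centroids`` rows follow the same order.
    """

    centroids: pd.DataFrame  # (k, n_topics)
    labels: pd.Series  # cell_id -> RCN name
    inertia: float
    k: int


def cluster_topics(
    weights: pd.DataFrame, k: int = DEFAULT_K, seed: int = 0, n_init: int = 10
) -> RcnModel:
    """K-means on motif-weight vectors; labels stable under row order.

    Rows are canonicalized by cell_id before fitting so the result does not
    depend on input ordering.
    """
    from sklearn.cluster import KMeans

    distinct = weights.drop_duplicates().shape[0]
    if k > distinct:
        raise ValueError(f"k={k} exceeds {distinct} distinct weight vectors")
    w = weights.sort_index(kind="stable")
    km = KMeans(n_clusters=k, random_state=seed, n_init=n_init)
    raw = km.fit_predict(w.to_numpy())
    # canonical order: RCN1 = most abundant
    order = np.argsort(-np.bincount(raw, minlength=k), kind="stable")
    rank = np.empty(k, int)
    rank[order] = np.arange(k)
    names = np.array([f"RCN{r + 1}" for r in rank])
    labels = pd.Series(names[raw], index=w.index, name="rcn").reindex(weights.index)
    centroids = pd.DataFrame(
        km.cluster_centers_[order],
        index=pd.Index([f"RCN{i + 1}" for i in range(k)], name="rcn"),
        columns=weights.columns,
    )
    return RcnModel(
        centroids=centroids, labels=labels, inertia=float(km.inertia_), k=k
    )


def scree_curve(
    weights: pd.DataFrame, k_range: Sequence[int] = range(2, 16), seed: int = 0
) -> tuple[pd.Series, int]:
    """Inertia per candidate k plus a suggested elbow.

    The elbow suggestion is the k maximizing the discrete second difference
    of the inertia curve (a suggestion only — inspect the curve).  On a flat
    curve the lowest candidate k is returned with a warning.
    """
    from sklearn.cluster import KMeans

    ks = list(k_range)
    if any(b <= a for a, b in zip(ks, ks[1:])):
        raise ValueError("k_range must be ascending")
    w = weights.sort_index(kind="stable").to_numpy()
    inertia = pd.Series(
        [KMeans(n_clusters=kk, random_state=seed, n_init=5).fit(w).inertia_
         for kk in ks],
        index=pd.Index(ks, name="k"),
        name="inertia",
    )
    if np.ptp(inertia.to_numpy()) == 0:
        warnings.warn("flat scree curve; no elbow")
        return inertia, ks[0]
    if len(ks) < 3:
        return inertia, ks[0]
    second = inertia.to_numpy()[:-2] - 2 * inertia.to_numpy()[1:-1] + inertia.to_numpy()[2:]
    return inertia, ks[1 + int(np.argmax(second))]


def assign_rcns(
    cells: pd.DataFrame,
    n_neighbors: int = DEFAULT_N_NEIGHBORS,
    n_topics: int = DEFAULT_N_TOPICS,
    k: int = DEFAULT_K,
    seed: int = 0,
    label_col: str = "phenotype",
) -> tuple[pd.DataFrame, LdaModel, RcnModel]:
    """Documents -> LDA -> K-means; returns cells with an ``rcn`` column.

    Cells from samples too small to form neighborhoods get no label (NaN).
    """
    docs = build_neighborhood_matrix(cells, n_neighbors, label_col)
    lda = fit_lda(docs, n_topics=n_topics, seed=seed)
    rcn = cluster_topics(lda.cell_weights, k=k, seed=seed)
    out = cells.copy()
    out["rcn"] = out["cell_id"].map(rcn.labels)
    return out, lda, rcn


def rcn_composition(
    cells: pd.DataFrame,
    rcn_col: str = "rcn",
    label_col: str = "phenotype",
    presence_threshold: float = 0.01,
) -> dict[str, pd.DataFrame | pd.Series]:
    """Cohort RCN summaries.

    Returns ``composition`` (RCN × phenotype mean fractions, rows sum to 1),
    ``sample_proportions`` (sample × RCN fractions, rows sum to 1), and
    ``prevalence`` (fraction of samples where the RCN holds at least
    ``presence_threshold`` of the sample's labeled cells).
    """
    lab = cells.dropna(subset=[rcn_col])
    comp = (
        lab.groupby([rcn_col, label_col], observed=True).size().unstack(fill_value=0)
    )
    composition = comp.div(comp.sum(axis=1), axis=0)
    sp = (
        lab.groupby(["sample_id", rcn_col], observed=True).size().unstack(fill_value=0)
    )
    sample_proportions = sp.div(sp.sum(axis=1), axis=0)
    prevalence = (sample_proportions >= presence_threshold).mean(axis=0)
    return {
        "composition": composition,
        "sample_proportions": sample_proportions,
        "prevalence": prevalence.rename("prevalence"),
    }
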