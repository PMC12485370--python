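"""Survival and group-comparison statistics for spatial features.

Standard machinery — Kaplan–Meier curves, log-rank tests, Cox proportional
hazards (Efron ties) — is delegated to lifelines; rank tests to scipy and
Benjamini–Hochberg to statsmodels.  The maximally-selected-rank-statistic
cutoff search is implemented here: the standardized two-group log-rank
statistic is evaluated at every candidate cutoff of a continuous feature
(restricted to an inner quantile band with a minimum group size), the
cutoff maximizing |z| is selected, and the selection-adjusted p-value comes
from a permutation null of the maximum statistic (the naive minimum p over
cutoffs is anti-conservative; the permutation of max|z| accounts for the
selection).  The multi-cutoff log-rank evaluation is vectorized over
cutoffs so a 1,000-permutation adjustment runs in well under a second at
cohort scale; it is validated against the ordinary log-rank test at any
single split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "MaxstatResult",
    "maxstat_cutoff",
    "mann_whitney",
    "kruskal_wallis",
    "bh_adjust",
    "association_scan",
    "GroupTestResult",
]


# ---------------------------------------------------------------------------
# Kaplan–Meier / log-rank / Cox (lifelines-backed)
# ---------------------------------------------------------------------------


def km_estimate(
    time: Sequence[float], event: Sequence[int], horizon: float | None = 60.0
):
    """Product-limit survival estimate.

    Returns ``(table, s_horizon)``: a step-function table with columns
    ``time``/``survival`` (S(0) = 1) and the survival probability at the
    reporting horizon (default 60 months, i.e. 5 years), or None if no
    horizon is requested.
    """
    from lifelines import KaplanMeierFitter

    t = np.asarray(time, float)
    e = np.asarray(event, int)
    if len(t) == 0:
        raise ValueError("need at least one subject")
    if (t < 0).any():
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    table = kmf.survival_function_.reset_index()
    table.columns = ["time", "survival"]
    s_h = float(kmf.predict(horizon)) if horizon is not None else None
    return table, s_h


def logrank_test(
    time: Sequence[float], event: Sequence[int], group: Sequence
) -> tuple[float, float]:
    """Log-rank chi-square test across 2+ groups; returns (statistic, p)."""
    from lifelines.statistics import multivariate_logrank_test

    g = pd.Series(group)
    if g.nunique() < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    res = multivariate_logrank_test(np.asarray(time, float), g,
                                    np.asarray(event, int))
    return float(res.test_statistic), float(res.p_value)


def cox_fit(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: Sequence[str],
    formula: str | None = None,
) -> pd.DataFrame:
    """Cox proportional-hazards fit (Efron tie handling, lifelines).

    Returns the coefficient table (log-HR ``coef``, ``exp(coef)``,
    confidence bounds, Wald ``p``).  Constant covariates and convergence
    failures raise with a diagnostic.  Pass more covariates for a
    multivariable model; categorical covariates can be handled through
    ``formula``.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    for c in covariates:
        if formula is None and df[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant")
    n_events = int(df[event_col].sum())
    if n_events < len(covariates):
        warnings.warn(
            f"only {n_events} events for {len(covariates)} covariates; "
            "estimates will be unstable"
        )
    cph = CoxPHFitter()
    cols = [duration_col, event_col] + list(covariates)
    try:
        cph.fit(df[cols], duration_col=duration_col, event_col=event_col,
                formula=formula)
    except ConvergenceError as err:  # separation / flat likelihood
        raise RuntimeError(f"Cox model failed to converge: {err}") from err
    return cph.summary


# ---------------------------------------------------------------------------
# Maximally selected rank statistics
# ---------------------------------------------------------------------------


def _logrank_z_multi(
    time: np.ndarray, event: np.ndarray, groups: np.ndarray
) -> np.ndarray:
    """Standardized log-rank z for each column of a boolean group matrix.

    ``groups`` is (n, C): column c indicates membership of "group 1" under
    split c.  Returns z_c = (O - E)/sqrt(V) for group 1; 0 where V = 0
    (degenerate split).  Vectorized over all C splits in one pass.
    """
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    G = groups[order].astype(float)
    n = len(t)
    starts = np.r_[0, 1 + np.flatnonzero(np.diff(t))]
    d = np.add.reduceat(e.astype(float), starts)  # events per distinct time
    d1 = np.add.reduceat(e[:, None] * G, starts, axis=0)
    csum = np.vstack([np.zeros(G.shape[1]), np.cumsum(G, axis=0)])
    n1 = G.sum(axis=0)[None, :] - csum[starts]  # group-1 at risk per time
    n_risk = (n - starts).astype(float)
    has_events = d > 0
    d, d1 = d[has_events], d1[has_events]
    n1, n_risk = n1[has_events], n_risk[has_events]
    frac = n1 / n_risk[:, None]
    O = d1.sum(axis=0)
    E = (d[:, None] * frac).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        vterm = (
            d[:, None]
            * frac
            * (1 - frac)
            * ((n_risk - d) / np.maximum(n_risk - 1, 1))[:, None]
        )
    V = vterm.sum(axis=0)
    z = np.zeros(groups.shape[1])
    ok = V > 0
    z[ok] = (O[ok] - E[ok]) / np.sqrt(V[ok])
    return z


@dataclass
class MaxstatResult:
    """Outcome of a maximally-selected log-rank cutoff search."""

    feature: str
    cutoffs: np.ndarray
    statistics: np.ndarray  # |z| per cutoff
    selected_cutoff: float
    max_statistic: float
    p_value: float
    method: str = "permutation"
    n_perm: int = 0
    naive_min_p: float = field(default=np.nan)


def maxstat_cutoff(
    feature: Sequence[float],
    time: Sequence[float],
    event: Sequence[int],
    n_perm: int = 1000,
    seed: int = 0,
    quantile_band: tuple[float, float] = (0.10, 0.90),
    min_group: int = 10,
    feature_name: str = "feature",
    candidates: Sequence[float] | None = None,
) -> MaxstatResult:
    """Optimal survival cutoff on a continuous feature, selection-adjusted.

    Candidates are the observed feature values inside the inner quantile
    band (default 10th–90th percentile) leaving at least ``min_group``
    subjects on each side of the split ``feature <= cutoff`` versus
    ``feature > cutoff``.  The selected cutoff maximizes the absolute
    standardized log-rank statistic; its p-value is the permutation tail
    probability of that maximum under random reassignment of the feature
    (``n_perm`` label permutations), which corrects for having searched.
    """
    x = np.asarray(feature, float)
    t = np.asarray(time, float)
    e = np.asarray(event, int)
    if candidates is not None:
        cand = np.unique(np.asarray(candidates, float))
    else:
        lo, hi = np.quantile(x, quantile_band)
        cand = np.unique(x[(x >= lo) & (x <= hi)])
    splits = x[:, None] <= cand[None, :]
    sizes = splits.sum(axis=0)
    ok = (sizes >= min_group) & (len(x) - sizes >= min_group)
    cand, splits = cand[ok], splits[:, ok]
    if len(cand) == 0:
        raise ValueError(
            f"no candidate cutoff leaves {min_group} subjects on both sides"
        )
    absz = np.abs(_logrank_z_multi(t, e, splits))
    best = int(np.argmax(absz))
    max_obs = float(absz[best])

    from scipy.stats import chi2

    naive_min_p = float(chi2.sf(max_obs**2, df=1))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(x))
        if np.abs(_logrank_z_multi(t, e, splits[perm])).max() >= max_obs:
            exceed += 1
    p = (1.0 + exceed) / (n_perm + 1.0)
    return MaxstatResult(
        feature=feature_name,
        cutoffs=cand,
        statistics=absz,
        selected_cutoff=float(cand[best]),
        max_statistic=max_obs,
        p_value=p,
        n_perm=n_perm,
        naive_min_p=naive_min_p,
    )


# ---------------------------------------------------------------------------
# Rank tests and multiple-testing correction
# ---------------------------------------------------------------------------


@dataclass
class GroupTestResult:
    test: str
    statistic: float
    p: float
    family: str = ""
    p_adjusted: float = np.nan


def mann_whitney(
    a: Sequence[float], b: Sequence[float], alternative: str = "two-sided"
) -> GroupTestResult:
    """Mann–Whitney U test (exact where scipy can, tie-corrected otherwise)."""
    from scipy.stats import mannwhitneyu

    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty group")
    if np.ptp(np.r_[a, b]) == 0:  # all values identical: no evidence
        return GroupTestResult("mann-whitney", len(a) * len(b) / 2.0, 1.0)
    res = mannwhitneyu(a, b, alternative=alternative)
    return GroupTestResult("mann-whitney", float(res.statistic), float(res.pvalue))


def kruskal_wallis(*groups: Sequence[float]) -> GroupTestResult:
    """Kruskal–Wallis H test across 3+ groups (2 allowed, equals U-test)."""
    from scipy.stats import kruskal

    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    flat = np.concatenate([np.asarray(g, float) for g in groups])
    if np.ptp(flat) == 0:
        return GroupTestResult("kruskal-wallis", 0.0, 1.0)
    res = kruskal(*groups)
    return GroupTestResult("kruskal-wallis", float(res.statistic), float(res.pvalue))


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1).

    NaN entries propagate (they are excluded from the family size).
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, float)
    valid = ~np.isnan(p)
    if ((p[valid] < 0) | (p[valid] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    if valid.sum():
        out[valid] = multipletests(p[valid], method="fdr_bh")[1]
    return out


def association_scan(
    features: pd.DataFrame,
    labels: pd.Series,
    family: str = "scan",
) -> pd.DataFrame:
    """Rank-test every feature column against a categorical label.

    Two label levels use Mann–Whitney U, three or more Kruskal–Wallis; the
    scan is one BH family.  Rows with missing labels are dropped; an
    all-missing label raises.  Returns a tidy table with raw and adjusted p.
    """
    lab = labels.reindex(features.index)
    keep = lab.notna()
    if not keep.any():
        raise ValueError("label is entirely missing")
    lab = lab[keep]
    levels = sorted(lab.unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 label levels")
    rows = []
    for col in features.columns:
        vals = features.loc[keep, col]
        grouped = [vals[lab == lv].to_numpy(dtype=float) for lv in levels]
        if any(len(g) == 0 for g in grouped):
            warnings.warn(f"feature {col!r}: a label level has no observations; skipped")
            continue
        res = (
            mann_whitney(grouped[0], grouped[1])
            if len(levels) == 2
            else kruskal_wallis(*grouped)
        )
        rows.append(
            {"feature": col, "test": res.test, "statistic": res.statistic,
             "p": res.p, "family": family}
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjusted"] = bh_adjust(out["p"].to_numpy())
    return out
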