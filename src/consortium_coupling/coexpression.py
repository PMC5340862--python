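"""Responsive-gene calling, differential tests, and correlation K-means.

A gene is *responsive* on a treatment axis when its replicate-mean
expression changes at least two-fold between the lowest and highest
treatment levels (interior conditions are ignored).  Co-expression
structure across the two species is summarized by K-means in
correlation distance (1 - Pearson r) with "eigen-gene" centroids: each
profile is standardized, centroids are member means re-standardized,
and the four recovered centroids are labeled against the archetypal
shapes seen along ordered treatments -- tent (peak at the midpoint),
inverse tent, monotone decreasing, monotone increasing.

The differential-expression contract (>2-fold change with
Benjamini-Hochberg adjusted p < 0.05) is implemented with a Welch test
on log2 replicate values; see the methods note for why this stand-in
preserves the decision rule without a full count model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .core_model import Axis, Design, ExpressionMatrix, GeneTable, ProfileMatrix

logger = logging.getLogger(__name__)

PATTERNS = ("tent", "inverse-tent", "decreasing", "increasing")

DEFAULT_PSEUDOCOUNT = 0.5


class CoexpressionError(ValueError):
    pass


def call_responsive(
    cond_means: pd.DataFrame | ProfileMatrix,
    axis: Axis,
    threshold: float = 2.0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Call treatment-responsive genes on one axis.

    Compares the lowest- and highest-treatment condition means only.  A
    pseudocount (expression units, default 0.5) is added to both terms
    before forming the ratio so that marginally expressed genes cannot
    divide by zero.  The threshold is inclusive and symmetric: a gene
    is responsive when max(fold, 1/fold) >= threshold, with direction
    ``up`` when the high extreme is larger and ``down`` otherwise.

    Returns a DataFrame indexed by gene id with columns ``axis``,
    ``fold_change`` (high/low ratio), ``direction`` and ``responsive``.
    """
    if isinstance(cond_means, ProfileMatrix):
        values, axis = cond_means.values, cond_means.axis
    else:
        values = cond_means[list(axis.labels)]
    if values.shape[1] < 2:
        raise CoexpressionError("responsive calling needs >= 2 axis conditions")
    if (values.to_numpy() < 0).any():
        raise CoexpressionError("condition means must be >= 0")
    low = values.iloc[:, 0].to_numpy(dtype=float)
    high = values.iloc[:, -1].to_numpy(dtype=float)
    fold = (high + pseudocount) / (low + pseudocount)
    responsive = np.maximum(fold, 1.0 / fold) >= threshold
    direction = np.where(
        ~responsive, "none", np.where(fold >= 1.0, "up", "down")
    )
    return pd.DataFrame(
        {
            "axis": axis.name,
            "fold_change": fold,
            "direction": direction,
            "responsive": responsive,
        },
        index=values.index,
    )


def count_responsive(
    calls: pd.DataFrame,
    gene_table: GeneTable | None = None,
    species=None,
    direction: str | None = None,
) -> int:
    """Count responsive genes, optionally restricted by species/direction."""
    mask = calls["responsive"].copy()
    if species is not None:
        if gene_table is None:
            raise CoexpressionError("species restriction requires a gene table")
        sp = gene_table.species_series().reindex(calls.index)
        mask &= sp == getattr(species, "value", str(species))
    if direction is not None:
        mask &= calls["direction"] == direction
    return int(mask.sum())


def responsive_summary(calls: pd.DataFrame, gene_table: GeneTable) -> pd.DataFrame:
    """Responsive counts per (species, direction) for one axis."""
    sp = gene_table.species_series().reindex(calls.index)
    sub = calls[calls["responsive"]]
    table = (
        pd.crosstab(sp[sub.index], sub["direction"])
        .rename_axis(index="species", columns="direction")
    )
    return table


def test_differential(
    expr: ExpressionMatrix,
    design: Design,
    condition_a: str,
    condition_b: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
    prior_df: float = 10.0,
) -> pd.DataFrame:
    """Per-gene differential expression between two conditions.

    A moderated two-sample t-test on log2(value + pseudocount)
    replicate values: each group's genewise variance is shrunk toward
    the median genewise variance with ``prior_df`` prior degrees of
    freedom (the empirical-Bayes device standard for duplicate-level
    RNA-seq designs, where raw genewise variance estimates are too
    unstable to power a Welch test), followed by Benjamini-Hochberg
    adjustment across all tested genes.  Decision rule: significant
    iff \\|log2 fold change\\| > ``lfc_threshold`` (i.e. >2-fold) and
    adjusted p < ``alpha``.  Identical replicate sets in both
    conditions give log2FC = 0 and p = 1.
    """
    a = list(design.samples_for(condition_a))
    b = list(design.samples_for(condition_b))
    if len(a) < 2 or len(b) < 2:
        raise CoexpressionError(
            f"both conditions need >= 2 replicates "
            f"({condition_a}: {len(a)}, {condition_b}: {len(b)})"
        )
    log_a = np.log2(expr.df[a].to_numpy(dtype=float) + pseudocount)
    log_b = np.log2(expr.df[b].to_numpy(dtype=float) + pseudocount)
    na, nb = len(a), len(b)
    lfc = log_b.mean(axis=1) - log_a.mean(axis=1)
    var_a = log_a.var(axis=1, ddof=1)
    var_b = log_b.var(axis=1, ddof=1)
    # pooled genewise residual variance, then shrink toward the median
    df_resid = na + nb - 2
    s2 = ((na - 1) * var_a + (nb - 1) * var_b) / df_resid
    s2_prior = float(np.median(s2))
    s2_tilde = (prior_df * s2_prior + df_resid * s2) / (prior_df + df_resid)
    se = np.sqrt(s2_tilde * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df=prior_df + df_resid)
    p = np.where(np.isnan(p), 1.0, np.minimum(p, 1.0))
    _, padj, _, _ = multipletests(p, method="fdr_bh")
    significant = (np.abs(lfc) > lfc_threshold) & (padj < alpha)
    return pd.DataFrame(
        {
            "log2_fold_change": lfc,
            "p_value": p,
            "adjusted_p": padj,
            "significant": significant,
        },
        index=expr.df.index,
    )


@dataclass
class ClusterResult:
    """Correlation K-means output for one treatment axis."""

    k: int
    axis: str
    assignments: pd.Series  # gene_id -> cluster index (0..k-1)
    centroids: np.ndarray  # k x axis-length, standardized eigen-genes
    pattern_labels: dict[int, str]
    objective: float  # total within-cluster (1 - r)
    within_cluster_mean_correlation: float
    seed: int
    n_init: int


def _standardize_rows(X: np.ndarray, index) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        bad = list(np.asarray(index)[flat])[:3]
        raise CoexpressionError(
            f"cannot standardize constant profiles (apply variance_mask first): {bad}"
        )
    return (X - mu) / sd


def _standardize_centroids(C: np.ndarray) -> np.ndarray:
    mu = C.mean(axis=1, keepdims=True)
    sd = C.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0  # degenerate centroid: leave centered
    return (C - mu) / sd


def _lloyd(X: np.ndarray, centroids: np.ndarray, max_iter: int = 300):
    """Lloyd iterations in correlation distance.

    Returns (assignments, centroids, objective history).  X rows and
    centroids are standardized, so 1 - r = 1 - (x . c) / L.
    """
    n, L = X.shape
    k = centroids.shape[0]
    history: list[float] = []
    assign = np.full(n, -1)
    for _ in range(max_iter):
        dist = 1.0 - (X @ centroids.T) / L
        new_assign = np.argmin(dist, axis=1)
        row_dist = dist[np.arange(n), new_assign]
        # re-seed any empty cluster with the farthest profile
        for c in range(k):
            if not (new_assign == c).any():
                far = int(np.argmax(row_dist))
                new_assign[far] = c
                row_dist[far] = 0.0
        history.append(float(row_dist.sum()))
        if (new_assign == assign).all():
            break
        assign = new_assign
        centroids = np.vstack(
            [X[assign == c].mean(axis=0) for c in range(k)]
        )
        centroids = _standardize_centroids(centroids)
    return assign, centroids, history


def kmeans_correlation(
    profiles: ProfileMatrix | pd.DataFrame,
    k: int = 4,
    seed: int = 0,
    n_init: int = 50,
    max_iter: int = 300,
) -> ClusterResult:
    """Correlation-distance K-means with eigen-gene centroids.

    Profiles are standardized (mean 0, SD 1) so that Euclidean-style
    centroid means remain meaningful under the correlation metric;
    distance to a centroid is 1 - Pearson r.  The best of ``n_init``
    random initializations (k distinct profiles each) by total
    within-cluster distance is kept; the Lloyd loop runs to an
    assignment fixpoint or ``max_iter`` iterations and re-seeds empty
    clusters with the farthest profile.  Output is deterministic for
    fixed (profiles, k, seed, n_init).
    """
    if isinstance(profiles, ProfileMatrix):
        df, axis_name = profiles.values, profiles.axis.name
    else:
        df, axis_name = profiles, "unknown"
    if df.shape[1] < 3:
        raise CoexpressionError("clustering needs an axis of length >= 3")
    X = _standardize_rows(df.to_numpy(dtype=float), df.index)
    n, L = X.shape
    distinct = np.unique(np.round(X, 12), axis=0)
    if len(distinct) < k:
        raise CoexpressionError(
            f"only {len(distinct)} distinct profiles for k={k} clusters"
        )
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        # draw until the k seed profiles are pairwise distinct
        while True:
            idx = rng.choice(n, size=k, replace=False)
            if len(np.unique(np.round(X[idx], 12), axis=0)) == k:
                break
        assign, centroids, history = _lloyd(X, X[idx].copy(), max_iter=max_iter)
        if best is None or history[-1] < best[2][-1]:
            best = (assign, centroids, history)
    assign, centroids, history = best
    corr = (X @ centroids.T) / L
    within_r = float(corr[np.arange(n), assign].mean())
    labels = label_patterns(centroids)
    result = ClusterResult(
        k=k,
        axis=axis_name,
        assignments=pd.Series(assign, index=df.index, name="cluster"),
        centroids=centroids,
        pattern_labels=labels,
        objective=history[-1],
        within_cluster_mean_correlation=within_r,
        seed=seed,
        n_init=n_init,
    )
    logger.info(
        "k-means (%s axis): k=%d, n=%d, objective=%.4f, mean within-cluster r=%.3f",
        axis_name, k, n, result.objective, within_r,
    )
    return result


def pattern_templates(length: int) -> dict[str, np.ndarray]:
    """Standardized archetype shapes over an ordered treatment axis."""
    i = np.arange(length, dtype=float)
    mid = (length - 1) / 2.0
    raw = {
        "tent": -np.abs(i - mid),
        "inverse-tent": np.abs(i - mid),
        "decreasing": -i,
        "increasing": i,
    }
    return {
        name: (v - v.mean()) / v.std() for name, v in raw.items()
    }


def label_patterns(centroids: np.ndarray) -> dict[int, str]:
    """Assign a unique archetype label to each centroid.

    Labels are chosen by maximum-weight matching on the centroid vs
    template correlation matrix, so each of tent / inverse-tent /
    decreasing / increasing is used exactly once when k equals the
    number of templates.  Ties resolve by the template order above.
    """
    k, L = centroids.shape
    templates = pattern_templates(L)
    names = list(templates)
    if k > len(names):
        raise CoexpressionError(f"cannot label {k} centroids with {len(names)} patterns")
    C = _standardize_centroids(np.asarray(centroids, dtype=float))
    T = np.vstack([templates[n] for n in names])
    corr = (C @ T.T) / L
    rows, cols = optimize.linear_sum_assignment(-corr)
    return {int(r): names[c] for r, c in zip(rows, cols)}


def cross_species_summary(
    result: ClusterResult, gene_table: GeneTable
) -> pd.DataFrame:
    """Per-cluster species counts, with the cluster's pattern label."""
    sp = gene_table.species_series().reindex(result.assignments.index)
    table = pd.crosstab(result.assignments, sp)
    table = table.rename_axis(index="cluster", columns="species")
    for value in ("cyanobacterium", "heterotroph"):
        if value not in table.columns:
            table[value] = 0
    table = table[sorted(table.columns)]
    table["pattern"] = [result.pattern_labels[c] for c in table.index]
    return table
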