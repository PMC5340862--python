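"""Functional-category enrichment for gene sets.

The enrichment ratio of a category in a gene set is the percentage of
set genes carrying the category divided by the percentage in the
reference universe (by default, all genes of the set's species):

    ratio = (k / n) / (K / N)

with N universe genes, K of them in the category, a set of n genes and
k category hits.  Significance is the one-sided exact hypergeometric
tail (Fisher's exact test for over- or under-representation), computed
by direct log-space summation.  The raw p < alpha rule drives the
significance flag; Benjamini-Hochberg adjusted values are reported
alongside for users who prefer category-wise FDR control.
"""

from __future__ import annotations

import logging
from math import lgamma

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .core_model import GeneTable

logger = logging.getLogger(__name__)


class EnrichmentError(ValueError):
    pass


def _check_table(k: int, n: int, K: int, N: int) -> None:
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise EnrichmentError(f"invalid table k={k}, n={n}, K={K}, N={N}")
    if k > K:
        raise EnrichmentError(f"k={k} exceeds category size K={K}")
    if k < max(0, n - (N - K)):
        raise EnrichmentError(
            f"k={k} below the minimum feasible overlap for n={n}, K={K}, N={N}"
        )


def enrichment_ratio(k: int, n: int, K: int, N: int) -> float:
    """(k/n) / (K/N); requires n > 0 and K > 0."""
    _check_table(k, n, K, N)
    if n == 0 or K == 0:
        raise EnrichmentError("enrichment ratio undefined for n=0 or K=0")
    return (k / n) / (K / N)


def _log_binom(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def _log_pmf(x: int, n: int, K: int, N: int) -> float:
    return (
        _log_binom(K, x) + _log_binom(N - K, n - x) - _log_binom(N, n)
    )


def fisher_p(k: int, n: int, K: int, N: int, tail: str = "over") -> float:
    """One-sided exact hypergeometric tail probability.

    ``over``: P(X >= k) for over-representation; ``under``: P(X <= k).
    Summed in log space for numerical stability; exact to double
    precision for all practically sized tables.
    """
    _check_table(k, n, K, N)
    lo = max(0, n - (N - K))
    hi = min(n, K)
    if tail == "over":
        xs = range(k, hi + 1)
    elif tail == "under":
        xs = range(lo, k + 1)
    else:
        raise EnrichmentError(f"tail must be 'over' or 'under', got {tail!r}")
    log_terms = [_log_pmf(x, n, K, N) for x in xs]
    if not log_terms:
        return 0.0
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def enrich_all(
    set_ids,
    gene_table: GeneTable,
    universe_ids=None,
    tail: str = "over",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Enrichment of every category of the universe in a gene set.

    The universe defaults to all genes of the set's species (the
    "genome as a whole"); pass ``universe_ids`` to restrict it, e.g. to
    the filter-surviving genes.  The set must be a subset of the
    universe and single-species.  Returns one row per category present
    in the universe, sorted by p.
    """
    set_ids = list(dict.fromkeys(set_ids))
    if not set_ids:
        raise EnrichmentError("empty gene set")
    missing = [g for g in set_ids if g not in gene_table]
    if missing:
        raise EnrichmentError(f"set genes absent from gene table: {missing[:3]}")
    species = {gene_table.species_of(g) for g in set_ids}
    if len(species) > 1:
        raise EnrichmentError("gene set spans both species; enrich per species")
    (sp,) = species
    if universe_ids is None:
        universe = list(gene_table.genes_of(sp))
    else:
        universe = list(dict.fromkeys(universe_ids))
        universe = [g for g in universe if gene_table.species_of(g) is sp]
    if not universe:
        raise EnrichmentError("empty universe")
    outside = set(set_ids) - set(universe)
    if outside:
        raise EnrichmentError(
            f"set genes outside the universe: {sorted(outside)[:3]}"
        )
    N = len(universe)
    n = len(set_ids)
    cat_universe: dict[str, int] = {}
    for g in universe:
        for c in gene_table.categories_of(g):
            cat_universe[c] = cat_universe.get(c, 0) + 1
    if not cat_universe:
        raise EnrichmentError("no categories present in the universe")
    cat_set: dict[str, int] = {c: 0 for c in cat_universe}
    for g in set_ids:
        for c in gene_table.categories_of(g):
            cat_set[c] += 1
    rows = []
    for cat in sorted(cat_universe):
        K = cat_universe[cat]
        k = cat_set[cat]
        p = fisher_p(k, n, K, N, tail=tail)
        rows.append(
            {
                "category": cat,
                "N": N,
                "K": K,
                "n": n,
                "k": k,
                "ratio": enrichment_ratio(k, n, K, N),
                "p_value": p,
            }
        )
    df = pd.DataFrame(rows)
    _, padj, _, _ = multipletests(df["p_value"].to_numpy(), method="fdr_bh")
    df["adjusted_p"] = padj
    df["significant"] = df["p_value"] < alpha
    return df.sort_values(["p_value", "category"]).reset_index(drop=True)
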