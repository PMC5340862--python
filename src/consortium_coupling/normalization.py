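"""Count normalization, gene filtering, and profile transforms.

Raw counts are first depth-normalized with median-of-ratios size
factors, then divided by gene length in kilobases.  Two expression
variants are supported:

``scaled`` (default)
    classic reads-per-kilobase-per-million: the per-kb value is further
    multiplied by 1e6 / (sum of size-factor-normalized counts in the
    sample), so thresholds carry the familiar RPKM scale.
``per-kb``
    the literal "normalized counts per kilobase" reading, with no
    per-million rescaling.

Gene filtering applies two removal rules -- a mean raw count of zero in
any condition, and a grand-mean expression below a threshold (default
15) -- and, ahead of clustering, a variance mask dropping the flattest
fraction of profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import (
    Axis,
    CountMatrix,
    Design,
    ExpressionMatrix,
    GeneTable,
    ProfileMatrix,
    Species,
)

logger = logging.getLogger(__name__)


class NormalizationError(ValueError):
    pass


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios sample size factors.

    For every gene with nonzero counts in all samples ("reference
    genes"), compute the ratio of its count in a sample to its
    geometric mean across samples; the sample's factor is the median of
    those ratios.

    Raises
    ------
    NormalizationError
        If fewer than two samples are present or no gene has positive
        counts in every sample (the pseudo-reference fallback some
        tools offer is deliberately not implemented).
    """
    df = counts.df
    if df.shape[1] < 2:
        raise NormalizationError("size factors need at least two samples")
    positive = (df.to_numpy() > 0).all(axis=1)
    if not positive.any():
        raise NormalizationError(
            "no gene has nonzero counts in every sample; cannot form the "
            "median-of-ratios reference (pseudo-reference fallback is disabled)"
        )
    ref = df.loc[positive].to_numpy(dtype=float)
    log_geomean = np.log(ref).mean(axis=1, keepdims=True)
    ratios = np.exp(np.log(ref) - log_geomean)
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=df.columns, name="size_factor")


def per_kb_expression(
    counts: CountMatrix,
    factors: pd.Series,
    genes: GeneTable,
    variant: str = "scaled",
    library: str = "joint",
) -> ExpressionMatrix:
    """Depth- and length-normalized expression.

    value[g, j] = (count[g, j] / factor[j]) / (length_g / 1000), and for
    the ``scaled`` variant additionally * 1e6 / sum_g(count[g, j] /
    factor[j]).  With ``library="per-species"`` the per-million
    denominator is the normalized library of the gene's own species
    only; the default ``joint`` library mirrors mapping both genomes as
    one reference.
    """
    if variant not in ("scaled", "per-kb"):
        raise NormalizationError(f"unknown expression variant {variant!r}")
    if library not in ("joint", "per-species"):
        raise NormalizationError(f"unknown library mode {library!r}")
    df = counts.df
    missing = [s for s in df.columns if s not in factors.index]
    if missing:
        raise NormalizationError(f"size factors missing for samples {missing}")
    norm = df.div(factors[df.columns], axis=1)
    lengths_kb = genes.lengths_bp.reindex(df.index) / 1000.0
    if lengths_kb.isna().any():
        bad = list(lengths_kb.index[lengths_kb.isna()])[:3]
        raise NormalizationError(f"genes absent from gene table: {bad}")
    perkb = norm.div(lengths_kb, axis=0)
    if variant == "per-kb":
        return ExpressionMatrix(perkb, variant=variant)
    if library == "joint":
        scale = 1e6 / norm.sum(axis=0)
        scaled = perkb.mul(scale, axis=1)
    else:
        species = genes.species_series().reindex(df.index)
        scaled = perkb.copy()
        for sp in Species:
            mask = (species == sp.value).to_numpy()
            if not mask.any():
                continue
            totals = norm.loc[mask].sum(axis=0)
            scaled.loc[mask] = perkb.loc[mask].mul(1e6 / totals, axis=1)
    return ExpressionMatrix(scaled, variant=variant)


def condition_means(
    expr: ExpressionMatrix | CountMatrix, design: Design
) -> pd.DataFrame:
    """Arithmetic mean over replicates, one column per design condition."""
    df = expr.df
    out = {}
    for label in design.condition_labels:
        samples = list(design.samples_for(label))
        missing = [s for s in samples if s not in df.columns]
        if missing:
            raise NormalizationError(
                f"condition {label!r}: samples {missing} absent from matrix"
            )
        out[label] = df[samples].mean(axis=1)
    return pd.DataFrame(out)


@dataclass
class FilterReport:
    """Outcome of the gene-level filters.

    The removal counts partition the input:
    n_input - n_removed_zero_condition - n_removed_low_expression
    - n_masked_low_variance = number of kept genes.  A gene failing
    both removal rules is tallied under the zero-condition rule.
    """

    n_input: int
    n_removed_zero_condition: int
    n_removed_low_expression: int
    kept: tuple[str, ...]
    n_masked_low_variance: int = 0
    min_expression: float = 15.0

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_removed_zero_condition": self.n_removed_zero_condition,
            "n_removed_low_expression": self.n_removed_low_expression,
            "n_masked_low_variance": self.n_masked_low_variance,
            "n_kept": len(self.kept),
            "min_expression": self.min_expression,
        }


def filter_genes(
    counts: CountMatrix,
    expr: ExpressionMatrix,
    design: Design,
    min_expression: float = 15.0,
) -> FilterReport:
    """Apply the two removal rules.

    A gene is removed iff its mean raw count over replicates is zero in
    at least one condition, or its mean expression over *all* samples
    of the dataset is strictly below ``min_expression``.  Both rules
    are evaluated over every condition/sample of the dataset, so the
    filter is idempotent on its own kept set.
    """
    count_means = condition_means(counts, design)
    zero_any = (count_means == 0).any(axis=1)
    grand_mean = expr.df.loc[counts.df.index, list(design.samples)].mean(axis=1)
    low = grand_mean < min_expression
    removed_zero = zero_any
    removed_low = low & ~zero_any
    kept = tuple(counts.df.index[~(zero_any | low)])
    report = FilterReport(
        n_input=len(counts.df),
        n_removed_zero_condition=int(removed_zero.sum()),
        n_removed_low_expression=int(removed_low.sum()),
        kept=kept,
        min_expression=min_expression,
    )
    logger.info(
        "gene filter: %d input, %d removed (zero-count condition), "
        "%d removed (mean expression < %g), %d kept",
        report.n_input,
        report.n_removed_zero_condition,
        report.n_removed_low_expression,
        min_expression,
        len(kept),
    )
    return report


def variance_mask(profiles: ProfileMatrix | pd.DataFrame, fraction: float = 0.30) -> tuple[str, ...]:
    """Drop the flattest profiles ahead of clustering.

    Removes the ``floor(fraction * n)`` genes with the smallest sample
    variance of their profile values; ties are broken by gene id
    (lexicographic) so the mask is deterministic.  Returns the kept
    gene ids in the input order.
    """
    df = profiles.values if isinstance(profiles, ProfileMatrix) else profiles
    if len(df) == 0:
        raise NormalizationError("variance_mask: no profiles given")
    if not (0 <= fraction < 1):
        raise NormalizationError(f"fraction must be in [0, 1), got {fraction}")
    n_remove = int(np.floor(fraction * len(df)))
    if n_remove == 0:
        return tuple(df.index)
    variances = df.var(axis=1, ddof=1)
    order = sorted(df.index, key=lambda g: (variances[g], g))
    removed = set(order[:n_remove])
    return tuple(g for g in df.index if g not in removed)


def normalize_profile(profiles, gene_ids=None):
    """Reference-scale profiles: divide by the lowest-treatment value.

    Accepts a 1-D sequence (one profile) or a genes-x-conditions
    DataFrame / ProfileMatrix; the first column is the reference (the
    lowest irradiance or pO2 condition) and becomes exactly 1.0.

    Raises
    ------
    NormalizationError
        If any reference value is <= 0, naming the offending gene.
    """
    if isinstance(profiles, ProfileMatrix):
        scaled = normalize_profile(profiles.values)
        return ProfileMatrix(values=scaled, axis=profiles.axis)
    if isinstance(profiles, pd.DataFrame):
        ref = profiles.iloc[:, 0]
        bad = ref.index[ref <= 0]
        if len(bad):
            raise NormalizationError(
                f"reference (lowest-treatment) value <= 0 for gene {bad[0]!r}"
            )
        return profiles.div(ref, axis=0)
    values = np.asarray(profiles, dtype=float)
    if values[0] <= 0:
        name = gene_ids if gene_ids is not None else "<unnamed>"
        raise NormalizationError(f"reference value <= 0 for gene {name!r}")
    return values / values[0]


def log_mean_center(profiles, gene_ids=None):
    """log2 of each profile value over the profile's arithmetic mean.

    The transform used to display cluster expression patterns; output
    rows sum to <= 0 (AM-GM), with equality only for constant profiles.
    """
    if isinstance(profiles, ProfileMatrix):
        return ProfileMatrix(values=log_mean_center(profiles.values), axis=profiles.axis)
    if isinstance(profiles, pd.DataFrame):
        arr = profiles.to_numpy(dtype=float)
        if (arr <= 0).any():
            bad = profiles.index[(arr <= 0).any(axis=1)][0]
            raise NormalizationError(f"nonpositive profile value for gene {bad!r}")
        return pd.DataFrame(
            np.log2(arr / arr.mean(axis=1, keepdims=True)),
            index=profiles.index,
            columns=profiles.columns,
        )
    values = np.asarray(profiles, dtype=float)
    if (values <= 0).any():
        name = gene_ids if gene_ids is not None else "<unnamed>"
        raise NormalizationError(f"nonpositive profile value for gene {name!r}")
    return np.log2(values / values.mean())


def axis_profiles(
    cond_means: pd.DataFrame, axis: Axis, gene_ids=None
) -> ProfileMatrix:
    """Slice per-condition means down to one axis's ordered conditions."""
    missing = [lab for lab in axis.labels if lab not in cond_means.columns]
    if missing:
        raise NormalizationError(f"axis conditions missing from means: {missing}")
    values = cond_means[list(axis.labels)]
    if gene_ids is not None:
        values = values.loc[list(gene_ids)]
    return ProfileMatrix(values=values, axis=axis)
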