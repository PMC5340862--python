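"""Shared domain types and tabular I/O for the consortium pipeline.

The pipeline analyses a two-species phototroph-heterotroph consortium
(a thermophilic cyanobacterium plus an obligate aerobic heterotroph)
grown in turbidostat steady states arranged along two treatment axes:
an irradiance axis at fixed (lowest) oxygen tension, and a dissolved-O2
(pO2) axis at fixed (highest) irradiance.  The two axes share one
corner condition: highest irradiance at the lowest pO2.

All interchange files are tab-separated UTF-8 text with a header row;
writers prepend a ``#consortium-coupling v<version>`` comment line and
readers ignore ``#`` comments.  Missing cells are an error everywhere:
silently imputing zeros would corrupt the zero-count gene filter
downstream.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from ._version import __version__

logger = logging.getLogger(__name__)

FORMAT_HEADER = f"#consortium-coupling v{__version__}"

IRRADIANCE_AXIS = "irradiance"
PO2_AXIS = "pO2"


class CoreModelError(ValueError):
    """Invalid domain object or interchange file."""


class Species(str, enum.Enum):
    """The two members of the binary consortium."""

    CYANOBACTERIUM = "cyanobacterium"
    HETEROTROPH = "heterotroph"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class GeneRecord:
    """One gene of either species.

    ``length_bp`` feeds the per-kilobase expression normalization;
    ``categories`` are opaque functional-category labels used by the
    enrichment stage.
    """

    gene_id: str
    species: Species
    length_bp: int
    categories: frozenset[str] = frozenset()
    product: str = ""

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise CoreModelError("gene_id must be a non-empty string")
        if self.length_bp <= 0:
            raise CoreModelError(
                f"gene {self.gene_id!r}: length_bp must be positive, got {self.length_bp}"
            )


class GeneTable:
    """Immutable catalog of genes from both species.

    Gene ids are unique; iteration order is the input order.
    """

    def __init__(self, records: Iterable[GeneRecord]):
        records = list(records)
        seen: set[str] = set()
        for rec in records:
            if rec.gene_id in seen:
                raise CoreModelError(f"duplicate gene_id {rec.gene_id!r} in gene table")
            seen.add(rec.gene_id)
        self._records: tuple[GeneRecord, ...] = tuple(records)
        self._by_id = {rec.gene_id: rec for rec in records}

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self._records)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self._by_id[gene_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneTable):
            return NotImplemented
        return self._records == other._records

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(rec.gene_id for rec in self._records)

    @property
    def lengths_bp(self) -> pd.Series:
        return pd.Series(
            {rec.gene_id: rec.length_bp for rec in self._records}, name="length_bp"
        )

    def species_of(self, gene_id: str) -> Species:
        return self._by_id[gene_id].species

    def species_series(self) -> pd.Series:
        return pd.Series(
            {rec.gene_id: rec.species.value for rec in self._records}, name="species"
        )

    def genes_of(self, species: Species | str) -> tuple[str, ...]:
        species = Species(species)
        return tuple(r.gene_id for r in self._records if r.species is species)

    def categories_of(self, gene_id: str) -> frozenset[str]:
        return self._by_id[gene_id].categories

    @property
    def category_vocabulary(self) -> tuple[str, ...]:
        vocab: set[str] = set()
        for rec in self._records:
            vocab |= rec.categories
        return tuple(sorted(vocab))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [r.gene_id for r in self._records],
                "species": [r.species.value for r in self._records],
                "length_bp": [r.length_bp for r in self._records],
                "categories": [";".join(sorted(r.categories)) for r in self._records],
                "product": [r.product for r in self._records],
            }
        )

    def save(self, path: str | Path) -> None:
        _write_tsv(self.to_frame(), path)


def load_gene_table(path: str | Path) -> GeneTable:
    """Read a gene table TSV.

    Required columns: ``gene_id``, ``species``, ``length_bp``,
    ``categories`` (semicolon-delimited, may be empty); ``product`` is
    optional.  Duplicate ids and non-positive lengths are hard errors.
    """
    df = _read_tsv(path)
    required = {"gene_id", "species", "length_bp", "categories"}
    missing = required - set(df.columns)
    if missing:
        raise CoreModelError(f"gene table {path}: missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        cats = row.categories if isinstance(row.categories, str) else ""
        product = getattr(row, "product", "")
        if not isinstance(product, str):  # empty cell read as NaN
            product = ""
        records.append(
            GeneRecord(
                gene_id=str(row.gene_id),
                species=Species(row.species),
                length_bp=int(row.length_bp),
                categories=frozenset(c for c in cats.split(";") if c),
                product=product,
            )
        )
    return GeneTable(records)


@dataclass(frozen=True)
class SteadyStateCondition:
    """One turbidostat steady state.

    Parameters
    ----------
    label
        Condition code, e.g. ``HL-LO`` (high light, low O2).
    irradiance
        Incident irradiance, umol photons m^-2 s^-1.
    pO2
        Partial pressure of O2 in the inlet gas, atm.
    n_replicates
        Biological replicates sampled at this steady state (>= 2;
        transcriptomes were sampled at least in duplicate, one
        condition in quadruplicate).
    """

    label: str
    irradiance: float
    pO2: float
    n_replicates: int

    def __post_init__(self) -> None:
        if self.irradiance < 0 or self.pO2 < 0:
            raise CoreModelError(
                f"condition {self.label!r}: irradiance and pO2 must be >= 0"
            )
        if self.n_replicates < 2:
            raise CoreModelError(
                f"condition {self.label!r}: n_replicates must be >= 2, "
                f"got {self.n_replicates}"
            )


@dataclass(frozen=True)
class Axis:
    """An ordered treatment series at one fixed value of the other factor."""

    name: str  # "irradiance" or "pO2"
    conditions: tuple[SteadyStateCondition, ...]
    fixed_value: float  # the pinned value of the complementary factor

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self.conditions)

    @property
    def treatment_values(self) -> tuple[float, ...]:
        if self.name == IRRADIANCE_AXIS:
            return tuple(c.irradiance for c in self.conditions)
        return tuple(c.pO2 for c in self.conditions)

    def __len__(self) -> int:
        return len(self.conditions)


@dataclass(frozen=True)
class DesignAxes:
    irradiance: Axis
    pO2: Axis


class Design:
    """Steady-state experimental design: conditions plus a sample map."""

    def __init__(
        self,
        conditions: Sequence[SteadyStateCondition],
        sample_map: Mapping[str, str],
    ):
        labels = [c.label for c in conditions]
        if len(set(labels)) != len(labels):
            raise CoreModelError("condition labels must be unique")
        pairs = [(c.irradiance, c.pO2) for c in conditions]
        if len(set(pairs)) != len(pairs):
            raise CoreModelError("(irradiance, pO2) pairs must be unique")
        by_label = {c.label: c for c in conditions}
        counts: dict[str, int] = {label: 0 for label in by_label}
        for sample, label in sample_map.items():
            if label not in by_label:
                raise CoreModelError(
                    f"sample {sample!r} maps to undeclared condition {label!r}"
                )
            counts[label] += 1
        for label, cond in by_label.items():
            if counts[label] != cond.n_replicates:
                raise CoreModelError(
                    f"condition {label!r} declares {cond.n_replicates} replicates "
                    f"but {counts[label]} samples map to it"
                )
        self.conditions: tuple[SteadyStateCondition, ...] = tuple(conditions)
        self.sample_map: dict[str, str] = dict(sample_map)
        self._by_label = by_label

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Design):
            return NotImplemented
        return (
            self.conditions == other.conditions and self.sample_map == other.sample_map
        )

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self.sample_map)

    @property
    def condition_labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self.conditions)

    def condition(self, label: str) -> SteadyStateCondition:
        return self._by_label[label]

    def samples_for(self, label: str) -> tuple[str, ...]:
        return tuple(s for s, lab in self.sample_map.items() if lab == label)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sample, label in self.sample_map.items():
            cond = self._by_label[label]
            rows.append(
                {
                    "sample_id": sample,
                    "label": label,
                    "irradiance": cond.irradiance,
                    "pO2": cond.pO2,
                }
            )
        return pd.DataFrame(rows)

    def save(self, path: str | Path) -> None:
        _write_tsv(self.to_frame(), path)


def load_design(path: str | Path) -> Design:
    """Read a design TSV with columns sample_id, label, irradiance, pO2.

    Replicate counts are inferred from the number of samples mapped to
    each condition label.  Condition order follows first appearance.
    """
    df = _read_tsv(path)
    required = {"sample_id", "label", "irradiance", "pO2"}
    missing = required - set(df.columns)
    if missing:
        raise CoreModelError(f"design {path}: missing columns {sorted(missing)}")
    conditions: list[SteadyStateCondition] = []
    seen: dict[str, tuple[float, float]] = {}
    counts: dict[str, int] = {}
    for row in df.itertuples(index=False):
        label = str(row.label)
        pair = (float(row.irradiance), float(row.pO2))
        if label in seen:
            if seen[label] != pair:
                raise CoreModelError(
                    f"design {path}: condition {label!r} has inconsistent treatments"
                )
        else:
            seen[label] = pair
        counts[label] = counts.get(label, 0) + 1
    for label, (irr, po2) in seen.items():
        conditions.append(
            SteadyStateCondition(
                label=label, irradiance=irr, pO2=po2, n_replicates=counts[label]
            )
        )
    sample_map = {str(r.sample_id): str(r.label) for r in df.itertuples(index=False)}
    return Design(conditions, sample_map)


def validate_design(design: Design) -> DesignAxes:
    """Extract the two treatment axes from a design.

    The irradiance axis is the largest group of conditions sharing one
    pO2 value (ties broken toward the lowest pO2), sorted by increasing
    irradiance; the pO2 axis is the largest group sharing one
    irradiance (ties broken toward the highest irradiance), sorted by
    increasing pO2.  Each axis needs at least three conditions.  The
    output is invariant under permutation of the input condition order.
    """
    irr_axis = _find_axis(
        design,
        group_key=lambda c: c.pO2,
        sort_key=lambda c: c.irradiance,
        tie_break=min,
        name=IRRADIANCE_AXIS,
    )
    po2_axis = _find_axis(
        design,
        group_key=lambda c: c.irradiance,
        sort_key=lambda c: c.pO2,
        tie_break=max,
        name=PO2_AXIS,
    )
    return DesignAxes(irradiance=irr_axis, pO2=po2_axis)


def _find_axis(design, group_key, sort_key, tie_break, name) -> Axis:
    groups: dict[float, list[SteadyStateCondition]] = {}
    for cond in design.conditions:
        groups.setdefault(group_key(cond), []).append(cond)
    best_size = max(len(v) for v in groups.values())
    if best_size < 3:
        raise CoreModelError(
            f"no valid {name} axis: need >=3 conditions at a fixed "
            f"{'pO2' if name == IRRADIANCE_AXIS else 'irradiance'} "
            f"(largest group has {best_size})"
        )
    fixed = tie_break(k for k, v in groups.items() if len(v) == best_size)
    conds = tuple(sorted(groups[fixed], key=sort_key))
    values = [sort_key(c) for c in conds]
    if len(set(values)) != len(values):
        raise CoreModelError(f"{name} axis: duplicate treatment values {values}")
    return Axis(name=name, conditions=conds, fixed_value=fixed)


class CountMatrix:
    """Raw read counts, genes x samples (genes in rows)."""

    def __init__(self, df: pd.DataFrame):
        if df.index.has_duplicates or df.columns.has_duplicates:
            raise CoreModelError("count matrix has duplicate gene or sample ids")
        if df.isna().any().any():
            raise CoreModelError("count matrix contains missing cells")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise CoreModelError("count matrix contains non-numeric cells")
        if (values < 0).any():
            bad = df.columns[(values < 0).any(axis=0)][0]
            raise CoreModelError(f"negative count in sample {bad!r}")
        if not np.allclose(values, np.round(values)):
            raise CoreModelError("counts must be integers")
        self.df = df.astype(np.int64)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.df.index)

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self.df.columns)

    def save(self, path: str | Path) -> None:
        _write_tsv(self.df.rename_axis("gene_id").reset_index(), path)


class ExpressionMatrix:
    """Per-kilobase normalized expression, genes x samples, nonneg finite."""

    def __init__(self, df: pd.DataFrame, variant: str = "scaled"):
        values = df.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise CoreModelError("expression matrix contains non-finite values")
        if (values < 0).any():
            raise CoreModelError("expression values must be >= 0")
        self.df = df.astype(float)
        self.variant = variant

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.df.index)

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self.df.columns)

    def save(self, path: str | Path) -> None:
        _write_tsv(self.df.rename_axis("gene_id").reset_index(), path)


def load_counts(
    path: str | Path, gene_table: GeneTable, design: Design
) -> CountMatrix:
    """Read a counts TSV (genes in rows, samples in columns).

    Genes absent from the gene table are dropped with a logged warning;
    samples absent from the design, negative counts, and missing cells
    are hard errors.
    """
    df = _read_tsv(path)
    if df.columns[0] != "gene_id":
        raise CoreModelError(f"counts {path}: first column must be 'gene_id'")
    df = df.set_index("gene_id")
    unknown_samples = [s for s in df.columns if s not in design.sample_map]
    if unknown_samples:
        raise CoreModelError(
            f"counts {path}: samples not in design: {unknown_samples}"
        )
    missing_samples = [s for s in design.samples if s not in df.columns]
    if missing_samples:
        raise CoreModelError(
            f"counts {path}: design samples missing from matrix: {missing_samples}"
        )
    known = df.index.isin(gene_table.gene_ids)
    n_dropped = int((~known).sum())
    if n_dropped:
        logger.warning(
            "counts %s: dropped %d genes absent from the gene table", path, n_dropped
        )
    restricted = df.loc[known, list(design.samples)]
    matrix = CountMatrix(restricted)
    matrix.n_dropped_genes = n_dropped  # type: ignore[attr-defined]
    return matrix


def load_expression(path: str | Path) -> ExpressionMatrix:
    df = _read_tsv(path)
    if df.columns[0] != "gene_id":
        raise CoreModelError(f"expression {path}: first column must be 'gene_id'")
    return ExpressionMatrix(df.set_index("gene_id"))


@dataclass
class ProfileMatrix:
    """Per-gene condition profiles along one treatment axis.

    Rows are genes; columns are the axis condition labels in order of
    increasing treatment value.  ``values`` holds replicate means (or a
    transform of them).
    """

    values: pd.DataFrame
    axis: Axis

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.axis.labels):
            raise CoreModelError(
                "profile columns must equal the axis condition labels in order: "
                f"{list(self.values.columns)} != {list(self.axis.labels)}"
            )

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# TSV plumbing

def _write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(FORMAT_HEADER + "\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str})
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed file
        raise CoreModelError(f"cannot parse TSV {path}: {exc}") from exc
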