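"""Seeded generators for every input the pipeline consumes.

The generators emulate the study conditions of a two-species
turbidostat experiment: five steady states spanning an irradiance axis
(197 / 1,190 / 1,995 umol photons m^-2 s^-1 at pO2 = 0 atm) and a pO2
axis (0 / 0.30 / 0.59 atm at the highest irradiance), transcriptomes
sampled in duplicate (quadruplicate at the shared corner condition of
the binary culture), 1-min turbidostat process logs, two-population
flow-cytometry event streams, and treated/control ROS plates.

Expression profiles are planted from archetypal shapes along each
ordered axis -- monotone increasing/decreasing (geometric ramps
spanning ``responsive_fold`` between the extremes), tent and inverse
tent (extremum at the midpoint, extremes equal), and flat.  Responsive
genes are exactly the monotone ones: their extreme-condition ratio is
``responsive_fold`` (default 4), a safety margin above the 2-fold
calling threshold, while every non-responsive gene moves at most
``nonresponsive_fold_max`` (default 1.5) between any two conditions.
Replicate counts follow a negative-binomial observation model whose
``dispersion`` parameter is the extra-Poisson coefficient of variation
(NB size = dispersion**-2), reflecting the tight replicate concordance
of steady-state continuous culture.

Every generator is a pure function of (config, seed): identical inputs
give bit-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .core_model import (
    Axis,
    CountMatrix,
    Design,
    GeneTable,
    GeneRecord,
    IRRADIANCE_AXIS,
    PO2_AXIS,
    Species,
    SteadyStateCondition,
    validate_design,
)
from .physiology import (
    GasConfig,
    Gate,
    TurbidostatLog,
    cmol_rate,
    dissolved_o2,
)

logger = logging.getLogger(__name__)

SHAPES = ("tent", "inverse-tent", "decreasing", "increasing", "flat")

CULTURE_BINARY = "binary"
CULTURE_AXENIC = "axenic"

#: 20 opaque functional-category labels for the synthetic gene catalog.
CATEGORY_VOCABULARY = (
    "photosystem II",
    "photosystem I stabilization",
    "carbon fixation",
    "carboxysome",
    "pyruvate metabolism",
    "TCA cycle",
    "oxidative phosphorylation",
    "NADH dehydrogenase",
    "nitrate assimilation",
    "amino acid biosynthesis",
    "methionine metabolism",
    "cysteine metabolism",
    "vitamin B12 biosynthesis",
    "vitamin B12 salvage",
    "Fe-S cluster assembly",
    "peroxide detoxification",
    "RNA polymerase",
    "ribosome",
    "sugar transport",
    "EPS synthesis",
)


class SyntheticDataError(ValueError):
    pass


@dataclass(frozen=True)
class TruthConfig:
    """Ground-truth configuration for the transcriptome generator.

    Planted responsive counts are keyed by (culture, axis, species);
    the cyanobacterial defaults are the study-calibrated counts (354 /
    339 light-responsive and 105 / 60 O2-responsive genes under axenic
    / binary growth), and the heterotroph defaults are free choices of
    realistic magnitude.  ``shape_fractions`` sets the tent /
    inverse-tent split among *non-responsive* genes per axis (the rest
    are flat).
    """

    n_genes_cyano: int = 2476
    n_genes_het: int = 2016
    planted_responsive: Mapping[tuple[str, str, str], int] = field(
        default_factory=lambda: {
            (CULTURE_AXENIC, IRRADIANCE_AXIS, "cyanobacterium"): 354,
            (CULTURE_BINARY, IRRADIANCE_AXIS, "cyanobacterium"): 339,
            (CULTURE_AXENIC, PO2_AXIS, "cyanobacterium"): 105,
            (CULTURE_BINARY, PO2_AXIS, "cyanobacterium"): 60,
            (CULTURE_BINARY, IRRADIANCE_AXIS, "heterotroph"): 300,
            (CULTURE_BINARY, PO2_AXIS, "heterotroph"): 200,
        }
    )
    shape_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"tent": 0.12, "inverse-tent": 0.12}
    )
    responsive_fold: float = 4.0
    nonresponsive_fold_max: float = 1.5
    dispersion: float = 0.05
    het_read_fraction: float = 0.10
    baseline_mean: float = 200.0
    baseline_sigma: float = 0.3
    baseline_floor_frac: float = 0.6
    library_sigma: float = 0.15

    def __post_init__(self) -> None:
        if not (self.responsive_fold > 2.0 > self.nonresponsive_fold_max):
            raise SyntheticDataError(
                "need responsive_fold > 2 > nonresponsive_fold_max, got "
                f"{self.responsive_fold} and {self.nonresponsive_fold_max}"
            )
        if self.dispersion < 0:
            raise SyntheticDataError("dispersion must be >= 0")
        if not (0 <= self.het_read_fraction < 1):
            raise SyntheticDataError("het_read_fraction must be in [0, 1)")
        total_shapes = sum(self.shape_fractions.values())
        if total_shapes > 1:
            raise SyntheticDataError("non-responsive shape fractions exceed 1")


def default_design(culture: str = CULTURE_BINARY) -> Design:
    """The five steady states of the study, with its replication scheme.

    Duplicates everywhere, except the shared corner condition (highest
    irradiance at pO2 = 0) of the binary culture, which was sampled in
    quadruplicate.
    """
    reps_hl_lo = 4 if culture == CULTURE_BINARY else 2
    conditions = [
        SteadyStateCondition("LL-LO", irradiance=197.0, pO2=0.0, n_replicates=2),
        SteadyStateCondition("ML-LO", irradiance=1190.0, pO2=0.0, n_replicates=2),
        SteadyStateCondition(
            "HL-LO", irradiance=1995.0, pO2=0.0, n_replicates=reps_hl_lo
        ),
        SteadyStateCondition("HL-MO", irradiance=1995.0, pO2=0.30, n_replicates=2),
        SteadyStateCondition("HL-HO", irradiance=1995.0, pO2=0.59, n_replicates=2),
    ]
    prefix = "BI" if culture == CULTURE_BINARY else "AX"
    sample_map = {}
    for cond in conditions:
        for r in range(1, cond.n_replicates + 1):
            sample_map[f"{prefix}_{cond.label}_r{r}"] = cond.label
    return Design(conditions, sample_map)


def make_genomes(truth: TruthConfig, seed: int) -> GeneTable:
    """Synthetic two-species gene catalog.

    Gene lengths are uniform integers on 300-3000 bp; each gene carries
    0-2 categories from a fixed 20-label vocabulary.
    """
    rng = np.random.default_rng(seed)
    records = []
    specs = [
        ("TE", Species.CYANOBACTERIUM, truth.n_genes_cyano),
        ("MR", Species.HETEROTROPH, truth.n_genes_het),
    ]
    for prefix, species, n in specs:
        lengths = rng.integers(300, 3001, size=n)
        n_cats = rng.integers(0, 3, size=n)
        for i in range(n):
            cats = rng.choice(
                len(CATEGORY_VOCABULARY), size=n_cats[i], replace=False
            )
            records.append(
                GeneRecord(
                    gene_id=f"{prefix}_{i + 1:04d}",
                    species=species,
                    length_bp=int(lengths[i]),
                    categories=frozenset(CATEGORY_VOCABULARY[c] for c in cats),
                    product=f"{species.value} protein {i + 1}",
                )
            )
    return GeneTable(records)


def _shape_multiplier(shape: str, position: np.ndarray, truth: TruthConfig) -> np.ndarray:
    """Multiplier of a shape at fractional axis positions in [0, 1]."""
    F = truth.responsive_fold
    A = truth.nonresponsive_fold_max
    if shape == "increasing":
        return F ** position
    if shape == "decreasing":
        return F ** (-position)
    if shape == "tent":
        return A ** (1.0 - np.abs(2.0 * position - 1.0))
    if shape == "inverse-tent":
        return A ** (np.abs(2.0 * position - 1.0) - 1.0)
    if shape == "flat":
        return np.ones_like(position)
    raise SyntheticDataError(f"unknown shape {shape!r}")


def _axis_positions(axis: Axis, design: Design) -> dict[str, float]:
    """Fractional position of every design condition along one axis."""
    values = np.asarray(axis.treatment_values, dtype=float)
    ranks = np.arange(len(values), dtype=float)
    out = {}
    for cond in design.conditions:
        value = cond.irradiance if axis.name == IRRADIANCE_AXIS else cond.pO2
        out[cond.label] = float(np.interp(value, values, ranks) / (len(values) - 1))
    return out


def _assign_shapes(
    rng: np.random.Generator,
    gene_ids: list[str],
    n_responsive: int,
    truth: TruthConfig,
) -> pd.Series:
    """Draw per-gene shapes: monotone for responsive genes, tent /
    inverse-tent / flat for the rest."""
    n = len(gene_ids)
    if n_responsive > n:
        raise SyntheticDataError(
            f"planted responsive count {n_responsive} exceeds {n} genes"
        )
    shapes = np.empty(n, dtype=object)
    order = rng.permutation(n)
    responsive_idx = order[:n_responsive]
    n_up = n_responsive // 2 + n_responsive % 2
    shapes[responsive_idx[:n_up]] = "increasing"
    shapes[responsive_idx[n_up:]] = "decreasing"
    rest = order[n_responsive:]
    p_tent = truth.shape_fractions.get("tent", 0.0)
    p_inv = truth.shape_fractions.get("inverse-tent", 0.0)
    draws = rng.choice(
        ["tent", "inverse-tent", "flat"],
        size=len(rest),
        p=[p_tent, p_inv, 1.0 - p_tent - p_inv],
    )
    shapes[rest] = draws
    return pd.Series(shapes, index=gene_ids, name="shape")


def simulate_expression(
    genes: GeneTable,
    design: Design,
    truth: TruthConfig,
    seed: int,
    culture: str = CULTURE_BINARY,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate a two-species steady-state count matrix with its truth.

    Per-gene condition means are baseline x (irradiance-shape
    multiplier) x (pO2-shape multiplier); genes responsive on one axis
    carry a ratio-1 shape on the other, so that the set of genes whose
    noise-free extreme-condition ratio reaches 2-fold on an axis is
    exactly the planted responsive set for that axis.  Replicate counts
    add a per-sample library-depth factor (lognormal) and
    negative-binomial observation noise; the heterotroph's share of the
    sequenced library is ``het_read_fraction``.

    Returns the count matrix and a truth table holding each gene's
    baseline, per-axis shape and responsiveness, and its noise-free
    condition means.
    """
    if culture not in (CULTURE_BINARY, CULTURE_AXENIC):
        raise SyntheticDataError(f"unknown culture {culture!r}")
    axes = validate_design(design)
    rng = np.random.default_rng(seed)
    if culture == CULTURE_AXENIC:
        gene_ids = list(genes.genes_of(Species.CYANOBACTERIUM))
    else:
        gene_ids = list(genes.gene_ids)
    if not gene_ids:
        raise SyntheticDataError("no genes to simulate")
    species = genes.species_series().reindex(gene_ids)

    # per-axis shapes, responsive sets disjoint across axes within a species
    shape_cols: dict[str, pd.Series] = {}
    for sp in ("cyanobacterium", "heterotroph"):
        ids = [g for g in gene_ids if species[g] == sp]
        if not ids:
            continue
        n_light = truth.planted_responsive.get((culture, IRRADIANCE_AXIS, sp), 0)
        n_o2 = truth.planted_responsive.get((culture, PO2_AXIS, sp), 0)
        if n_light + n_o2 > len(ids):
            raise SyntheticDataError(
                f"planted responsive counts for {sp} ({n_light} + {n_o2}) "
                f"exceed the {len(ids)} genes available"
            )
        light_shapes = _assign_shapes(rng, ids, n_light, truth)
        # O2-responsive genes drawn from genes not light-responsive
        monotone = light_shapes.isin(["increasing", "decreasing"])
        free = [g for g in ids if not monotone[g]]
        o2_free = _assign_shapes(rng, free, n_o2, truth)
        o2_shapes = pd.Series("flat", index=ids, name="shape")
        # light-responsive genes stay ratio-1 on the O2 axis
        taken = light_shapes[monotone].index
        o2_shapes[taken] = rng.choice(
            ["tent", "inverse-tent", "flat"], size=len(taken)
        )
        o2_shapes[o2_free.index] = o2_free
        shape_cols.setdefault(IRRADIANCE_AXIS, pd.Series(dtype=object))
        shape_cols.setdefault(PO2_AXIS, pd.Series(dtype=object))
        shape_cols[IRRADIANCE_AXIS] = pd.concat(
            [shape_cols[IRRADIANCE_AXIS], light_shapes]
        )
        shape_cols[PO2_AXIS] = pd.concat([shape_cols[PO2_AXIS], o2_shapes])
    shape_light = shape_cols[IRRADIANCE_AXIS].reindex(gene_ids)
    shape_o2 = shape_cols[PO2_AXIS].reindex(gene_ids)

    # baselines: lognormal around baseline_mean with a floor keeping every
    # gene well above the expression filter and the calling noise floor
    floor = truth.baseline_floor_frac * truth.baseline_mean
    baselines = truth.baseline_mean * np.exp(
        rng.normal(0.0, truth.baseline_sigma, size=len(gene_ids))
    )
    baselines = np.maximum(baselines, floor)
    baselines = pd.Series(baselines, index=gene_ids, name="baseline")
    if culture == CULTURE_BINARY and truth.het_read_fraction > 0:
        is_het = (species == "heterotroph").to_numpy()
        if is_het.any() and (~is_het).any():
            f = truth.het_read_fraction
            scale = (
                f / (1.0 - f)
                * baselines[~is_het].sum()
                / baselines[is_het].sum()
            )
            baselines[is_het] *= scale

    light_pos = _axis_positions(axes.irradiance, design)
    o2_pos = _axis_positions(axes.pO2, design)

    def multipliers(shapes: pd.Series, position: float) -> np.ndarray:
        out = np.ones(len(shapes))
        pos = np.array([position])
        for shape in SHAPES:
            mask = (shapes == shape).to_numpy()
            if mask.any():
                out[mask] = _shape_multiplier(shape, pos, truth)[0]
        return out

    cond_means = {}
    for cond in design.conditions:
        m_light = multipliers(shape_light, light_pos[cond.label])
        m_o2 = multipliers(shape_o2, o2_pos[cond.label])
        cond_means[cond.label] = baselines.to_numpy() * m_light * m_o2
    mean_df = pd.DataFrame(cond_means, index=gene_ids)

    lib = np.exp(rng.normal(0.0, truth.library_sigma, size=len(design.samples)))
    lib = pd.Series(lib, index=list(design.samples), name="library_factor")
    counts = np.empty((len(gene_ids), len(design.samples)), dtype=np.int64)
    for j, sample in enumerate(design.samples):
        mu = mean_df[design.sample_map[sample]].to_numpy() * lib[sample]
        if truth.dispersion == 0:
            counts[:, j] = np.rint(mu).astype(np.int64)
        else:
            size = truth.dispersion**-2
            counts[:, j] = rng.negative_binomial(size, size / (size + mu))
    count_matrix = CountMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=list(design.samples))
    )

    light_labels = axes.irradiance.labels
    o2_labels = axes.pO2.labels
    truth_df = pd.DataFrame(
        {
            "species": species,
            "baseline": baselines,
            "shape_irradiance": shape_light,
            "shape_pO2": shape_o2,
            "responsive_irradiance": shape_light.isin(["increasing", "decreasing"]),
            "responsive_pO2": shape_o2.isin(["increasing", "decreasing"]),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    for label in design.condition_labels:
        truth_df[f"mean_{label}"] = mean_df[label]
    truth_df.attrs["culture"] = culture
    truth_df.attrs["irradiance_axis"] = list(light_labels)
    truth_df.attrs["pO2_axis"] = list(o2_labels)
    logger.info(
        "simulated %s transcriptome: %d genes x %d samples",
        culture, len(gene_ids), len(design.samples),
    )
    return count_matrix, truth_df


# ---------------------------------------------------------------------------
# Turbidostat kinetics

@dataclass(frozen=True)
class KineticsParams:
    """Growth-kinetics parameters of one culture.

    The specific growth rate is the piecewise-linear light response
    ``mu_points`` minus a linear O2 inhibition ``sensitivity * pO2``.
    Only the top irradiance growth rate (0.289 h^-1, the ~2.4-h
    doubling time) is anchored to a measured value; the low- and
    mid-irradiance defaults are plausible placeholders (see the
    methods note).  ``pq`` is the photosynthetic quotient used to tie
    the simulated O2 balance to growth; the recovery of its slope, not
    its particular value, is what analyses test.
    """

    mu_points: Mapping[float, float] = field(
        default_factory=lambda: {197.0: 0.08, 1190.0: 0.18, 1995.0: 0.289}
    )
    sensitivity: float = 0.086  # h^-1 atm^-1
    pq: float = 0.40  # Cmol biomass per mol O2
    noise_rel: float = 0.02
    od_setpoint: float = 0.4
    gas_flow_L_h: float = 30.0
    volume_L: float = 5.5
    temperature_C: float = 52.0
    biomass_g_L: float = 0.25
    dO2_excess_uM: float = 15.0
    inlet_co2_frac: float = 0.05
    gas: GasConfig = field(default_factory=GasConfig)

    def __post_init__(self) -> None:
        if not (0 <= self.noise_rel <= 0.1):
            raise SyntheticDataError("noise_rel must be in [0, 0.1]")
        if self.pq <= 0 or self.sensitivity < 0:
            raise SyntheticDataError("pq must be > 0 and sensitivity >= 0")

    @classmethod
    def axenic(cls, **overrides) -> "KineticsParams":
        defaults = dict(sensitivity=0.127, pq=0.30)
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def binary(cls, **overrides) -> "KineticsParams":
        defaults = dict(sensitivity=0.086, pq=0.40)
        defaults.update(overrides)
        return cls(**defaults)

    def mu_at(self, irradiance: float) -> float:
        xs = np.array(sorted(self.mu_points))
        ys = np.array([self.mu_points[x] for x in xs])
        return float(np.interp(irradiance, xs, ys))

    def mu(self, condition: SteadyStateCondition) -> float:
        return self.mu_at(condition.irradiance) - self.sensitivity * condition.pO2


def simulate_turbidostat(
    params: KineticsParams,
    condition: SteadyStateCondition,
    duration_h: float,
    seed: int,
) -> TurbidostatLog:
    """Simulate a 1-min turbidostat log at one steady state.

    Every logged channel sits at its steady-state model value with
    relative Gaussian noise ``noise_rel``: dilution rate at the modeled
    mu, OD730 at the setpoint, dissolved O2 at the Henry-law
    equilibrium plus a photosynthetic excess, and off-gas O2/CO2
    fractions consistent with the configured photosynthetic quotient
    through the same gas balance the analyzer inverts (round-trip
    closure is exact at zero noise).
    """
    mu = params.mu(condition)
    if mu <= 0:
        raise SyntheticDataError(
            f"non-positive growth rate {mu:.4f} h^-1 at condition {condition.label!r}"
        )
    tau = 1.0 / mu
    if duration_h < 3.0 * tau:
        raise SyntheticDataError(
            f"duration {duration_h} h is below 3 residence times ({3 * tau:.2f} h)"
        )
    n = int(round(duration_h * 60.0))
    rng = np.random.default_rng(seed)
    gas = params.gas
    c_dis = dissolved_o2(condition.pO2, gas) + params.dO2_excess_uM
    q_o2 = cmol_rate(mu, gas) / params.pq  # mmol O2 h^-1 g^-1
    molar = gas.pressure_atm / (0.0820574 * gas.gas_temp_K)
    flow_mmol = params.gas_flow_L_h * molar * 1000.0
    xv = params.biomass_g_L * params.volume_L
    y_in = condition.pO2
    y_o2_out = y_in + (q_o2 * xv - mu * c_dis * params.volume_L * 1e-3) / flow_mmol
    q_c = cmol_rate(mu, gas)  # Cmmol h^-1 g^-1; CO2 uptake matches growth
    y_co2_out = params.inlet_co2_frac - q_c * xv / flow_mmol
    if y_co2_out < 0:
        raise SyntheticDataError("inlet CO2 fraction cannot support the growth rate")

    def channel(value: float) -> np.ndarray:
        if params.noise_rel == 0:
            return np.full(n, value)
        return value * (1.0 + params.noise_rel * rng.standard_normal(n))

    df = pd.DataFrame(
        {
            "time_h": np.arange(n) / 60.0,
            "dilution_rate": channel(mu),
            "od730": channel(params.od_setpoint),
            "dissolved_o2_uM": channel(c_dis),
            "offgas_o2_frac": channel(y_o2_out),
            "offgas_co2_frac": channel(y_co2_out),
        }
    )
    return TurbidostatLog(
        df=df,
        condition=condition.label,
        gas_flow_L_h=params.gas_flow_L_h,
        volume_L=params.volume_L,
        biomass_g_L=params.biomass_g_L,
        inlet_o2_frac=y_in,
        inlet_co2_frac=params.inlet_co2_frac,
        temperature_C=params.temperature_C,
    )


# ---------------------------------------------------------------------------
# Flow cytometry

@dataclass(frozen=True)
class FacsTruth:
    """Community composition and per-population channel distributions.

    The default fractions are the study's steady-state composition
    (90.2% cyanobacterium, 9.1% heterotroph), with a 0.7% debris
    population absorbing the remainder.  Channel means are separated
    by at least 4 pooled SDs so the default size/complexity gates are
    unambiguous.
    """

    fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "cyanobacterium": 0.902,
            "heterotroph": 0.091,
            "debris": 0.007,
        }
    )
    populations: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            "cyanobacterium": {
                "fsc": (120.0, 8.0),
                "ssc": (100.0, 8.0),
                "red_fl": (500.0, 60.0),
                "green_fl": (50.0, 10.0),
            },
            "heterotroph": {
                "fsc": (60.0, 6.0),
                "ssc": (40.0, 5.0),
                "red_fl": (20.0, 5.0),
                "green_fl": (300.0, 40.0),
            },
            "debris": {
                "fsc": (15.0, 4.0),
                "ssc": (12.0, 4.0),
                "red_fl": (5.0, 2.0),
                "green_fl": (10.0, 4.0),
            },
        }
    )

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise SyntheticDataError(f"population fractions sum to {total}, not 1")
        names = list(self.populations)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                separated = False
                for ch in ("fsc", "ssc"):
                    ma, sa = self.populations[a][ch]
                    mb, sb = self.populations[b][ch]
                    pooled = np.sqrt((sa**2 + sb**2) / 2.0)
                    if abs(ma - mb) >= 4.0 * pooled:
                        separated = True
                if not separated:
                    raise SyntheticDataError(
                        f"populations {a!r} and {b!r} are not separated by >= 4 "
                        "pooled SDs on any scatter channel"
                    )

    def default_gates(self) -> dict[str, Gate]:
        """Rectangular mean +/- 4 SD gates in (FSC, SSC) per population."""
        gates = {}
        for name, channels in self.populations.items():
            (mf, sf), (ms, ss) = channels["fsc"], channels["ssc"]
            gates[name] = Gate(
                fsc=(max(0.0, mf - 4 * sf), mf + 4 * sf),
                ssc=(max(0.0, ms - 4 * ss), ms + 4 * ss),
            )
        return gates


def simulate_facs(truth: FacsTruth, n_events: int, seed: int) -> pd.DataFrame:
    """Simulate a FACS event table with per-event truth labels."""
    if n_events < 1:
        raise SyntheticDataError("n_events must be >= 1")
    rng = np.random.default_rng(seed)
    names = list(truth.fractions)
    counts = rng.multinomial(n_events, [truth.fractions[n] for n in names])
    frames = []
    for name, count in zip(names, counts):
        channels = truth.populations[name]
        frames.append(
            pd.DataFrame(
                {
                    ch: np.maximum(
                        0.0, rng.normal(channels[ch][0], channels[ch][1], size=count)
                    )
                    for ch in ("fsc", "ssc", "red_fl", "green_fl")
                }
            ).assign(truth_label=name)
        )
    events = pd.concat(frames, ignore_index=True)
    return events.iloc[rng.permutation(len(events))].reset_index(drop=True)


# ---------------------------------------------------------------------------
# ROS plates

def default_ros_groups() -> dict[str, float]:
    """Treated-well fluorescence means: higher under binary cultivation,
    insensitive to the pO2 treatment."""
    return {
        "axenic-LO": 520.0,
        "axenic-HO": 540.0,
        "binary-LO": 920.0,
        "binary-HO": 940.0,
    }


def simulate_ros_plate(
    group_means: Mapping[str, float],
    control_mean: float = 200.0,
    sd: float = 40.0,
    n_reps: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate treated and solvent-control wells per group.

    Each of ``n_reps`` replicates (subfractions of cells from one
    steady state) yields one dye-treated and one matched control well
    with Gaussian noise ``sd``.
    """
    if n_reps < 2:
        raise SyntheticDataError("n_reps must be >= 2")
    if control_mean < 0 or any(m < 0 for m in group_means.values()):
        raise SyntheticDataError("well means must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for group in group_means:
        for rep in range(1, n_reps + 1):
            rows.append(
                {
                    "group": group,
                    "replicate": rep,
                    "treated": group_means[group] + sd * rng.standard_normal(),
                    "control": control_mean + sd * rng.standard_normal(),
                }
            )
    return pd.DataFrame(rows)
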