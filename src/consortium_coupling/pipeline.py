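"""End-to-end orchestration of the consortium analysis.

``run_pipeline`` composes the stages in study order -- simulate (or
load) -> normalize -> filter -> responsive calls -> co-clustering ->
enrichment -> kinetics -> report -- and writes every intermediate
table plus a run manifest.  Reruns with an identical config and seed
produce byte-identical TSV/JSON payloads (the manifest carries the
only timestamp).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coexpression, enrichment, normalization, physiology, synthetic_data
from ._version import __version__
from .core_model import (
    CountMatrix,
    Design,
    GeneTable,
    IRRADIANCE_AXIS,
    PO2_AXIS,
    Species,
    load_counts,
    load_design,
    load_gene_table,
    validate_design,
)
from .synthetic_data import (
    CULTURE_AXENIC,
    CULTURE_BINARY,
    FacsTruth,
    KineticsParams,
    TruthConfig,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Single configuration object driving every stage."""

    simulate: bool = True
    gene_table_path: str | None = None
    counts_path: str | None = None
    design_path: str | None = None
    truth: TruthConfig = field(default_factory=TruthConfig)
    facs: FacsTruth = field(default_factory=FacsTruth)
    rpkm_variant: str = "scaled"
    library: str = "joint"
    min_rpkm: float = 15.0
    mask_fraction: float = 0.30
    responsive_threshold: float = 2.0
    pseudocount: float = 0.5
    k: int = 4
    n_init: int = 50
    facs_runs: int = 3
    facs_events: int = 50_000
    kinetics_duration_po2_h: float = 16.0
    kinetics_duration_light_h: float = 40.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        truth_raw = raw.pop("truth", {})
        if "planted_responsive" in truth_raw:
            truth_raw["planted_responsive"] = {
                tuple(k.split("/")): v
                for k, v in truth_raw["planted_responsive"].items()
            }
        facs_raw = raw.pop("facs", {})
        return cls(
            truth=TruthConfig(**truth_raw),
            facs=FacsTruth(**facs_raw),
            **raw,
        )

    def digest(self) -> str:
        def normalize(obj):
            if dataclasses.is_dataclass(obj):
                return {f.name: normalize(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, dict):
                return {str(k): normalize(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
            if isinstance(obj, (frozenset, set)):
                return sorted(map(str, obj))
            if isinstance(obj, (list, tuple)):
                return [normalize(v) for v in obj]
            return obj

        payload = json.dumps(normalize(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path, seed: int = 1) -> Path:
    """Execute the full analysis; returns the output directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool_version": __version__,
        "config_digest": config.digest(),
        "seed": seed,
        "inputs": {},
        "stage_rows": {},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    report: dict = {"tool_version": __version__, "seed": seed}

    # --- stage: simulate / load inputs -------------------------------------
    stage = "simulate" if config.simulate else "normalize"
    try:
        if config.simulate:
            genes = synthetic_data.make_genomes(config.truth, seed)
            design = synthetic_data.default_design(CULTURE_BINARY)
            counts, truth_df = synthetic_data.simulate_expression(
                genes, design, config.truth, seed, culture=CULTURE_BINARY
            )
            genes.save(out / "gene_table.tsv")
            design.save(out / "design.tsv")
            counts.save(out / "counts.tsv")
            truth_df.reset_index().to_csv(out / "truth.tsv", sep="\t", index=False)
        else:
            if not (
                config.gene_table_path
                and config.counts_path
                and config.design_path
            ):
                raise PipelineError(
                    "normalize", "gene_table_path, counts_path and design_path required"
                )
            genes = load_gene_table(config.gene_table_path)
            design = load_design(config.design_path)
            counts = load_counts(config.counts_path, genes, design)
        axes = validate_design(design)
        manifest["stage_rows"]["counts"] = len(counts.df)
        for name in ("gene_table.tsv", "counts.tsv", "design.tsv"):
            path = out / name
            if path.exists():
                manifest["inputs"][name] = _sha256(path)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- stage: normalize ---------------------------------------------------
    try:
        factors = normalization.size_factors(counts)
        expr = normalization.per_kb_expression(
            counts, factors, genes, variant=config.rpkm_variant, library=config.library
        )
        expr.save(out / "expression.tsv")
        manifest["stage_rows"]["expression"] = len(expr.df)
    except Exception as exc:
        raise PipelineError("normalize", str(exc)) from exc

    # --- stage: filter --------------------------------------------------------
    try:
        report_filter = normalization.filter_genes(
            counts, expr, design, min_expression=config.min_rpkm
        )
        (out / "filter_report.json").write_text(
            json.dumps(report_filter.to_dict(), indent=2) + "\n"
        )
        kept = list(report_filter.kept)
        manifest["stage_rows"]["filtered"] = len(kept)
        means = normalization.condition_means(expr, design).loc[kept]
    except Exception as exc:
        raise PipelineError("filter", str(exc)) from exc

    # --- stage: respond -------------------------------------------------------
    try:
        report["responsive"] = {}
        calls_by_axis = {}
        for axis in (axes.irradiance, axes.pO2):
            calls = coexpression.call_responsive(
                means,
                axis,
                threshold=config.responsive_threshold,
                pseudocount=config.pseudocount,
            )
            calls_by_axis[axis.name] = calls
            calls.rename_axis("gene_id").reset_index().to_csv(
                out / f"responsive_{axis.name}.tsv", sep="\t", index=False
            )
            summary = coexpression.responsive_summary(calls, genes)
            report["responsive"][axis.name] = {
                sp: {
                    "total": coexpression.count_responsive(calls, genes, species=sp),
                    **{
                        d: int(summary.loc[sp, d]) if sp in summary.index and d in summary.columns else 0
                        for d in ("up", "down")
                    },
                }
                for sp in ("cyanobacterium", "heterotroph")
            }
    except Exception as exc:
        raise PipelineError("respond", str(exc)) from exc

    # --- stage: cluster --------------------------------------------------------
    try:
        report["clusters"] = {}
        cluster_results = {}
        for axis in (axes.irradiance, axes.pO2):
            profiles = normalization.axis_profiles(means, axis)
            scaled = normalization.normalize_profile(profiles)
            kept_ids = normalization.variance_mask(scaled, config.mask_fraction)
            masked = scaled.values.loc[list(kept_ids)]
            result = coexpression.kmeans_correlation(
                normalization.axis_profiles(masked, axis),
                k=config.k,
                seed=seed,
                n_init=config.n_init,
            )
            cluster_results[axis.name] = result
            summary = coexpression.cross_species_summary(result, genes)
            assignments = result.assignments.rename_axis("gene_id").reset_index()
            assignments["pattern"] = assignments["cluster"].map(result.pattern_labels)
            assignments.to_csv(
                out / f"clusters_{axis.name}.tsv", sep="\t", index=False
            )
            pd.DataFrame(
                result.centroids, columns=list(axis.labels)
            ).rename_axis("cluster").reset_index().to_csv(
                out / f"centroids_{axis.name}.tsv", sep="\t", index=False
            )
            report["clusters"][axis.name] = {
                "k": result.k,
                "pattern_labels": {
                    str(c): lab for c, lab in result.pattern_labels.items()
                },
                "species_counts": {
                    str(c): {
                        "cyanobacterium": int(summary.loc[c, "cyanobacterium"]),
                        "heterotroph": int(summary.loc[c, "heterotroph"]),
                    }
                    for c in summary.index
                },
                "within_cluster_mean_correlation": round(
                    result.within_cluster_mean_correlation, 4
                ),
            }
    except Exception as exc:
        raise PipelineError("cluster", str(exc)) from exc

    # --- stage: enrich ----------------------------------------------------------
    try:
        report["top_enrichments"] = {}
        for axis_name, calls in calls_by_axis.items():
            for sp in ("cyanobacterium", "heterotroph"):
                ids = [
                    g
                    for g in calls.index[calls["responsive"]]
                    if genes.species_of(g).value == sp
                ]
                if len(ids) < 2:
                    continue
                table = enrichment.enrich_all(ids, genes)
                table.to_csv(
                    out / f"enrichment_{axis_name}_{sp}.tsv", sep="\t", index=False
                )
                top = table.iloc[0]
                report["top_enrichments"][f"{axis_name}/{sp}"] = {
                    "category": top["category"],
                    "ratio": round(float(top["ratio"]), 3),
                    "p_value": float(top["p_value"]),
                }
    except Exception as exc:
        raise PipelineError("enrich", str(exc)) from exc

    # --- stage: kinetics ---------------------------------------------------------
    try:
        report["kinetics"] = _kinetics_stage(config, axes, seed)
    except Exception as exc:
        raise PipelineError("kinetics", str(exc)) from exc

    # --- stage: facs / ros ---------------------------------------------------------
    try:
        gates = config.facs.default_gates()
        percents = []
        for i in range(config.facs_runs):
            events = synthetic_data.simulate_facs(
                config.facs, config.facs_events, seed + 1000 + i
            )
            comp = physiology.facs_composition(events, gates)
            percents.append(comp)
        report["facs"] = {
            "runs": config.facs_runs,
            "events_per_run": config.facs_events,
            "mean_percent": {
                name: round(float(np.mean([p[name] for p in percents])), 3)
                for name in list(gates) + ["ungated"]
            },
        }
        plate = synthetic_data.simulate_ros_plate(
            synthetic_data.default_ros_groups(), seed=seed + 2000
        )
        ros = physiology.ros_corrected(plate)
        report["ros"] = {
            "group_means": {
                g: round(float(ros.group_stats.loc[g, "mean"]), 2)
                for g in ros.group_stats.index
            },
            "significant_pairs": [
                f"{r.group_a} vs {r.group_b}"
                for r in ros.pairwise.itertuples()
                if r.significant
            ],
        }
    except Exception as exc:
        raise PipelineError("facs/ros", str(exc)) from exc

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    logger.info("pipeline complete: %s", out)
    return out


def _kinetics_stage(config: PipelineConfig, axes, seed: int) -> dict:
    """Simulated turbidostat physiology for both cultures."""
    gas = physiology.GasConfig()
    out: dict = {}
    for culture, params in (
        (CULTURE_AXENIC, KineticsParams.axenic()),
        (CULTURE_BINARY, KineticsParams.binary()),
    ):
        sens_points = []
        pq_points = []
        offset = 0 if culture == CULTURE_AXENIC else 100
        for i, cond in enumerate(axes.pO2.conditions):
            log = synthetic_data.simulate_turbidostat(
                params, cond, config.kinetics_duration_po2_h, seed + 3000 + offset + i
            )
            window = physiology.detect_steady_state(log)
            if window is None:
                raise PipelineError("kinetics", f"no steady state at {cond.label}")
            rate = physiology.growth_rate(log, window)
            sens_points.append((cond.pO2, rate.mu))
        for i, cond in enumerate(axes.irradiance.conditions):
            log = synthetic_data.simulate_turbidostat(
                params, cond, config.kinetics_duration_light_h, seed + 3500 + offset + i
            )
            window = physiology.detect_steady_state(log)
            if window is None:
                raise PipelineError("kinetics", f"no steady state at {cond.label}")
            rate = physiology.growth_rate(log, window)
            q = physiology.net_o2_rate(log, window, gas)
            pq_points.append((q, physiology.cmol_rate(rate.mu, gas)))
        fit = physiology.o2_sensitivity(sens_points)
        pq_slope, pq_se = physiology.photosynthetic_quotient(pq_points)
        mu_top = max(mu for _, mu in sens_points)
        out[culture] = {
            "sensitivity_h_per_atm": round(fit.slope_abs, 4),
            "sensitivity_se": round(fit.se, 4),
            "photosynthetic_quotient": round(pq_slope, 4),
            "pq_se": round(pq_se, 4),
            "mu_max_h": round(mu_top, 4),
            "doubling_time_h": round(float(np.log(2) / mu_top), 2),
        }
    max_po2 = max(c.pO2 for c in axes.pO2.conditions)
    out["gas"] = {
        "max_pO2_atm": max_po2,
        "dissolved_o2_uM": round(physiology.dissolved_o2(max_po2, gas)),
        "percent_air_saturation": round(physiology.percent_air_saturation(max_po2, gas)),
    }
    return out
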