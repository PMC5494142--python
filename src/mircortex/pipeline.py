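"""End-to-end pipeline: simulate -> preprocess -> associate -> network ->
integrate -> report.

:class:`PipelineConfig` holds every path, threshold and flag; it round-trips
through YAML unchanged. :func:`run_pipeline` executes the stages in order,
writes each stage's outputs, and emits a versioned JSON summary plus a
structured log recording every threshold and model formula used, so the
covariate handling of every fit can be audited.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as mio
from .association import associate_all, bonferroni_threshold, covariate_sensitivity
from .containers import COVARIATES
from .integration import (build_mir_pathways, decompose_pathway_effects,
                          rank_mir_pathways)
from .network import build_network, correlation_map, network_to_edge_table
from .preprocess import preprocess_mirna
from .simulate import (CohortParams, GroundTruth, MirnaParams, MrnaParams,
                       PlantedPathway, generate_cohort, generate_mirna_counts,
                       generate_mrna_and_annotations)

logger = logging.getLogger("mircortex")

SUMMARY_SCHEMA_VERSION = 1


def _json_default(o):
    import numpy as np
    if isinstance(o, np.integer):
        return int(o)
    if isinstance(o, np.floating):
        return float(o)
    if isinstance(o, np.bool_):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end run; serializes losslessly to YAML."""

    out_dir: str = "mircortex_out"
    seed: int = 0
    # synthetic cohort
    n_samples: int = 700
    n_features: int = 309
    planted_feature_index: int = 1      # 1-based; 0 disables planting
    planted_outcome: str = "ad"
    planted_variance: float = -0.067    # signed: negative = down with pathology
    plant_pathway: bool = True
    pathway_coupling: float = -0.5
    pathway_direct_beta: float = 0.15
    # preprocessing thresholds
    call_rate: float = 0.95
    min_count: float = 15.0
    low_expression_fraction: float = 0.5
    lincrna_min_expected: float = 5.0
    log2_transform: bool = True
    run_combat: bool = True
    # association
    bonferroni_alpha: float = 0.05
    paper_mimic_threshold: float | None = None   # e.g. 0.00016 overrides per-class
    # network
    screen_alpha: float = 0.05
    # integration
    min_mir_pathway_size: int = 3
    opposite_direction: bool = True
    top_k: int = 8

    def validate(self) -> None:
        if not 0.0 < self.call_rate <= 1.0:
            raise ValueError("call_rate outside (0, 1]")
        if self.min_count < 0 or self.lincrna_min_expected < 0:
            raise ValueError("count floors must be non-negative")
        if not 0.0 < self.low_expression_fraction <= 1.0:
            raise ValueError("low_expression_fraction outside (0, 1]")
        for name in ("bonferroni_alpha", "screen_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} outside (0, 1)")
        if not abs(self.planted_variance) < 1.0:
            raise ValueError("planted_variance magnitude must be < 1")

    # -- serialization ----------------------------------------------------
    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class PipelineResult:
    """In-memory handles to every stage output of one run."""

    cohort: pd.DataFrame
    truth: GroundTruth
    processed: object
    filter_report: object
    associations: pd.DataFrame
    sensitivity: pd.DataFrame
    network: object
    edge_table: pd.DataFrame
    mir_pathway_table: pd.DataFrame | None
    decomposition: pd.DataFrame | None
    summary: dict = field(default_factory=dict)


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with stage provenance."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return False
    return _Ctx()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage in order and write all outputs under out_dir."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    summary: dict = {"schema_version": SUMMARY_SCHEMA_VERSION,
                     "seed": config.seed, "thresholds": {
                         "call_rate": config.call_rate,
                         "min_count": config.min_count,
                         "low_expression_fraction": config.low_expression_fraction,
                         "lincrna_min_expected": config.lincrna_min_expected,
                         "screen_alpha": config.screen_alpha,
                         "bonferroni_alpha": config.bonferroni_alpha,
                         "paper_mimic_threshold": config.paper_mimic_threshold}}
    try:
        with _stage("simulate"):
            truth = GroundTruth(seed=config.seed)
            planted_id = None
            if config.planted_feature_index:
                planted_id = f"miR-synth-{config.planted_feature_index:04d}"
                truth.effects[planted_id] = (config.planted_outcome,
                                             config.planted_variance)
            if config.plant_pathway and planted_id is not None:
                truth.planted_pathway = PlantedPathway(
                    mirna_id=planted_id, coupling=config.pathway_coupling,
                    direct_beta=config.pathway_direct_beta,
                    outcome=config.planted_outcome)
            cohort = generate_cohort(config.n_samples, config.seed, CohortParams())
            raw, background = generate_mirna_counts(
                cohort, truth, config.n_features, config.seed, MirnaParams())
            mrna = target_table = pathways = None
            if config.plant_pathway and planted_id is not None:
                mrna, target_table, pathways = generate_mrna_and_annotations(
                    cohort, raw, truth, config.seed, MrnaParams())
            mio.write_cohort_csv(cohort, out / "cohort.csv")
            mio.write_expression_tsv(raw, out / "mirna_raw.tsv")
            background.to_csv(out / "background.tsv", sep="\t",
                              header=["background"])
            mio.write_ground_truth(truth, out / "ground_truth.json")
            summary["simulate"] = {"n_samples": int(len(cohort)),
                                   "n_features": int(raw.n_features),
                                   "frac_ad": float(cohort["ad"].mean())}

        with _stage("preprocess"):
            processed, report = preprocess_mirna(
                raw, background, call_rate=config.call_rate,
                min_value=config.min_count,
                low_frac=config.low_expression_fraction,
                log2=config.log2_transform, run_combat=config.run_combat)
            mio.write_expression_tsv(processed, out / "mirna_processed.tsv")
            (out / "filter_report.json").write_text(
                json.dumps(report.to_dict(), indent=2))
            summary["preprocess"] = {
                "features_retained": int(processed.n_features),
                "samples_retained": int(processed.n_samples),
                "steps": [{"name": s.name, "n_before": s.n_before,
                           "n_after": s.n_after} for s in report.steps]}

        with _stage("associate"):
            logger.info("model: expression ~ outcome + %s",
                        " + ".join(COVARIATES))
            assoc = associate_all(
                processed, cohort, alpha=config.bonferroni_alpha,
                fixed_threshold=config.paper_mimic_threshold)
            assoc.to_csv(out / "associations.tsv", sep="\t", index=False)
            sens = covariate_sensitivity(processed, cohort)
            sens.to_csv(out / "sensitivity.tsv", sep="\t")
            thr = assoc.attrs["bonferroni_threshold"]
            summary["associate"] = {
                "bonferroni_threshold": float(thr),
                "significant_per_outcome": {
                    oc: int(assoc.query("outcome == @oc")["significant"].sum())
                    for oc in ("np", "nft", "ad")}}

        with _stage("network"):
            net = build_network(processed, cohort,
                                screen_alpha=config.screen_alpha)
            edges = network_to_edge_table(net)
            edges.to_csv(out / "network_edges.tsv", sep="\t", index=False)
            import networkx as nx
            nx.write_graphml(net, out / "network.graphml")
            n_feat_nodes = sum(1 for _, d in net.nodes(data=True)
                               if d.get("kind") == "feature")
            summary["network"] = {"n_feature_nodes": int(n_feat_nodes),
                                  "n_edges": int(net.number_of_edges()),
                                  "edges": edges.to_dict(orient="records")}
            sig = [n for n, d in net.nodes(data=True)
                   if d.get("kind") == "feature"]
            if len(sig) >= 2:
                corr = correlation_map(processed, cohort, sorted(sig))
                corr.to_csv(out / "correlation_map.tsv", sep="\t")

        mir_table = decomp = None
        if config.plant_pathway and planted_id is not None:
            with _stage("integrate"):
                mio.write_expression_tsv(mrna, out / "mrna.tsv")
                mio.write_target_table(target_table, out / "targets.tsv")
                mio.write_gmt(pathways, out / "pathways.gmt")
                gene_assoc = associate_all(mrna, cohort, outcomes=("ad",))
                mir_pairs = build_mir_pathways(
                    target_table, pathways, min_size=config.min_mir_pathway_size)
                mir_table = rank_mir_pathways(
                    assoc, gene_assoc, mir_pairs,
                    opposite_direction=config.opposite_direction)
                export = mir_table.head(config.top_k).copy()
                export["genes"] = export["genes"].map(lambda g: ";".join(g))
                export.to_csv(out / "mir_pathways.tsv", sep="\t", index=False)
                pp = truth.planted_pathway
                decomp = decompose_pathway_effects(
                    mrna, processed, cohort, pp.genes, pp.mirna_id
                ) if pp.mirna_id in processed.feature_ids else None
                if decomp is not None:
                    decomp.to_csv(out / "decomposition.tsv", sep="\t",
                                  index=False)
                summary["integrate"] = {
                    "n_mir_pathways": int(len(mir_table)),
                    "top": export[["mirna_id", "pathways", "direction",
                                   "joint_score"]].to_dict(orient="records")}

        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True,
                       default=_json_default) + "\n")
        return PipelineResult(
            cohort=cohort, truth=truth, processed=processed,
            filter_report=report, associations=assoc, sensitivity=sens,
            network=net, edge_table=edges, mir_pathway_table=mir_table,
            decomposition=decomp, summary=summary)
    finally:
        logger.removeHandler(handler)
        handler.close()
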