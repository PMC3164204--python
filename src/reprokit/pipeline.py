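"""End-to-end orchestration from one YAML configuration.

Runs normalize -> detection calls -> differential expression (all
contrasts vs donor) -> regulation profiles -> gene-set dynamics ->
fuzzy c-means clustering -> EMT-suppression signature -> interaction
network build/score/classify, writing one TSV per stage plus a JSON run
manifest.  Identical config + seed produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, clustering, emt, io
from .expression import (CONTRAST_ORDER, DONOR_GROUP, call_detection,
                         differential_expression, normalize, pca_projection,
                         regulation_profile)
from .genesets import activation_timecourse, derive_associated_sets
from .network import (InteractionNetwork, build_subnetwork, classify_nodes,
                      paths_through, score_nodes)
from .synthetic import simulate_emt_timecourse, simulate_network

logger = logging.getLogger(__name__)

DEFAULT_PLANTED_PATHS = (
    ("POU5F1", "FRAT2", "GSK3B", "MYCN"),
    ("KLF4", "CREBBP", "GLI3", "ZIC3"),
)


@dataclass
class RunConfig:
    """Thresholds and inputs of a pipeline run.

    Exactly one of ``synthetic`` (generator keyword arguments) or
    ``inputs`` (paths: expression, samples, network, roles) must be set.
    Threshold defaults are the analysis' canonical values: detection
    p < 0.01, p_adj < 0.05, fold change 1.5, fuzzifier 1.7, alpha-core
    0.5, 10 recovery bins, 0.75 high-score quantile.
    """

    outdir: str = "reprokit_run"
    rng_seed: int = 0
    detection_threshold: float = 0.01
    p_adj_threshold: float = 0.05
    fold_change: float = 1.5
    fuzzifier: float = 1.7
    alpha_core: float = 0.5
    n_clusters: int = 9
    n_bins: int = 10
    high_quantile: float = 0.75
    prior_df: float | None = None
    log_transform_input: bool = True
    synthetic: dict | None = None
    inputs: dict | None = None
    via_node: str = "GSK3B"

    def __post_init__(self) -> None:
        checks = [
            (0 < self.detection_threshold < 1, "detection_threshold in (0,1)"),
            (0 < self.p_adj_threshold < 1, "p_adj_threshold in (0,1)"),
            (self.fold_change > 1, "fold_change > 1"),
            (self.fuzzifier > 1, "fuzzifier > 1"),
            (0 <= self.alpha_core <= 1, "alpha_core in [0,1]"),
            (self.n_bins >= 2, "n_bins >= 2"),
            (0 <= self.high_quantile <= 1, "high_quantile in [0,1]"),
            (self.n_clusters >= 2, "n_clusters >= 2"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid config: expected {msg}")
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError("exactly one of synthetic | inputs must be set")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)


def _load_inputs(cfg: RunConfig):
    paths = cfg.inputs
    for key in ("expression", "samples"):
        if key not in paths or not Path(paths[key]).exists():
            raise FileNotFoundError(f"missing input file for {key!r}: {paths.get(key)}")
    groups = io.read_sample_map(paths["samples"])
    matrix = io.read_expression_tsv(paths["expression"], groups)
    net = None
    if "network" in paths:
        edges = io.read_sif(paths["network"])
        roles = io.read_roles(paths["roles"]) if "roles" in paths else {}
        net = InteractionNetwork.from_edges(edges, roles)
    return matrix, None, None, None, net


def _synthesize(cfg: RunConfig):
    kwargs = dict(cfg.synthetic or {})
    net_kwargs = kwargs.pop("network", {})
    kwargs.setdefault("rng_seed", cfg.rng_seed)
    kwargs.setdefault("pluri_on_genes", 100)
    kwargs.setdefault("fibro_off_genes", 100)
    scenario = simulate_emt_timecourse(**kwargs)
    net = simulate_network(
        n_nodes=net_kwargs.get("n_nodes", 30),
        edge_prob=net_kwargs.get("edge_prob", 0.05),
        sources=net_kwargs.get("sources", ["POU5F1", "KLF4"]),
        sinks=net_kwargs.get("sinks", ["MYCN", "ZIC3"]),
        planted_paths=net_kwargs.get("planted_paths", [list(p) for p in DEFAULT_PLANTED_PATHS]),
        rng_seed=net_kwargs.get("rng_seed", cfg.rng_seed + 1),
    )
    return scenario.matrix, scenario.truth, scenario.compendium, scenario.seeds, net


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle to ``outdir``.

    Returns the manifest dictionary (also written as ``manifest.json``).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    if config.synthetic is not None:
        matrix, truth, compendium, seeds, net = _synthesize(config)
        log_input = False
    else:
        matrix, truth, compendium, seeds, net = _load_inputs(config)
        log_input = config.log_transform_input

    matrix = normalize(matrix.intensities, matrix.groups,
                       detection_p=matrix.detection_p, log_transform=log_input)
    io.write_expression_tsv(matrix, out / "expression_normalized.tsv")
    io.write_sample_map(matrix.groups, out / "samples.tsv")
    counts["probes"] = len(matrix.probe_ids)
    counts["samples"] = len(matrix.samples)

    calls = call_detection(matrix)
    counts["analysis_set"] = len(calls.analysis_set)
    logger.info("detection filter kept %d/%d probes", counts["analysis_set"],
                counts["probes"])
    pd.Series(calls.analysis_set).to_csv(out / "analysis_set.tsv", sep="\t",
                                         index=False, header=["probe_id"])

    pca = pca_projection(matrix)
    pca.to_csv(out / "pca_projection.tsv", sep="\t", index_label="sample")

    contrasts = [g for g in matrix.group_labels() if g != DONOR_GROUP]
    de_results = {
        c: differential_expression(matrix, calls, c, prior_df=config.prior_df)
        for c in contrasts
    }
    for c, df in de_results.items():
        counts[f"regulated_{c}"] = int(df["regulated"].sum())
        logger.info("contrast %s: %d regulated probes", c, counts[f"regulated_{c}"])
    order = tuple(c for c in CONTRAST_ORDER if c in de_results) or tuple(contrasts)
    profiles = regulation_profile(de_results, order=order)
    combined = pd.DataFrame({"profile.id": profiles})
    for c in order:
        combined[f"{c}.logFC"] = de_results[c]["log2fc"]
        combined[f"{c}.p_adj"] = de_results[c]["p_adj"]
    combined.to_csv(out / "differential_expression.tsv", sep="\t",
                    index_label="pid", float_format="%.6g")

    partition = derive_associated_sets(calls)
    counts["pluripotency_associated"] = len(partition.pluripotency_associated)
    counts["fibroblast_associated"] = len(partition.fibroblast_associated)
    io.write_gmt({
        "PLURIPOTENCY_ASSOCIATED": list(partition.pluripotency_associated),
        "FIBROBLAST_ASSOCIATED": list(partition.fibroblast_associated),
    }, out / "associated_sets.gmt", description="presence-derived")
    timecourse = activation_timecourse(calls, partition)
    timecourse.to_csv(out / "activation_timecourse.tsv", sep="\t",
                      index_label="group", float_format="%.6g")

    regulated_any = combined.index[profiles.str.contains("1")]
    logfc_table = pd.DataFrame({c: de_results[c]["log2fc"] for c in order}).loc[regulated_any]
    counts["clustered_probes"] = len(logfc_table)
    if len(logfc_table) > config.n_clusters:
        fcm = clustering.fuzzy_cmeans(logfc_table, c=config.n_clusters,
                                      m=config.fuzzifier, rng_seed=config.rng_seed)
        assignment = clustering.alpha_core(fcm, alpha=config.alpha_core)
        assignment.to_csv(out / "clusters.tsv", sep="\t", index_label="probe",
                          float_format="%.6g")
    else:
        logger.warning("too few regulated probes (%d) to cluster", len(logfc_table))

    if compendium is not None:
        ranked = emt.seed_rank(compendium, seeds)
        ranked.to_csv(out / "emt_ranked.tsv", sep="\t", index_label="gene",
                      float_format="%.6g")
        recovery = emt.recovery_test(compendium, seeds, n_bins=config.n_bins,
                                     rng_seed=config.rng_seed)
        with open(out / "emt_recovery.json", "w") as fh:
            json.dump({"bin_counts": recovery.bin_counts.tolist(),
                       "n_draws": recovery.n_draws,
                       "p_value": recovery.p_value}, fh, indent=2)
        table = emt.signature_table(ranked, de_results, order)
        table.to_csv(out / "emt_signature.tsv", sep="\t", float_format="%.6g")
        counts["emt_universe"] = len(ranked)

    if net is not None:
        sub = build_subnetwork(net)
        scores = classify_nodes(score_nodes(net), high_quantile=config.high_quantile)
        scores.to_csv(out / "node_scores.tsv", sep="\t", float_format="%.6g")
        sub.to_graphml(out / "subnetwork.graphml", node_attrs=scores)
        counts["subnetwork_nodes"] = len(sub.nodes)
        if config.via_node in net.nodes:
            hits = paths_through(net, via=config.via_node)
            with open(out / "paths_via.tsv", "w") as fh:
                fh.write("path\n")
                for p in hits:
                    fh.write("->".join(p) + "\n")
            counts["paths_via"] = len(hits)

    manifest = {
        "package_version": __version__,
        "rng_seed": config.rng_seed,
        "config": {k: v for k, v in asdict(config).items() if k != "outdir"},
        "counts": counts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
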