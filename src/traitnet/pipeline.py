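"""End-to-end orchestration: simulate/ingest through the full analysis.

``run_pipeline`` chains every stage — normalization, imputation, variance
components and BLUPs, Spearman correlation, threshold calibration, network
construction, walktrap communities with significance testing and merging,
permutation-tested node statistics, and Pearson edge validation — persisting
each intermediate artifact and a JSON report. Identical config and seed give
an identical report.

``analyze_blup_table`` enters the same chain at the BLUP stage, for
re-analysis of an externally computed line x feature table.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community as community_mod
from . import io as io_mod
from . import network as network_mod
from . import nodestats as nodestats_mod
from . import preprocess as preprocess_mod
from .containers import BlupMatrix, ReplicateProfileTable
from .simulate import (
    SimulationConfig,
    config_from_dict,
    config_to_dict,
    generate_panel,
    truth_report,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs; round-trips through YAML."""

    simulation: SimulationConfig | None = None
    data_path: str | None = None
    annotation_path: str | None = None
    outdir: str = "traitnet_out"
    plate_method: str = "divide"
    impute_components: int = 3
    q_target: float = 0.05
    p_grid: tuple = network_mod.DEFAULT_P_GRID
    r_candidates: tuple = network_mod.DEFAULT_R_CANDIDATES
    stability_tolerance: float = 0.01
    diameter_tolerance: int = 0
    walktrap_steps: int = 4
    alpha: float = 0.05
    n_permutations: int = 10_000
    permutation_mode: str = "profiles"
    top_k: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.simulation is None and self.data_path is None:
            raise ValueError("config needs either a simulation or a data_path")
        if not 0 < self.q_target < 1:
            raise ValueError("q_target must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = config_to_dict(self.simulation)
        d["p_grid"] = list(map(float, self.p_grid))
        d["r_candidates"] = list(map(float, self.r_candidates))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", None)
        if sim is not None:
            sim = config_from_dict(sim)
        if "p_grid" in d:
            d["p_grid"] = tuple(d["p_grid"])
        if "r_candidates" in d:
            d["r_candidates"] = tuple(d["r_candidates"])
        return cls(simulation=sim, **d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class AnalysisReport:
    """Machine-readable run summary; every number is recomputable from the
    persisted intermediates."""

    payload: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        io_mod.write_json(self.payload, path)


def _stage(name: str):
    logger.info("stage: %s", name)


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Execute the full analysis; persist artifacts under ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "resolved_config.yaml")

    _stage("ingest")
    if config.simulation is not None:
        table, truth = generate_panel(config.simulation)
        io_mod.write_table(table, outdir / "raw_table.tsv",
                           outdir / "annotations.tsv")
        io_mod.write_json(truth_report(truth), outdir / "planted_truth.json")
    else:
        table = io_mod.read_table(config.data_path, config.annotation_path)
        truth = None
    table.validate()

    _stage("normalize")
    normalized = preprocess_mod.normalize_panel(table, config.plate_method)
    n_missing = normalized.n_missing
    logger.info("normalized matrix: %s samples x %s features, %d missing cells",
                *normalized.values.shape, n_missing)

    _stage("impute")
    if n_missing == 0:
        logger.info("imputation skipped: no missing cells")
        completed = normalized
        imputation_skipped = True
    else:
        completed = preprocess_mod.impute_missing(
            normalized, n_components=config.impute_components, seed=config.seed
        )
        imputation_skipped = False
    io_mod.write_normalized(completed, outdir / "normalized.tsv",
                            outdir / "provenance.tsv")

    _stage("variance components")
    components = preprocess_mod.fit_variance_components(completed)
    components.table.to_csv(outdir / "variance_components.tsv", sep="\t")

    _stage("BLUP")
    blups = preprocess_mod.compute_blups(completed, components)
    io_mod.write_blups(blups, outdir / "blups.tsv", outdir / "grand_means.tsv")

    _stage("descriptive statistics")
    desc = preprocess_mod.descriptive_stats(blups, components)
    desc.table.to_csv(outdir / "descriptive_stats.tsv", sep="\t")

    report = _analyze(blups, config, outdir, annotations=table.annotations)
    payload = report.payload
    payload["preprocessing"] = {
        "n_lines": int(blups.values.shape[0]),
        "n_features": int(blups.values.shape[1]),
        "n_missing_cells": int(n_missing),
        "missing_fraction": float(n_missing / completed.values.size),
        "imputation_skipped": imputation_skipped,
        "n_degenerate_features": len(components.degenerate_features()),
    }
    payload["heritability"] = {
        "h2_bin_counts": {k: int(v) for k, v in desc.h2_bin_counts.items()},
        "h2_bin_frequencies": {
            k: float(v) for k, v in desc.h2_bin_frequencies.items()
        },
        "fraction_below_0.5": float((components.h2.dropna() < 0.5).mean()),
        "max_h2": float(components.h2.max()),
    }
    cvs = desc.table.dropna(subset=["cv"])
    mets = cvs.index.intersection(table.features_of_class("metabolite"))
    enzs = cvs.index.intersection(table.features_of_class("enzyme"))
    payload["cv"] = {
        "metabolite_median_cv": float(cvs.loc[mets, "cv"].median()) if len(mets) else None,
        "enzyme_median_cv": float(cvs.loc[enzs, "cv"].median()) if len(enzs) else None,
    }
    report.to_json(outdir / "report.json")
    return report


def analyze_blup_table(
    blups: BlupMatrix,
    config: PipelineConfig,
    outdir=None,
    r_cutoff: float | None = None,
) -> AnalysisReport:
    """Run the network stages on an existing line x feature BLUP table.

    ``r_cutoff`` overrides stability calibration (for re-analyses where the
    cutoff is fixed a priori); the p-cutoff always comes from the BH
    step-up at ``config.q_target``.
    """
    outdir = Path(outdir) if outdir is not None else Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = _analyze(blups, config, outdir, annotations=blups.annotations,
                      r_cutoff_override=r_cutoff)
    report.to_json(outdir / "report.json")
    return report


def _analyze(
    blups: BlupMatrix,
    config: PipelineConfig,
    outdir: Path,
    annotations: pd.DataFrame | None,
    r_cutoff_override: float | None = None,
) -> AnalysisReport:
    _stage("correlation")
    corr = network_mod.spearman_all_pairs(blups)
    io_mod.write_matrix(corr.rho, outdir / "spearman_rho.tsv")
    io_mod.write_matrix(corr.p, outdir / "spearman_p.tsv")
    io_mod.write_matrix(corr.q, outdir / "spearman_q.tsv")
    corr.pair_table().to_csv(outdir / "correlation_pairs.tsv", sep="\t",
                             index=False)

    _stage("threshold calibration")
    iu = np.triu_indices(len(corr.features), k=1)
    p_cutoff = network_mod.bh_threshold(corr.p.to_numpy()[iu],
                                        q_target=config.q_target)
    if r_cutoff_override is not None:
        r_cutoff = float(r_cutoff_override)
        calibration = None
    else:
        calibration = network_mod.select_r_cutoff(
            corr,
            p_grid=config.p_grid,
            candidates=config.r_candidates,
            tolerance=config.stability_tolerance,
            diameter_tolerance=config.diameter_tolerance,
            q_target=config.q_target,
        )
        r_cutoff = calibration.r_cutoff
        p_cutoff = calibration.p_cutoff
        calibration.scan.to_csv(outdir / "stability_scan.tsv", sep="\t",
                                index=False)
    if p_cutoff <= 0:
        raise RuntimeError(
            "network construction: BH step-up rejects nothing at "
            f"q={config.q_target}; no edges can be called significant"
        )

    _stage("network construction")
    G = network_mod.build_network(corr, r_cutoff, p_cutoff, annotations)
    props = network_mod.network_properties(G)
    logger.info("network: %d nodes, %d edges", props.n_nodes, props.n_edges)

    _stage("communities")
    if G.number_of_nodes() > 0:
        partition = community_mod.walktrap(G, steps=config.walktrap_steps)
        tested = community_mod.attach_significance(G, partition)
        merged = community_mod.merge_communities(G, tested, alpha=config.alpha)
    else:
        partition = tested = merged = community_mod.CommunityPartition({})

    _stage("node statistics")
    perm = nodestats_mod.permutation_test(
        blups,
        r_cutoff,
        p_cutoff,
        n_iter=config.n_permutations,
        seed=config.seed,
        mode=config.permutation_mode,
    )
    stats_nodes = perm.table.loc[perm.table.index.intersection(G.nodes)]
    node_table = stats_nodes.copy()
    node_table["community"] = pd.Series(
        {n: tested.assignment.get(n) for n in node_table.index}
    )
    node_table["merged_community"] = pd.Series(
        {n: merged.assignment.get(n) for n in node_table.index}
    )
    node_table.to_csv(outdir / "node_stats.tsv", sep="\t")

    _stage("edge validation")
    validation = nodestats_mod.edge_validation(blups, G)
    validation.table.to_csv(outdir / "edge_validation.tsv", sep="\t", index=False)

    _stage("export")
    for n in G.nodes:
        G.nodes[n]["community"] = int(tested.assignment.get(n, -1))
        G.nodes[n]["merged_community"] = int(merged.assignment.get(n, -1))
        G.nodes[n]["degree"] = int(G.degree(n))
        G.nodes[n]["betweenness"] = float(
            node_table.loc[n, "betweenness"]
        ) if n in node_table.index else 0.0
    io_mod.export_network(G, outdir, stem="network")
    _write_partition_tsv(merged, tested, outdir / "communities.tsv")

    mol_class = {}
    if annotations is not None:
        mol_class = annotations["molecular_class"].to_dict()
    n_met = sum(1 for n in G.nodes if mol_class.get(n) == "metabolite")
    n_enz = sum(1 for n in G.nodes if mol_class.get(n) == "enzyme")

    def _top(col: str, pcol: str) -> list[dict]:
        top = node_table.sort_values(col, ascending=False).head(config.top_k)
        return [
            {
                "feature": idx,
                col: float(row[col]),
                "p": float(row[pcol]),
            }
            for idx, row in top.iterrows()
        ]

    payload = {
        "thresholds": {
            "r_cutoff": float(r_cutoff),
            "p_cutoff": float(p_cutoff),
            "q_target": float(config.q_target),
            "calibrated": calibration is not None,
        },
        "network": {
            **props.as_dict(),
            "n_metabolite_nodes": n_met,
            "n_enzyme_nodes": n_enz,
            "max_degree": int(max((d for _, d in G.degree), default=0)),
            "average_betweenness": float(node_table["betweenness"].mean())
            if len(node_table) else None,
            "max_betweenness": float(node_table["betweenness"].max())
            if len(node_table) else None,
        },
        "communities": {
            "initial": {
                "count": len(tested.communities),
                "sizes": {str(c): s for c, s in tested.sizes.items()},
                "p_values": {
                    str(c): (None if p is community_mod.NOT_TESTED else float(p))
                    for c, p in tested.p_values.items()
                },
            },
            "merged": {
                "count": len(merged.communities),
                "sizes": {str(c): s for c, s in merged.sizes.items()},
                "p_values": {
                    str(c): (None if p is community_mod.NOT_TESTED else float(p))
                    for c, p in merged.p_values.items()
                },
                "merged_from": {
                    str(c): list(map(int, origins))
                    for c, origins in merged.merged_from.items()
                },
                "unmerged": list(map(int, merged.unmerged)),
            },
        },
        "node_statistics": {
            "n_permutations": int(config.n_permutations),
            "top_degree": _top("degree", "p_degree"),
            "top_betweenness": _top("betweenness", "p_betweenness"),
        },
        "edge_validation": {
            "abs_r_bins": {k: int(v) for k, v in validation.abs_r_counts.items()},
            "shared_variance_bins": {
                k: int(v) for k, v in validation.shared_variance_counts.items()
            },
        },
    }
    return AnalysisReport(payload)


def _write_partition_tsv(merged, tested, path) -> None:
    rows = []
    for node in sorted(tested.assignment):
        cid = tested.assignment[node]
        mid = merged.assignment.get(node)
        p = merged.p_values.get(mid)
        rows.append(
            {
                "feature_id": node,
                "community_id": cid,
                "merged_community_id": mid,
                "community_p_value": "" if p is community_mod.NOT_TESTED else p,
            }
        )
    pd.DataFrame(rows, columns=[
        "feature_id", "community_id", "merged_community_id", "community_p_value"
    ]).to_csv(path, sep="\t", index=False)
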