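"""End-to-end orchestration: simulate -> associate -> score -> search -> enrich.

Each stage writes its outputs into the run directory and a manifest records
the configuration, seed, package version and a checksum per output file, so
identical (config, seed) reruns are byte-identical and verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import replace
from pathlib import Path

import pandas as pd

from . import __version__
from .association import ModelSpec, fit_incident, fit_medication, fit_prevalent
from .config import PipelineConfig
from .enrichment import enrich
from .io import (write_expression, write_gene_sets, write_network,
                 write_phenotypes, write_results)
from .modules import modules_table, search_all, select_and_merge
from .scoring import build_score_map
from .simulate import simulate_cohort, simulate_gene_sets, simulate_network

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in order and return the manifest dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_cfg = replace(config.simulation, seed=config.seed)
    outputs = {}

    def emit(name: str, writer, obj) -> Path:
        path = outdir / name
        writer(obj, path)
        outputs[name] = path
        return path

    expression = samples = network = None
    signal_genes = planted = gene_sets = None
    scores = None
    subnetwork = None

    stages = list(config.stages)
    for stage in stages:
        logger.info("stage: %s", stage)
        if stage == "simulate":
            expression, samples, signal_genes = simulate_cohort(sim_cfg)
            network, planted = simulate_network(sim_cfg, signal_genes)
            gene_sets = simulate_gene_sets(sim_cfg, planted)
            emit("expression.tsv", write_expression, expression)
            emit("phenotypes.csv", write_phenotypes, samples)
            emit("network.tsv", write_network, network)
            emit("gene_sets.gmt", write_gene_sets, gene_sets)
            (outdir / "truth_signal_genes.txt").write_text("\n".join(signal_genes) + "\n")
            (outdir / "truth_planted_module.txt").write_text("\n".join(planted) + "\n")
            outputs["truth_signal_genes.txt"] = outdir / "truth_signal_genes.txt"
            outputs["truth_planted_module.txt"] = outdir / "truth_planted_module.txt"
        elif stage == "assoc":
            if expression is None:
                raise RuntimeError("assoc stage requires the simulate stage's outputs")
            spec = ModelSpec(exposure="prevalent_af", covariate_set=config.covariate_set)
            results = fit_prevalent(expression, samples, spec)
            results = results.sort_values(["p", "feature_id"], kind="mergesort")
            emit("association_prevalent.tsv", write_results, results)
            outputs["_assoc"] = results
        elif stage == "score":
            results = outputs.get("_assoc")
            if results is None:
                raise RuntimeError("score stage requires the assoc stage")
            scores = build_score_map(results, network)
            score_df = pd.DataFrame(sorted(scores.items()), columns=["gene_id", "z"])
            emit("gene_scores.tsv",
                 lambda df, p: df.to_csv(p, sep="\t", index=False, float_format="%.15g"),
                 score_df)
        elif stage == "modules":
            if scores is None:
                raise RuntimeError("modules stage requires the score stage")
            search_graph = network.subgraph(scores.keys())
            mods = search_all(search_graph, scores)
            subnetwork, selected = select_and_merge(mods, config.top_fraction, search_graph)
            emit("modules.tsv",
                 lambda df, p: df.to_csv(p, sep="\t", index=False, float_format="%.15g"),
                 modules_table(mods))
            emit("subnetwork_edges.tsv", write_network, subnetwork)
            node_df = pd.DataFrame(
                {"gene_id": sorted(subnetwork.nodes)},
            )
            node_df["z"] = node_df["gene_id"].map(scores)
            node_df["degree"] = node_df["gene_id"].map(dict(subnetwork.degree))
            emit("subnetwork_nodes.tsv",
                 lambda df, p: df.to_csv(p, sep="\t", index=False, float_format="%.15g"),
                 node_df)
            outputs["_subnetwork"] = subnetwork
            outputs["_n_modules"] = len(mods)
        elif stage == "enrich":
            if subnetwork is None:
                raise RuntimeError("enrich stage requires the modules stage")
            table = enrich(subnetwork.nodes, gene_sets, scores.keys())
            emit("enrichment.tsv",
                 lambda df, p: df.to_csv(p, sep="\t", index=False, float_format="%.15g"),
                 table)
        else:
            raise RuntimeError(f"unknown stage {stage!r}")

    manifest = {
        "afnet_version": __version__,
        "seed": config.seed,
        "covariate_set": config.covariate_set,
        "top_fraction": config.top_fraction,
        "fdr_threshold": config.fdr_threshold,
        "simulation": sim_cfg.to_dict(),
        "stages": stages,
        "outputs": {
            name: _sha256(path)
            for name, path in outputs.items()
            if isinstance(path, Path)
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
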