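#!/usr/bin/env python
"""Pathway enrichment of the AF subnetwork.

Hypergeometric over-representation of subnetwork genes in each gene set,
with the scored network genes as the universe and BH-FDR across sets.

Reads results/subnetwork_nodes.tsv and scratch/synthetic_data/gene_sets.gmt,
writes results/enrichment.tsv.
"""

from pathlib import Path

import pandas as pd

from afnet import io as afio
from afnet.enrichment import enrich

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = ROOT.parent / "scratch" / "synthetic_data"


def main() -> None:
    nodes = pd.read_csv(ROOT / "subnetwork_nodes.tsv", sep="\t")["gene_id"]
    results = afio.read_results(ROOT / "association_prevalent.tsv")
    network = afio.read_edge_list(DATA / "network.tsv")
    universe = sorted(set(results["feature_id"]) & set(network.nodes))
    sets = afio.read_gene_sets(DATA / "gene_sets.gmt")

    table = enrich(nodes, sets, universe)
    table.to_csv(ROOT / "enrichment.tsv", sep="\t", index=False,
                 float_format="%.15g")

    top = table.iloc[0]
    n_sig = int((table["q"] < 0.05).sum())
    print(f"{len(table)} gene sets tested against a universe of {len(universe)} "
          f"network genes; {n_sig} enriched at FDR<0.05")
    print(f"top set: {top['set_name']}  overlap {top['ratio_str']}  "
          f"q = {top['q']:.2e}")
    print(f"overlap genes: {top['overlap_genes']}")


if __name__ == "__main__":
    main()
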