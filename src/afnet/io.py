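"""Readers and writers for the formats the pipeline touches.

Expression TSV (features x samples), phenotype CSV, edge-list TSV / SIF
networks, GMT gene sets, and the association / enrichment result tables.
All readers validate strictly and fail loudly; every writer/reader pair is
an identity on validated objects.  Gene identifiers are opaque strings;
mapping array probesets to gene symbols is the caller's responsibility
(see :func:`collapse_features`).
"""

from __future__ import annotations

import logging
from typing import Dict, List, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .simulate import AF_GROUPS, COVARIATE_COLUMNS, MEDICATION_COLUMNS

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ["feature_id", "effect", "se", "p", "q"]

MANDATORY_PHENOTYPE_COLUMNS = [
    "sample_id", "pedigree_id", "af_group", "age", "sex",
    "followup_time", "event",
]


class ParseError(ValueError):
    """Malformed or invalid input file."""


# ---------------------------------------------------------------- expression

def read_expression(path) -> pd.DataFrame:
    """Read a features-x-samples TSV of log2 intensities.

    First column holds feature IDs, header row holds sample IDs.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"duplicate feature ID {dup!r} in {path}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ParseError(f"duplicate sample ID {dup!r} in {path}")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"non-numeric expression value in {path}: {exc}") from exc
    if not np.isfinite(values.to_numpy()).all():
        bad = values.index[~np.isfinite(values).all(axis=1)][0]
        raise ParseError(f"non-finite expression value in feature {bad!r}")
    values.index.name = "feature_id"
    return values


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="feature_id", float_format="%.15g")


# ---------------------------------------------------------------- phenotypes

def read_phenotypes(path) -> pd.DataFrame:
    """Read the per-sample phenotype CSV and validate its contract."""
    df = pd.read_csv(path)
    missing = [c for c in MANDATORY_PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"phenotype file {path} lacks mandatory columns: {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"duplicate sample_id {dup!r}")
    bad_groups = set(df["af_group"]) - set(AF_GROUPS)
    if bad_groups:
        raise ParseError(f"unknown af_group values: {sorted(bad_groups)}")
    events_outside_incident = df[(df["event"] == 1) & (df["af_group"] != "incident")]
    if len(events_outside_incident):
        raise ParseError("event=1 outside the incident-AF group")
    non_prev = df["af_group"] != "prevalent"
    if df.loc[non_prev, "followup_time"].isna().any():
        raise ParseError("followup_time missing for a non-prevalent sample")
    return df


def write_phenotypes(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, index=False)


# ------------------------------------------------------------------ networks

def read_network(path, fmt: str = "tsv") -> nx.Graph:
    """Read an undirected network from a two-column TSV edge list or SIF.

    Self-loops are dropped (with a logged count); duplicate and reversed
    edges collapse onto one undirected edge.  An empty file yields an empty
    graph.
    """
    graph = nx.Graph()
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if fmt == "tsv":
                if len(fields) < 2:
                    raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
                pairs = [(fields[0], fields[1])]
            elif fmt == "sif":
                if len(fields) == 1:
                    graph.add_node(fields[0])
                    continue
                if len(fields) < 3:
                    raise ParseError(f"{path}:{lineno}: SIF line needs source, relation, target(s)")
                pairs = [(fields[0], t) for t in fields[2:]]
            else:
                raise ValueError(f"unknown network format {fmt!r}")
            for a, b in pairs:
                if a == b:
                    n_self += 1
                    graph.add_node(a)
                else:
                    graph.add_edge(a, b)
    if n_self:
        logger.warning("%d self-loop%s removed while reading %s",
                       n_self, "" if n_self == 1 else "s", path)
    return graph


def write_network(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{a}\t{b}\n")


def read_edge_list(path) -> nx.Graph:
    """Read a headered two-column edge-list TSV written by write_network."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected 2 columns")
    graph = nx.Graph()
    graph.add_edges_from(df.itertuples(index=False, name=None))
    graph.remove_edges_from(nx.selfloop_edges(graph))
    return graph


# ----------------------------------------------------------------- gene sets

def read_gene_sets(path) -> List[Tuple[str, str, List[str]]]:
    """Read a GMT file: one set per line, name TAB description TAB members."""
    sets: List[Tuple[str, str, List[str]]] = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs name, description, >=1 member")
            name, desc, members = fields[0], fields[1], [m for m in fields[2:] if m]
            if name in seen:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            if not members:
                raise ParseError(f"{path}:{lineno}: set {name!r} has no members")
            seen.add(name)
            sets.append((name, desc, members))
    return sets


def write_gene_sets(sets: Sequence[Tuple[str, str, Sequence[str]]], path) -> None:
    with open(path, "w") as fh:
        for name, desc, members in sets:
            fh.write("\t".join([name, desc, *members]) + "\n")


# ------------------------------------------------------------------- results

def write_results(results: pd.DataFrame, path) -> None:
    """Write an association result table (feature, effect, SE, p, q)."""
    cols = [c for c in RESULT_COLUMNS if c in results.columns]
    extra = [c for c in results.columns if c not in cols]
    results[cols + extra].to_csv(path, sep="\t", index=False, float_format="%.15g")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ----------------------------------------------------------- feature mapping

def collapse_features(
    results: pd.DataFrame, feature_to_gene: Dict[str, str]
) -> pd.DataFrame:
    """Map feature-level results to gene level, keeping per gene the feature
    with the smallest association p (needed when expression features and
    network nodes live in different namespaces)."""
    mapped = results[results["feature_id"].isin(feature_to_gene)].copy()
    mapped["gene_id"] = mapped["feature_id"].map(feature_to_gene)
    mapped = mapped.sort_values(["p", "feature_id"], kind="mergesort")
    return mapped.drop_duplicates("gene_id", keep="first").reset_index(drop=True)
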