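"""Gene scores for module search: inverse-normal transform of association p.

Each gene's two-sided association p-value is mapped to an upper-tail
standard-normal quantile, z = Phi^{-1}(1 - p), so stronger association
(smaller p) gives a larger score regardless of effect direction.  A signed
variant (z carries the sign of the estimated effect) is available behind a
flag.  The transform's functional form is an adopted convention of the
dense-module-search literature; the scores only need to be monotone in the
evidence for the greedy search to behave sensibly.
"""

from __future__ import annotations

import logging
from typing import Dict, Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

P_FLOOR = 1e-16


def p_to_z(p) -> np.ndarray | float:
    """Upper-tail inverse-normal transform of p-values in (0, 1].

    p is clipped to [1e-16, 1 - 1e-16] before the transform so the result is
    always finite; strict monotonicity (smaller p, larger z) holds on the
    clipped range.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0.0) or np.any(arr > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    z = stats.norm.isf(np.clip(arr, P_FLOOR, 1.0 - P_FLOOR))
    return float(z) if np.isscalar(p) else z


def build_score_map(
    results: pd.DataFrame,
    network: nx.Graph,
    signed: bool = False,
    gene_col: Optional[str] = None,
) -> Dict[str, float]:
    """Score map restricted to genes present in both results and network.

    Multiple features mapping to one gene collapse by minimum p before the
    transform.  Network nodes without a score are dropped from the search
    graph (their count is logged); an empty intersection is an error.
    """
    col = gene_col or ("gene_id" if "gene_id" in results.columns else "feature_id")
    df = results[results["p"].notna()].copy()
    df = df.sort_values(["p", col], kind="mergesort").drop_duplicates(col, keep="first")
    scored = dict(zip(df[col], zip(df["p"], df.get("effect", pd.Series(0, index=df.index)))))

    score_map: Dict[str, float] = {}
    for gene in network.nodes:
        if gene in scored:
            p, effect = scored[gene]
            z = p_to_z(p)
            if signed and effect < 0:
                z = -z
            score_map[gene] = float(z)
    dropped = network.number_of_nodes() - len(score_map)
    if dropped:
        logger.info("%d network node(s) without scores dropped from the search graph",
                    dropped)
    if not score_map:
        raise ValueError("no overlap between scored genes and network nodes")
    return score_map
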