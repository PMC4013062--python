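"""Hypergeometric over-representation of subnetwork genes in pathways.

For each gene set, the overlap with the AF subnetwork is tested with the
hypergeometric upper tail P(X >= n_overlap) when drawing |subnetwork| genes
from the universe (all scored genes on the PPI graph) with the set's
in-universe members as successes; p-values are BH-adjusted across the
tested sets.  The reported ratio is n_overlap / n_set, following the usual
"k/K (r)" pathway-table convention.
"""

from __future__ import annotations

import logging
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .association import bh_fdr

logger = logging.getLogger(__name__)

MIN_SET_SIZE = 3


def format_ratio(n_overlap: int, n_set: int) -> str:
    """Render an overlap as ``"k/K (r)"`` with the ratio at 2 d.p."""
    return f"{n_overlap}/{n_set} ({n_overlap / n_set:.2f})"


def enrich(
    subnetwork_genes: Iterable[str],
    sets: Sequence[Tuple[str, str, Sequence[str]]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Per-set enrichment of the subnetwork, sorted by p.

    Sets are intersected with the universe first; sets smaller than
    3 in-universe members are skipped (logged).  Columns: set_name,
    n_overlap, n_set, ratio, p, q, overlap_genes.
    """
    universe = set(universe)
    sub = set(subnetwork_genes)
    if not universe:
        raise ValueError("empty universe")
    if not sub:
        raise ValueError("empty subnetwork")
    if not sub <= universe:
        extra = sorted(sub - universe)[:5]
        raise ValueError(f"subnetwork genes outside the universe: {extra}")

    N, n_draw = len(universe), len(sub)
    rows: List[dict] = []
    n_skipped = 0
    for name, _desc, members in sets:
        in_univ = sorted(set(members) & universe)
        if len(in_univ) < MIN_SET_SIZE:
            n_skipped += 1
            continue
        overlap = sorted(sub & set(in_univ))
        k, K = len(overlap), len(in_univ)
        p = float(stats.hypergeom.sf(k - 1, N, K, n_draw))
        rows.append({
            "set_name": name,
            "n_overlap": k,
            "n_set": K,
            "ratio": k / K,
            "ratio_str": format_ratio(k, K),
            "p": min(p, 1.0),
            "overlap_genes": ";".join(overlap),
        })
    if n_skipped:
        logger.info("%d gene set(s) skipped (<%d in-universe members)",
                    n_skipped, MIN_SET_SIZE)
    if not rows:
        raise ValueError("no testable gene sets after universe intersection")
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    out = out.sort_values(["p", "set_name"], kind="mergesort").reset_index(drop=True)
    return out[["set_name", "n_overlap", "n_set", "ratio", "ratio_str",
                "p", "q", "overlap_genes"]]
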