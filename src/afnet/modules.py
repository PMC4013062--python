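"""Greedy dense-module search on a scored PPI graph.

Every scored gene serves as a seed exactly once.  From a seed, the module
grows by steepest ascent: at each step the neighbouring gene whose inclusion
maximises the module score Z_m = (sum_i z_i) / sqrt(k) is added, but only if
it strictly increases Z_m; ties break on lexicographic gene ID; growth stops
when no neighbour strictly improves the score.  The AF subnetwork is the
union of the top-fraction (default 1%) of modules by score, with the PPI
edges induced on that union.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import networkx as nx

__all__ = ["Module", "module_score", "grow_module", "search_all", "select_and_merge"]


@dataclass(frozen=True)
class Module:
    """A connected gene set found by greedy growth from one seed."""

    seed: str
    members: frozenset
    score: float

    @property
    def k(self) -> int:
        return len(self.members)


def module_score(members: Sequence[str], scores: Mapping[str, float]) -> float:
    """Z_m = (sum of member z-scores) / sqrt(k)."""
    members = list(members)
    if not members:
        raise ValueError("module must have at least one member")
    missing = [g for g in members if g not in scores]
    if missing:
        raise KeyError(f"unscored module member(s): {sorted(missing)[:5]}")
    return sum(scores[g] for g in members) / math.sqrt(len(members))


def grow_module(seed: str, graph: nx.Graph, scores: Mapping[str, float]) -> Module:
    """Grow one module from ``seed`` by the strict greedy rule.

    Only scored genes are candidates.  Deterministic: the best candidate is
    chosen by (score gain, then lexicographic gene ID).
    """
    if seed not in graph:
        raise KeyError(f"seed {seed!r} not in graph")
    if seed not in scores:
        raise KeyError(f"seed {seed!r} has no score")

    members = {seed}
    z_sum = scores[seed]
    current = z_sum  # k = 1
    frontier = {n for n in graph.neighbors(seed) if n in scores}
    while frontier:
        k_new = len(members) + 1
        best_gene, best_score = None, current
        for gene in sorted(frontier):
            cand = (z_sum + scores[gene]) / math.sqrt(k_new)
            if cand > best_score:
                best_gene, best_score = gene, cand
        if best_gene is None:
            break
        members.add(best_gene)
        z_sum += scores[best_gene]
        current = best_score
        frontier.discard(best_gene)
        frontier.update(
            n for n in graph.neighbors(best_gene) if n in scores and n not in members
        )
    return Module(seed=seed, members=frozenset(members), score=current)


def search_all(graph: nx.Graph, scores: Mapping[str, float]) -> List[Module]:
    """One module per scored node, seeds visited in sorted node order.

    Identical member sets arising from different seeds are all retained
    (one module per seed).
    """
    seeds = sorted(n for n in graph.nodes if n in scores)
    if not seeds:
        raise ValueError("no scored nodes in graph")
    return [grow_module(seed, graph, scores) for seed in seeds]


def select_and_merge(
    modules: Sequence[Module], top_fraction: float, graph: nx.Graph
) -> Tuple[nx.Graph, List[Module]]:
    """Merge the top-fraction highest-scoring modules into a subnetwork.

    Selects ceil(top_fraction * M) modules; ties at the cutoff break by
    lexicographic seed ID so exactly that many are kept.  Returns the
    induced subgraph on the union of their members, plus the selected
    modules.
    """
    if not modules:
        raise ValueError("empty module list")
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError(f"top_fraction must lie in (0, 1], got {top_fraction}")
    n_select = math.ceil(top_fraction * len(modules))
    ranked = sorted(modules, key=lambda m: (-m.score, m.seed))
    selected = ranked[:n_select]
    nodes = set().union(*(m.members for m in selected))
    return graph.subgraph(nodes).copy(), selected


def modules_table(modules: Sequence[Module]):
    """Modules as a DataFrame sorted by score descending (seed tie-break)."""
    import pandas as pd

    rows = [
        {"seed": m.seed, "k": m.k, "score": m.score,
         "members": ";".join(sorted(m.members))}
        for m in sorted(modules, key=lambda m: (-m.score, m.seed))
    ]
    return pd.DataFrame(rows, columns=["seed", "k", "score", "members"])
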