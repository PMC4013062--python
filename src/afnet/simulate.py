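"""Synthetic cohort, network and gene-set generator.

Emulates the statistical structure the downstream analysis assumes: a
pedigree-clustered cohort with a minority prevalent-AF group and a smaller
incident-AF group, log2 expression with planted over-expressed genes, a
scale-free protein-protein interaction (PPI) graph containing a planted
connected high-signal module, and a gene-set collection in which one
designated set is enriched for the planted module.

Everything is a pure function of (config, seed): the master seed spawns
one independent substream per component (cohort, expression, network,
gene sets), so each output is individually reproducible.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .config import ConfigurationError, SimulationConfig

AF_GROUPS = ("none", "prevalent", "incident")

COVARIATE_COLUMNS = [
    "smoking", "height", "weight", "sbp", "dbp",
    "diabetes", "mi", "heart_failure", "antihypertensive",
]
MEDICATION_COLUMNS = ["warfarin", "beta_blocker", "digoxin", "calcium_channel_blocker"]


def _substreams(seed: int, n: int) -> List[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def gene_ids(n_genes: int) -> List[str]:
    width = len(str(n_genes - 1))
    return [f"G{i:0{width}d}" for i in range(n_genes)]


def _draw_af_groups(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    n_prev = int(round(cfg.af_prevalent_frac * cfg.n_samples))
    n_inc = int(round(cfg.af_incident_frac * cfg.n_samples))
    n_none = cfg.n_samples - n_prev - n_inc
    if min(n_prev, n_inc, n_none) < 2:
        raise ConfigurationError(
            f"group sizes infeasible: none={n_none}, prevalent={n_prev}, incident={n_inc}"
        )
    groups = np.array(["none"] * n_none + ["prevalent"] * n_prev + ["incident"] * n_inc)
    return rng.permutation(groups)


def simulate_cohort(
    cfg: SimulationConfig,
) -> Tuple[pd.DataFrame, pd.DataFrame, List[str]]:
    """Generate (expression, samples, signal_genes).

    Expression for gene g in sample s is

        baseline_g + beta_age * age_s + beta_sex * male_s
        + family_intercept(ped(s)) + shift_g * 1[s prevalent AF] + noise,

    where ``shift_g`` is ``signal_effect`` for signal genes and
    ``signal_effect * (1 + planted_module_z_boost)`` for the subset of signal
    genes later planted as a connected module (the first
    ``planted_module_size`` signal genes, so network simulation can agree on
    the membership without sharing state).

    Returns
    -------
    expression:
        DataFrame, genes x samples, log2 scale.
    samples:
        One row per sample: pedigree, AF group, age, sex, risk-factor
        covariates, medication flags, follow-up time and event indicator.
    signal_genes:
        IDs of the truly shifted genes (planted-module members first).
    """
    rng_cohort, rng_expr = _substreams(cfg.seed, 4)[:2]
    n = cfg.n_samples

    sample_ids = [f"S{i:04d}" for i in range(n)]
    pedigree = rng_cohort.permutation(np.arange(n) % cfg.n_families)
    af_group = _draw_af_groups(cfg, rng_cohort)
    prev = af_group == "prevalent"
    inc = af_group == "incident"

    # Covariates shifted by AF group (AF cases older, more often male, more
    # comorbid) so that adjustment is non-degenerate.
    age = rng_cohort.normal(66.0, 9.0, n)
    age[prev] += 7.0
    age[inc] += 5.0
    p_male = np.where(prev, 0.64, np.where(inc, 0.61, 0.42))
    sex = (rng_cohort.random(n) < p_male).astype(int)  # 1 = male

    samples = pd.DataFrame({
        "sample_id": sample_ids,
        "pedigree_id": [f"F{p:04d}" for p in pedigree],
        "af_group": af_group,
        "age": np.round(age, 1),
        "sex": np.where(sex == 1, "male", "female"),
    })
    samples["smoking"] = (rng_cohort.random(n) < np.where(prev, 0.04, 0.09)).astype(int)
    samples["height"] = np.round(rng_cohort.normal(66.0, 4.0, n) + 1.5 * sex, 1)
    samples["weight"] = np.round(rng_cohort.normal(174.0, 39.0, n) + 10.0 * prev, 1)
    samples["sbp"] = np.round(rng_cohort.normal(128.0, 18.0, n) + 9.0 * inc, 1)
    samples["dbp"] = np.round(rng_cohort.normal(74.0, 10.0, n) - 5.0 * prev, 1)
    samples["diabetes"] = (rng_cohort.random(n) < np.where(prev | inc, 0.30, 0.15)).astype(int)
    samples["mi"] = (rng_cohort.random(n) < np.where(prev, 0.23, 0.02)).astype(int)
    samples["heart_failure"] = (rng_cohort.random(n) < np.where(prev, 0.25, 0.04)).astype(int)
    samples["antihypertensive"] = (rng_cohort.random(n) < np.where(prev | inc, 0.70, 0.46)).astype(int)
    samples["warfarin"] = (rng_cohort.random(n) < np.where(prev, 0.45, 0.02)).astype(int)
    samples["beta_blocker"] = (rng_cohort.random(n) < np.where(prev | inc, 0.55, 0.25)).astype(int)
    samples["digoxin"] = (rng_cohort.random(n) < np.where(prev, 0.20, 0.01)).astype(int)
    samples["calcium_channel_blocker"] = (
        rng_cohort.random(n) < np.where(prev | inc, 0.30, 0.15)
    ).astype(int)

    # Incident events: exponential times truncated at the follow-up horizon;
    # the AF-free referents are administratively censored at the horizon and
    # prevalent cases carry no follow-up (their AF predates the blood draw).
    horizon = cfg.followup_horizon
    u = rng_cohort.random(n)
    event_time = -np.log(1.0 - u * (1.0 - np.exp(-horizon / 3.0))) * 3.0
    followup = np.where(inc, np.round(event_time, 3), horizon)
    samples["followup_time"] = np.where(prev, np.nan, followup)
    samples["event"] = inc.astype(int)

    genes = gene_ids(cfg.n_genes)
    signal_genes = genes[: cfg.n_signal_genes]
    planted = set(signal_genes[: cfg.planted_module_size])

    baseline = rng_expr.uniform(4.0, 10.0, cfg.n_genes)
    fam_effects = rng_expr.normal(0.0, cfg.family_sd, cfg.n_families)
    shift = np.zeros(cfg.n_genes)
    for i, g in enumerate(signal_genes):
        shift[i] = cfg.signal_effect * (
            (1.0 + cfg.planted_module_z_boost) if g in planted else 1.0
        )
    values = (
        baseline[:, None]
        + cfg.beta_age * age[None, :]
        + cfg.beta_sex * sex[None, :]
        + fam_effects[pedigree][None, :]
        + shift[:, None] * prev[None, :].astype(float)
        + rng_expr.normal(0.0, cfg.noise_sd, (cfg.n_genes, n))
    )
    expression = pd.DataFrame(values, index=pd.Index(genes, name="feature_id"),
                              columns=sample_ids)
    return expression, samples, list(signal_genes)


def simulate_incident_gene(
    n: int,
    log_hr: float,
    event_frac: float = 0.075,
    horizon: float = 7.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate one expression feature that drives incident-AF hazard.

    Expression x ~ N(0, 1); event times are exponential with hazard
    ``lambda0 * exp(log_hr * x)`` and administrative censoring at
    ``horizon``; ``lambda0`` is solved so the expected event fraction under
    the marginal distribution of x equals ``event_frac``.  Used as the
    parameter-recovery oracle for the incident-AF Cox model.
    """
    from scipy.optimize import brentq

    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, 1.0, n)
    grid = np.linspace(-4, 4, 201)
    dens = np.exp(-grid**2 / 2) / np.sqrt(2 * np.pi)
    dens /= dens.sum()

    def expected_events(lam0: float) -> float:
        return float(np.sum(dens * (1.0 - np.exp(-lam0 * np.exp(log_hr * grid) * horizon))))

    lam0 = brentq(lambda l: expected_events(l) - event_frac, 1e-8, 10.0)
    t = rng.exponential(1.0 / (lam0 * np.exp(log_hr * x)))
    event = (t < horizon).astype(int)
    return pd.DataFrame({
        "expression": x,
        "followup_time": np.minimum(t, horizon),
        "event": event,
    })


def simulate_network(
    cfg: SimulationConfig, signal_genes: Sequence[str]
) -> Tuple[nx.Graph, List[str]]:
    """Generate a simple undirected PPI-like graph with a planted module.

    The background is scale-free (Barabasi-Albert, m=2, mean degree ~4) or a
    simplified power-law configuration model.  The planted module is the
    first ``planted_module_size`` signal genes, connected by a random
    spanning tree laid over the background graph -- the lightest structural
    footprint that guarantees connectivity, so that under a null
    configuration the planted genes remain nearly indistinguishable from
    the rest of the graph.
    """
    if len(signal_genes) < cfg.planted_module_size:
        raise ConfigurationError(
            f"planted_module_size={cfg.planted_module_size} exceeds "
            f"{len(signal_genes)} available signal genes"
        )
    rng = _substreams(cfg.seed, 4)[2]
    n = cfg.n_genes
    if cfg.network_model == "scale-free":
        g0 = nx.barabasi_albert_graph(n, 2, seed=int(rng.integers(2**31)))
    else:
        gamma = 2.5
        degs = np.clip(np.round(((1 - rng.random(n)) ** (-1.0 / (gamma - 1.0)))), 1, n // 4)
        degs = degs.astype(int)
        if degs.sum() % 2:
            degs[int(rng.integers(n))] += 1
        g0 = nx.configuration_model(degs, seed=int(rng.integers(2**31)))
        g0 = nx.Graph(g0)  # collapse multi-edges
        g0.remove_edges_from(nx.selfloop_edges(g0))

    genes = gene_ids(n)
    # Random node relabelling so signal genes land anywhere in the topology.
    perm = rng.permutation(n)
    graph = nx.relabel_nodes(g0, {i: genes[perm[i]] for i in range(n)})

    planted = list(signal_genes[: cfg.planted_module_size])
    order = list(rng.permutation(planted))
    for i in range(1, len(order)):  # random spanning tree: connectivity
        j = int(rng.integers(i))
        graph.add_edge(order[i], order[j])
    graph.remove_edges_from(nx.selfloop_edges(graph))
    return graph, planted


def simulate_gene_sets(
    cfg: SimulationConfig, planted_module: Sequence[str]
) -> List[Tuple[str, str, List[str]]]:
    """Generate a gene-set collection as (name, description, members) records.

    The first set, ``SET000_planted``, contains at least half of the planted
    module topped up with background genes; the rest are uniform draws from
    the gene universe with sizes in ``gene_set_size_range``.
    """
    genes = gene_ids(cfg.n_genes)
    universe = set(genes)
    if not set(planted_module) <= universe:
        raise ConfigurationError("planted module is not contained in the gene universe")
    lo, hi = cfg.gene_set_size_range
    rng = _substreams(cfg.seed, 4)[3]

    n_core = max((len(planted_module) + 1) // 2, min(len(planted_module), lo))
    core = list(planted_module[:n_core])
    size = int(rng.integers(max(lo, len(core)), hi + 1))
    background = [g for g in genes if g not in set(core)]
    members = core + list(rng.choice(background, size - len(core), replace=False))
    sets = [("SET000_planted", "planted-module-enriched set", sorted(members))]

    width = len(str(cfg.n_gene_sets))
    for k in range(1, cfg.n_gene_sets):
        size = int(rng.integers(lo, hi + 1))
        members = sorted(rng.choice(genes, size, replace=False))
        sets.append((f"SET{k:0{width}d}", "random set", members))
    return sets
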