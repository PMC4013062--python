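"""Configuration objects for the synthetic cohort generator and the pipeline.

The simulation defaults emulate a pedigree-clustered cohort of ~2,000
participants in which a minority carries prevalent atrial fibrillation (AF),
a second minority develops incident AF during follow-up, and a small set of
genes is over-expressed in prevalent AF by 0.07-0.17 log2 units -- the effect
scale reported for whole-blood transcript differences in AF cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Tuple


class ConfigurationError(ValueError):
    """Raised when a simulation or pipeline configuration is infeasible."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort, network and gene-set generator.

    Attributes
    ----------
    n_samples, n_families:
        Cohort size and number of pedigrees; samples are assigned to
        pedigrees near-uniformly.
    n_genes, n_signal_genes:
        Number of expression features and how many are truly shifted in
        prevalent AF.
    af_prevalent_frac, af_incident_frac:
        Fractions of the cohort with prevalent / incident AF; the remainder
        is the AF-free referent group. Counts are ``round(frac * n_samples)``.
    signal_effect:
        Log2 expression shift of signal genes in prevalent-AF samples.
    family_sd, noise_sd:
        Standard deviations of the per-pedigree Gaussian random intercept
        and of the residual noise.
    network_model:
        ``"scale-free"`` (Barabasi-Albert) or ``"configuration"``
        (power-law configuration model, simplified).
    planted_module_size:
        Size of the connected module planted among the signal genes.
    planted_module_z_boost:
        Multiplier applied on top of ``signal_effect`` for planted-module
        genes: their shift is ``signal_effect * (1 + boost)``, which inflates
        their association z-scores relative to other signal genes.
    n_gene_sets, gene_set_size_range:
        Gene-set collection emitted for the enrichment stage; one designated
        set is constructed to contain at least half of the planted module.
    seed:
        Master seed; every generator output is a pure function of
        (config, seed).
    """

    n_samples: int = 2000
    n_families: int = 700
    n_genes: int = 500
    n_signal_genes: int = 20
    af_prevalent_frac: float = 0.072
    af_incident_frac: float = 0.058
    signal_effect: float = 0.15
    family_sd: float = 0.3
    noise_sd: float = 0.5
    network_model: str = "scale-free"
    planted_module_size: int = 10
    planted_module_z_boost: float = 1.0
    n_gene_sets: int = 50
    gene_set_size_range: Tuple[int, int] = (10, 40)
    seed: int = 0
    # Small fixed covariate effects so that age/sex adjustment is
    # non-degenerate (log2 units per year / for male sex).
    beta_age: float = 0.005
    beta_sex: float = 0.05
    followup_horizon: float = 7.0

    def __post_init__(self) -> None:
        counts = {
            "n_samples": self.n_samples,
            "n_families": self.n_families,
            "n_genes": self.n_genes,
            "n_signal_genes": self.n_signal_genes,
            "planted_module_size": self.planted_module_size,
            "n_gene_sets": self.n_gene_sets,
        }
        for name, value in counts.items():
            if int(value) != value or value <= 0:
                raise ConfigurationError(f"{name} must be a positive integer, got {value!r}")
        for name in ("af_prevalent_frac", "af_incident_frac"):
            value = getattr(self, name)
            if not 0.0 < value < 1.0:
                raise ConfigurationError(f"{name} must lie in (0, 1), got {value!r}")
        if self.af_prevalent_frac + self.af_incident_frac >= 1.0:
            raise ConfigurationError("AF fractions must sum to less than 1")
        if self.n_samples < self.n_families:
            raise ConfigurationError(
                f"n_samples ({self.n_samples}) must be >= n_families ({self.n_families})"
            )
        if not (self.planted_module_size <= self.n_signal_genes <= self.n_genes):
            raise ConfigurationError(
                "require planted_module_size <= n_signal_genes <= n_genes, got "
                f"{self.planted_module_size} / {self.n_signal_genes} / {self.n_genes}"
            )
        if self.network_model not in ("scale-free", "configuration"):
            raise ConfigurationError(f"unknown network_model {self.network_model!r}")
        lo, hi = self.gene_set_size_range
        if not (1 <= lo <= hi):
            raise ConfigurationError(f"invalid gene_set_size_range {self.gene_set_size_range!r}")
        if hi > self.n_genes:
            raise ConfigurationError(
                f"gene_set_size_range max ({hi}) exceeds gene universe ({self.n_genes})"
            )
        for name in ("family_sd", "noise_sd", "signal_effect", "planted_module_z_boost"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "gene_set_size_range" in d:
            d["gene_set_size_range"] = tuple(d["gene_set_size_range"])
        return cls(**d)


@dataclass
class PipelineConfig:
    """End-to-end run configuration: simulate -> associate -> score -> search -> enrich."""

    outdir: str = "afnet_run"
    seed: int = 0
    covariate_set: str = "age_sex"  # or "full_risk_factors"
    top_fraction: float = 0.01
    fdr_threshold: float = 0.05
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    stages: Tuple[str, ...] = ("simulate", "assoc", "score", "modules", "enrich")

    def __post_init__(self) -> None:
        for name in ("top_fraction", "fdr_threshold"):
            value = getattr(self, name)
            if not 0.0 < value <= 1.0:
                raise ConfigurationError(f"{name} must lie in (0, 1], got {value!r}")
        if self.covariate_set not in ("age_sex", "full_risk_factors"):
            raise ConfigurationError(f"unknown covariate_set {self.covariate_set!r}")
        known = {"simulate", "assoc", "score", "modules", "enrich"}
        unknown = set(self.stages) - known
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
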