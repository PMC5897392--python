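"""Configuration objects for the simulator and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration field violates its stated constraints."""


@dataclass
class SimulationConfig:
    """Parameters of the multi-study synthetic cohort.

    Defaults emulate the four-study liver design: cohorts of 178, 149, 178
    and 83 European-like samples (588 in total), genotypes organised in LD
    blocks, planted primary and secondary cis effects on the scale of the
    reported eQTL effect sizes (a few tenths of an expression SD up to ~1 SD
    per allele), study-specific location/scale shifts in expression and a
    small rate of missing expression values.
    """

    n_studies: int = 4
    samples_per_study: tuple[int, ...] = (178, 149, 178, 83)
    n_variants: int = 2000
    n_genes: int = 40
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 20
    ld_rho: float = 0.8
    n_primary_effects: int = 10
    n_secondary_effects: int = 3
    effect_size_sd: float = 0.7
    noise_sd: float = 1.0
    batch_shift_sd: float = 1.0
    batch_scale_range: tuple[float, float] = (0.8, 1.25)
    missing_rate: float = 0.02
    outlier_pop_fraction: float = 0.0
    outlier_fst: float = 0.1
    panel_overlap: float = 0.9
    n_probes_per_gene: int = 1
    age_effect: float = 0.005
    sex_effect: float = 0.1
    chrom: str = "1"
    variant_spacing: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        self.samples_per_study = tuple(int(n) for n in self.samples_per_study)
        counts = {
            "n_studies": self.n_studies,
            "n_variants": self.n_variants,
            "n_genes": self.n_genes,
            "ld_block_size": self.ld_block_size,
            "n_probes_per_gene": self.n_probes_per_gene,
            "variant_spacing": self.variant_spacing,
        }
        for name, value in counts.items():
            if int(value) <= 0:
                raise ConfigurationError(f"{name} must be a positive count, got {value}")
        if len(self.samples_per_study) != self.n_studies:
            raise ConfigurationError("samples_per_study must have one entry per study")
        if any(n <= 0 for n in self.samples_per_study):
            raise ConfigurationError("study sample sizes must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if not 0 <= self.ld_rho < 1:
            raise ConfigurationError("ld_rho must be in [0, 1)")
        for name in ("missing_rate", "outlier_pop_fraction", "panel_overlap"):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ConfigurationError(f"{name} must be a fraction in [0, 1], got {value}")
        if self.n_primary_effects < 0 or self.n_secondary_effects < 0:
            raise ConfigurationError("effect counts must be non-negative")
        if self.batch_scale_range[0] <= 0 or self.batch_scale_range[0] > self.batch_scale_range[1]:
            raise ConfigurationError("batch_scale_range must be a positive interval")

    @property
    def n_samples_total(self) -> int:
        return sum(self.samples_per_study)

    @property
    def study_names(self) -> list[str]:
        return [f"study{i + 1}" for i in range(self.n_studies)]


@dataclass
class PipelineConfig:
    """Thresholds and paths for an end-to-end run.

    The defaults are the analysis thresholds of the liver study: MAF >= 0.05,
    HWE exact P >= 1e-6, reference-AF concordance within 10%, cross-study AF
    within 15%, variants genotyped in >= 100 samples, a +/-1 Mb cis window,
    Q < 0.001 for the primary scan, conditional P < 1e-6 and Q < 0.05 for the
    GWAS-overlap report.
    """

    input_dir: str = "."
    output_dir: str = "run"
    mode: str = "full"  # single-study | meta | mega | full
    maf_min: float = 0.05
    hwe_p_min: float = 1e-6
    reference_af_max_diff: float = 0.10
    cross_study_af_max_diff: float = 0.15
    min_genotyped: int = 100
    cis_window: int = 1_000_000
    q_threshold: float = 1e-3
    conditional_p_threshold: float = 1e-6
    gwas_q_threshold: float = 0.05
    knn_k: int = 10
    min_studies_meta: int = 2
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if self.mode not in {"single-study", "meta", "mega", "full"}:
            raise ConfigurationError(f"invalid mode {self.mode!r}")
        for name in (
            "maf_min",
            "hwe_p_min",
            "reference_af_max_diff",
            "cross_study_af_max_diff",
            "min_genotyped",
            "cis_window",
            "q_threshold",
            "conditional_p_threshold",
            "gwas_q_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")

    def thresholds(self) -> dict:
        """All thresholds as a flat dict (echoed into logs and summaries)."""
        d = asdict(self)
        d.pop("simulation", None)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = SimulationConfig(**sim)
        return cfg
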