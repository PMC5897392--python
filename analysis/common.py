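"""Shared setup for the analysis drivers: one fixed synthetic four-study
cohort (178/149/178/83 samples, 2,000 variants in LD blocks, 40 genes,
10 primary + 3 secondary planted effects) and the result directories."""

from pathlib import Path

from liverqtl.config import PipelineConfig, SimulationConfig
from liverqtl.simulate import simulate_study_set

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 2018

COHORT = SimulationConfig(
    n_variants=2000,
    n_genes=40,
    n_primary_effects=10,
    n_secondary_effects=3,
    effect_size_sd=0.7,
    missing_rate=0.02,
    seed=SEED,
)


def pipeline_config(out_name: str = "pipeline") -> PipelineConfig:
    return PipelineConfig(
        output_dir=str(RESULTS / out_name), seed=SEED, simulation=COHORT
    )


def load_cohort():
    """The cohort is regenerated deterministically from the seed on demand."""
    return simulate_study_set(COHORT)


def outdir(name: str) -> Path:
    d = RESULTS / name
    d.mkdir(parents=True, exist_ok=True)
    return d


def prepared():
    """Cohort after QC and normalization, ready for mapping.

    Re-derives the analysis-ready state deterministically (seconds at this
    scale) so each driver stays runnable on its own. Returns (cohort, merged
    genotypes, per-study cleaned genotypes, normalized expression,
    covariates with genotype PCs).
    """
    from liverqtl import simulate
    from liverqtl.containers import GenotypeMatrix
    from liverqtl.eqtl import build_covariates
    from liverqtl.expression import normalize_studies
    from liverqtl.genotype_qc import merge_panels, run_study_qc

    cohort = load_cohort()
    panel = simulate.variant_panel(COHORT)
    reference = panel[["chrom", "pos", "ref", "alt"]].copy()
    reference["af"] = panel["maf"]
    cleaned = {name: run_study_qc(gm, reference)[0]
               for name, gm in cohort.genotypes.items()}
    merged, _ = merge_panels(list(cleaned.values()))
    expression = normalize_studies(cohort.expression, knn_k=10)
    merged = GenotypeMatrix(
        merged.dosages.loc[expression.samples], merged.variants
    )
    covariates = build_covariates(
        cohort.covariates.reindex(expression.samples), merged, n_pcs=5
    )
    return cohort, merged, cleaned, expression, covariates
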