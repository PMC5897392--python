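"""Multi-study synthetic genotype/expression generator with known ground truth.

The generator emulates the four-cohort liver design: several studies of
~80-210 samples, a shared variant panel of which each study genotypes only a
fraction, local LD organised in blocks, planted primary and secondary cis
effects, study-specific location/scale shifts in expression, and missing
expression values. Every quantity is reproducible from ``SimulationConfig.seed``.

LD is generated by block-wise Gaussian copula thresholding: haplotype alleles
within a block share a latent Gaussian factor with correlation ``ld_rho``
(zero across blocks). Thresholding attenuates the realised dosage correlation
below ``ld_rho``; cross-block dosage correlation is ~0, which is the property
the conditional-analysis ground truth relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import ConfigurationError, SimulationConfig
from .containers import ExpressionMatrix, GenotypeMatrix, ProbeMatrix, TrueEffects


class EffectVariantError(KeyError):
    """A planted effect references a variant absent from the genotypes."""


# seed-stream tags so that each component draws from an independent stream
_TAG_PANEL = 11
_TAG_GENO = 23
_TAG_MASK = 37
_TAG_EFFECTS = 41
_TAG_COVAR = 53
_TAG_EXPR = 67
_TAG_ANNOT = 79


def _rng(config: SimulationConfig, tag: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, tag, *extra])


# ---------------------------------------------------------------------------
# panel, genes, masks
# ---------------------------------------------------------------------------

def variant_panel(config: SimulationConfig) -> pd.DataFrame:
    """Shared variant panel: id, chrom, pos (1-based), ref, alt, maf, block.

    One minor-allele frequency is drawn per LD block (uniform over
    ``maf_range``) and shared by the block's variants, which keeps
    within-block dosage correlation homogeneous.
    """
    rng = _rng(config, _TAG_PANEL)
    n = config.n_variants
    block = np.arange(n) // config.ld_block_size
    n_blocks = block.max() + 1
    lo, hi = config.maf_range
    block_maf = rng.uniform(lo, hi, size=n_blocks)
    maf = block_maf[block]
    # outlier population AFs (Balding-Nichols drift, shared by all studies)
    f = config.outlier_fst
    if f > 0:
        a = maf * (1 - f) / f
        b = (1 - maf) * (1 - f) / f
        outlier_maf = np.clip(rng.beta(a, b), 0.01, 0.99)
    else:
        outlier_maf = maf.copy()
    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, size=n)]
    # alt differs from ref and avoids palindromic pairs for simplicity
    complement = {"A": "T", "T": "A", "C": "G", "G": "C"}
    alt = np.array([
        next(b for b in "ACGT" if b != r and b != complement[r]) for r in ref
    ])
    pos = (np.arange(n) + 1) * config.variant_spacing
    ids = [f"var{i + 1:05d}" for i in range(n)]
    return pd.DataFrame(
        {
            "chrom": config.chrom,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "maf": maf,
            "outlier_maf": outlier_maf,
            "block": block,
        },
        index=pd.Index(ids, name="variant"),
    )


def gene_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Gene spans placed along the simulated chromosome.

    Returns a frame indexed by gene id with 1-based inclusive ``start``/``end``,
    ``chrom`` and alternating ``strand``. Genes are spaced so each cis window
    (+/-1 Mb by default) covers a contiguous slice of the variant panel.
    """
    span = config.n_variants * config.variant_spacing
    starts = np.linspace(1, max(span - 10_000, 1), config.n_genes).astype(int)
    length = 10_000
    genes = pd.DataFrame(
        {
            "chrom": config.chrom,
            "start": starts,
            "end": starts + length,
            "strand": np.where(np.arange(config.n_genes) % 2 == 0, "+", "-"),
        },
        index=pd.Index([f"gene{i + 1:04d}" for i in range(config.n_genes)], name="gene"),
    )
    return genes


def panel_masks(config: SimulationConfig) -> pd.DataFrame:
    """Boolean studies x variants frame: True where the study genotyped the variant.

    Each study genotypes a ``panel_overlap`` fraction drawn at random; the
    complement is missing for all its samples (emulating platform differences).
    """
    panel = variant_panel(config)
    masks = {}
    for s, name in enumerate(config.study_names):
        rng = _rng(config, _TAG_MASK, s)
        n_missing = int(round((1 - config.panel_overlap) * config.n_variants))
        missing = rng.choice(config.n_variants, size=n_missing, replace=False)
        m = np.ones(config.n_variants, dtype=bool)
        m[missing] = False
        masks[name] = m
    return pd.DataFrame(masks, index=panel.index).T


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _draw_dosages(
    panel: pd.DataFrame,
    n: int,
    rho: float,
    rng: np.random.Generator,
    n_outliers: int = 0,
) -> np.ndarray:
    """Draw n samples' dosages from the block copula; the last ``n_outliers``
    rows use the drifted (outlier-population) allele frequencies."""
    block = panel["block"].to_numpy()
    n_blocks = block.max() + 1
    n_variants = len(panel)
    u = rng.standard_normal((n, 2, n_blocks))
    e = rng.standard_normal((n, 2, n_variants))
    z = np.sqrt(rho) * u[:, :, block] + np.sqrt(1 - rho) * e
    t = np.broadcast_to(stats.norm.ppf(panel["maf"].to_numpy()), (n, 2, n_variants)).copy()
    if n_outliers:
        t[n - n_outliers:, :, :] = stats.norm.ppf(panel["outlier_maf"].to_numpy())
    return (z < t).sum(axis=1).astype(float)


def simulate_genotypes(
    config: SimulationConfig,
    study_index: int,
    *,
    apply_mask: bool = True,
) -> GenotypeMatrix:
    """Simulate one study's dosage matrix (0/1/2, NaN where not genotyped).

    Haplotypes are drawn from the block copula; if ``outlier_pop_fraction``
    is positive, that fraction of samples (the last rows) is drawn from the
    drifted allele frequencies instead, giving a planted ancestry outlier set.
    """
    if not 0 <= study_index < config.n_studies:
        raise ConfigurationError(
            f"study_index {study_index} out of range for {config.n_studies} studies"
        )
    panel = variant_panel(config)
    rng = _rng(config, _TAG_GENO, study_index)
    n = config.samples_per_study[study_index]
    n_out = int(round(config.outlier_pop_fraction * n))
    dosage = _draw_dosages(panel, n, config.ld_rho, rng, n_outliers=n_out)

    study = config.study_names[study_index]
    samples = pd.Index([f"{study}_s{i + 1:04d}" for i in range(n)], name="sample")
    dos = pd.DataFrame(dosage, index=samples, columns=panel.index)
    if apply_mask:
        genotyped = panel_masks(config).loc[study].to_numpy()
        dos.loc[:, ~genotyped] = np.nan
    variants = panel.drop(columns=["outlier_maf"]).copy()
    variants["n_genotyped"] = dos.notna().sum(axis=0).to_numpy()
    return GenotypeMatrix(dos, variants, study=study)


def simulate_reference_cohort(
    config: SimulationConfig,
    n_samples: int = 100,
    population: str = "EUR",
) -> tuple[GenotypeMatrix, pd.Series]:
    """An external reference cohort drawn from the same variant panel.

    Shares the panel (and hence the true allele frequencies) with the study
    cohorts but uses an independent random stream and contains no drifted
    samples — the role a population reference panel plays for the PCA
    ancestry filter. Returns the genotypes and a population label per sample.
    """
    panel = variant_panel(config)
    rng = _rng(config, _TAG_GENO, 999_983)
    dosage = _draw_dosages(panel, n_samples, config.ld_rho, rng)
    samples = pd.Index([f"ref_{population}_s{i + 1:04d}" for i in range(n_samples)],
                       name="sample")
    gm = GenotypeMatrix(
        pd.DataFrame(dosage, index=samples, columns=panel.index),
        panel.drop(columns=["outlier_maf"]).copy(),
        study="reference",
    )
    return gm, pd.Series(population, index=samples)


def outlier_sample_ids(config: SimulationConfig, study_index: int) -> list[str]:
    """Sample ids drawn from the drifted population (ground truth for QC tests)."""
    n = config.samples_per_study[study_index]
    n_out = int(round(config.outlier_pop_fraction * n))
    study = config.study_names[study_index]
    return [f"{study}_s{i + 1:04d}" for i in range(n - n_out, n)]


# ---------------------------------------------------------------------------
# planted effects
# ---------------------------------------------------------------------------

def plant_effects(config: SimulationConfig) -> TrueEffects:
    """Draw primary (and secondary) cis effects with unambiguous ground truth.

    Effect variants are restricted to variants genotyped by every study, so
    mega- and meta-analysis see the same planted signals. A secondary effect
    is placed in a different LD block of the same gene's cis window, making
    the primary/secondary dosage correlation ~0. Betas are drawn
    N(0, effect_size_sd) with magnitudes floored at 0.2 SD per allele.
    """
    rng = _rng(config, _TAG_EFFECTS)
    panel = variant_panel(config)
    genes = gene_annotation(config)
    shared = panel_masks(config).all(axis=0)
    window = 1_000_000

    n_primary = min(config.n_primary_effects, config.n_genes)
    gene_ids = list(rng.choice(genes.index.to_numpy(), size=n_primary, replace=False))
    rows = []
    for g_i, gene in enumerate(gene_ids):
        row = genes.loc[gene]
        cis = panel[
            (panel["pos"] >= row["start"] - window)
            & (panel["pos"] <= row["end"] + window)
            & shared.to_numpy()
        ]
        if cis.empty:
            continue
        v1 = rng.choice(cis.index.to_numpy())
        beta1 = rng.normal(0, config.effect_size_sd)
        beta1 = np.sign(beta1 or 1.0) * max(abs(beta1), 0.2)
        rows.append({"gene": gene, "variant": v1, "beta": beta1, "rank": "primary"})
        if g_i < config.n_secondary_effects:
            other = cis[cis["block"] != cis.loc[v1, "block"]]
            if other.empty:
                continue
            v2 = rng.choice(other.index.to_numpy())
            beta2 = rng.normal(0, config.effect_size_sd * 0.7)
            beta2 = np.sign(beta2 or 1.0) * max(abs(beta2), 0.2)
            rows.append({"gene": gene, "variant": v2, "beta": beta2, "rank": "secondary"})
    return TrueEffects(pd.DataFrame(rows, columns=["gene", "variant", "beta", "rank"]))


# ---------------------------------------------------------------------------
# covariates and expression
# ---------------------------------------------------------------------------

def simulate_covariates(config: SimulationConfig, study_index: int) -> pd.DataFrame:
    """Per-sample age (uniform integer 20-80) and sex (Bernoulli 1/2)."""
    rng = _rng(config, _TAG_COVAR, study_index)
    n = config.samples_per_study[study_index]
    study = config.study_names[study_index]
    samples = pd.Index([f"{study}_s{i + 1:04d}" for i in range(n)], name="sample")
    return pd.DataFrame(
        {
            "age": rng.integers(20, 81, size=n),
            "sex": rng.integers(0, 2, size=n),
            "study": study,
        },
        index=samples,
    )


def simulate_expression(
    genotypes: GenotypeMatrix,
    effects: TrueEffects,
    covariates: pd.DataFrame,
    config: SimulationConfig,
    study_index: int = 0,
    *,
    probe_level: bool = False,
) -> ExpressionMatrix | ProbeMatrix:
    """Expression = planted genetic effects + covariates + batch shift/scale + noise.

    The genetic component uses the study's dosages (mean-imputed where the
    panel mask left them missing). Per gene and study, a location shift
    ~N(0, batch_shift_sd) and a scale factor ~U(batch_scale_range) emulate
    platform differences; ``missing_rate`` of the cells are then blanked.
    With ``probe_level=True``, ``n_probes_per_gene`` probes per gene are
    emitted with independent measurement noise (for probe-collapse testing).
    """
    rng = _rng(config, _TAG_EXPR, study_index)
    genes = gene_annotation(config)
    n = genotypes.n_samples
    g = config.n_genes

    missing_vars = set(effects.entries["variant"]) - set(genotypes.dosages.columns)
    if missing_vars:
        raise EffectVariantError(
            f"effect variants absent from genotypes: {sorted(missing_vars)[:5]}"
        )

    base = np.zeros((n, g))
    gene_pos = {gid: i for i, gid in enumerate(genes.index)}
    for _, entry in effects.entries.iterrows():
        d = genotypes.dosages[entry["variant"]].to_numpy(dtype=float)
        if np.isnan(d).any():
            fill = np.nanmean(d) if np.isfinite(np.nanmean(d)) else 0.0
            d = np.where(np.isnan(d), fill, d)
        base[:, gene_pos[entry["gene"]]] += entry["beta"] * d

    cov = covariates.reindex(genotypes.samples)
    age = cov["age"].to_numpy(dtype=float)
    sex = cov["sex"].to_numpy(dtype=float)
    base += config.age_effect * (age - age.mean())[:, None]
    base += config.sex_effect * (sex - 0.5)[:, None]

    shift = rng.normal(0, config.batch_shift_sd, size=g)
    scale = rng.uniform(*config.batch_scale_range, size=g)

    n_probes = config.n_probes_per_gene if probe_level else 1
    blocks = []
    for p in range(n_probes):
        noise = rng.standard_normal((n, g)) * config.noise_sd
        vals = shift + scale * (base + noise)
        if config.missing_rate > 0:
            holes = rng.random((n, g)) < config.missing_rate
            vals = np.where(holes, np.nan, vals)
        blocks.append(vals)

    study = genotypes.study or config.study_names[study_index]
    study_labels = pd.Series(study, index=genotypes.samples)
    if not probe_level:
        values = pd.DataFrame(blocks[0], index=genotypes.samples, columns=genes.index)
        return ExpressionMatrix(values, study_labels)

    probe_cols, probe_map = [], {}
    for p in range(n_probes):
        for gid in genes.index:
            pid = f"{gid}_p{p + 1}"
            probe_cols.append(pid)
            probe_map[pid] = gid
    mat = np.concatenate(blocks, axis=1)
    values = pd.DataFrame(mat, index=genotypes.samples, columns=probe_cols)
    return ProbeMatrix(values, pd.Series(probe_map), study=study)


# ---------------------------------------------------------------------------
# variant annotations (regulatory classes / consequences)
# ---------------------------------------------------------------------------

CONSEQUENCES = [
    "upstream", "downstream", "intron", "missense", "synonymous",
    "UTR5", "UTR3", "non-coding-exon", "splice", "other",
]

_NULL_CLASS_P = np.array([0.01, 0.02, 0.05, 0.10, 0.22, 0.30, 0.30])
_NULL_CONSEQ_P = np.array([0.45, 0.44, 0.06, 0.005, 0.005, 0.01, 0.01, 0.01, 0.005, 0.005])


def simulate_annotations(
    variant_ids,
    eqtl_variants,
    config: SimulationConfig,
    regulatory_enrichment: float = 3.0,
) -> pd.DataFrame:
    """Assign regulatory classes 1-7 and consequence categories per variant.

    Variants listed in ``eqtl_variants`` have their odds of falling in the
    regulatory classes 1-4 (and in genic consequence categories) multiplied
    by ``regulatory_enrichment``; everything else follows the background
    distribution. This provides planted enrichment ground truth.
    """
    rng = _rng(config, _TAG_ANNOT)
    ids = pd.Index(variant_ids)
    is_eqtl = ids.isin(set(eqtl_variants))

    class_p_eqtl = _NULL_CLASS_P.copy()
    class_p_eqtl[:4] *= regulatory_enrichment
    class_p_eqtl /= class_p_eqtl.sum()
    conseq_p_eqtl = _NULL_CONSEQ_P.copy()
    conseq_p_eqtl[2:] *= regulatory_enrichment
    conseq_p_eqtl /= conseq_p_eqtl.sum()

    classes = np.where(
        is_eqtl,
        rng.choice(7, size=len(ids), p=class_p_eqtl) + 1,
        rng.choice(7, size=len(ids), p=_NULL_CLASS_P) + 1,
    )
    conseq_idx = np.where(
        is_eqtl,
        rng.choice(10, size=len(ids), p=conseq_p_eqtl),
        rng.choice(10, size=len(ids), p=_NULL_CONSEQ_P),
    )
    return pd.DataFrame(
        {
            "regulome_class": classes,
            "consequence": [CONSEQUENCES[i] for i in conseq_idx],
        },
        index=ids.rename("variant"),
    )


# ---------------------------------------------------------------------------
# whole-cohort convenience
# ---------------------------------------------------------------------------

@dataclass
class StudySet:
    """Everything one simulated multi-study cohort comprises."""

    config: SimulationConfig
    genotypes: dict[str, GenotypeMatrix]
    expression: dict[str, ExpressionMatrix]
    covariates: pd.DataFrame  # all studies stacked
    genes: pd.DataFrame
    effects: TrueEffects

    @property
    def study_names(self) -> list[str]:
        return list(self.genotypes)


def simulate_study_set(config: SimulationConfig, *, probe_level: bool = False) -> StudySet:
    """Simulate all studies of the design with one shared set of planted effects."""
    effects = plant_effects(config)
    genotypes, expression, covs = {}, {}, []
    for s, name in enumerate(config.study_names):
        full = simulate_genotypes(config, s, apply_mask=False)
        cov = simulate_covariates(config, s)
        expr = simulate_expression(full, effects, cov, config, s, probe_level=probe_level)
        masked = simulate_genotypes(config, s, apply_mask=True)
        genotypes[name] = masked
        expression[name] = expr
        covs.append(cov)
    return StudySet(
        config=config,
        genotypes=genotypes,
        expression=expression,
        covariates=pd.concat(covs),
        genes=gene_annotation(config),
        effects=effects,
    )
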