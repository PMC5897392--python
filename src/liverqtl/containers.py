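"""In-memory containers shared across the pipeline.

Dosage matrices are pandas DataFrames with samples on the rows and variants
on the columns; entries are expected alternate-allele counts in [0, 2],
NaN where a sample was not genotyped. Variant metadata travels alongside as
a second DataFrame indexed by variant id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix plus per-variant metadata.

    Attributes
    ----------
    dosages : DataFrame, samples x variants, values in [0, 2] or NaN.
    variants : DataFrame indexed by variant id with at least ``chrom``,
        ``pos`` (1-based), ``ref``, ``alt``; optionally ``maf``, ``hwe_p``,
        ``reference_af``, ``n_genotyped`` and per-study allele frequencies.
    study : label of the originating study, or None for a merged panel.
    """

    dosages: pd.DataFrame
    variants: pd.DataFrame
    study: str | None = None

    def __post_init__(self) -> None:
        if not self.dosages.columns.equals(self.variants.index):
            self.variants = self.variants.loc[self.dosages.columns]
        vals = self.dosages.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals, initial=0.0) < -1e-9 or np.nanmax(vals, initial=0.0) > 2 + 1e-9:
                raise ValueError("dosages must lie in [0, 2]")

    @property
    def samples(self) -> pd.Index:
        return self.dosages.index

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def alt_allele_frequency(self) -> pd.Series:
        """Observed alternate-allele frequency per variant (ignores missing)."""
        return self.dosages.mean(axis=0, skipna=True) / 2.0

    def subset_variants(self, ids) -> "GenotypeMatrix":
        ids = pd.Index(ids)
        return GenotypeMatrix(self.dosages.loc[:, ids], self.variants.loc[ids], self.study)


@dataclass
class ExpressionMatrix:
    """Samples x genes expression matrix on the log2 scale.

    ``study`` assigns every sample to its study of origin (the batch label
    used for empirical-Bayes correction).
    """

    values: pd.DataFrame
    study: pd.Series

    def __post_init__(self) -> None:
        self.study = self.study.reindex(self.values.index)
        if self.study.isna().any():
            raise ValueError("every sample needs a study label")

    @property
    def samples(self) -> pd.Index:
        return self.values.index

    @property
    def genes(self) -> pd.Index:
        return self.values.columns

    def is_complete(self) -> bool:
        return not self.values.isna().any().any()


@dataclass
class ProbeMatrix:
    """Samples x probes matrix with a probe -> gene map (one gene per probe)."""

    values: pd.DataFrame
    probe_to_gene: pd.Series
    study: str | None = None

    def __post_init__(self) -> None:
        missing = self.values.columns.difference(self.probe_to_gene.index)
        if len(missing):
            raise ValueError(f"probes without gene assignment: {list(missing)[:5]}")


@dataclass
class TrueEffects:
    """Planted gene-variant effects used as simulation ground truth.

    ``entries`` has columns gene, variant, beta (expression SD per alternate
    allele) and rank ('primary' or 'secondary'). A secondary entry always
    refers to a gene that also carries a primary entry, and is planted in a
    different LD block so the pair is essentially uncorrelated.
    """

    entries: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene", "variant", "beta", "rank"])
    )

    def __post_init__(self) -> None:
        ent = self.entries
        if ent.duplicated(["gene", "variant"]).any():
            raise ValueError("duplicate (gene, variant) truth entries")
        primary_genes = set(ent.loc[ent["rank"] == "primary", "gene"])
        secondary_genes = set(ent.loc[ent["rank"] == "secondary", "gene"])
        if not secondary_genes <= primary_genes:
            raise ValueError("secondary effects must accompany a primary effect")

    def for_gene(self, gene: str) -> pd.DataFrame:
        return self.entries[self.entries["gene"] == gene]

    @property
    def genes(self) -> list[str]:
        return sorted(self.entries["gene"].unique())
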