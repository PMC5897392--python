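"""Expression harmonization: log transform, probe collapsing, replicate
merging, outlier clamping, KNN imputation, quantile normalization and
empirical-Bayes batch correction.

The per-study order is fixed: log2 -> collapse probes -> merge replicates ->
clamp (where configured) -> merge studies -> KNN imputation -> quantile
normalization -> batch correction. Each step logs the resulting matrix shape.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, ProbeMatrix

log = logging.getLogger(__name__)


def log2_transform(values: pd.DataFrame | np.ndarray, offset: float = 0.001):
    """log2(value + offset); the offset keeps zero abundances finite."""
    arr = np.asarray(values, dtype=float)
    if np.nanmin(arr) < 0:
        raise ValueError("expression abundances must be non-negative before log transform")
    out = np.log2(arr + offset)
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out


def collapse_probes(probes: ProbeMatrix) -> ExpressionMatrix | pd.DataFrame:
    """Collapse probes to genes by the variance-weighted mean.

    The weight of probe p is its variance across samples, so noisy (more
    variable) probes contribute more — deliberately variance-weighted, not
    inverse-variance-weighted. Zero-variance probes get weight 0; if every
    probe of a gene has zero variance, the unweighted mean is used. Missing
    values are ignored pairwise. Output is invariant to probe order.
    """
    values = probes.values
    gene_of = probes.probe_to_gene
    out = {}
    for gene, probe_ids in sorted(gene_of.groupby(gene_of).groups.items()):
        sub = values.loc[:, sorted(probe_ids)]
        if sub.shape[1] == 1:
            out[gene] = sub.iloc[:, 0]
            continue
        w = sub.var(axis=0, ddof=1, skipna=True).fillna(0.0)
        if (w <= 0).all():
            w = pd.Series(1.0, index=sub.columns)
        mask = sub.notna()
        weighted = (sub * w).sum(axis=1, skipna=True)
        norm = (mask * w).sum(axis=1)
        out[gene] = weighted.where(norm > 0) / norm.replace(0, np.nan)
    collapsed = pd.DataFrame(out, index=values.index)
    collapsed.columns.name = "gene"
    if probes.study is None:
        return collapsed
    return ExpressionMatrix(collapsed, pd.Series(probes.study, index=values.index))


def merge_replicates(values: pd.DataFrame, replicate_groups: dict[str, list[str]]) -> pd.DataFrame:
    """One row per individual: the mean over its replicate sample rows."""
    out = {}
    for individual, members in replicate_groups.items():
        if not members:
            raise ValueError(f"replicate group {individual!r} is empty")
        out[individual] = values.loc[members].mean(axis=0, skipna=True)
    merged = pd.DataFrame(out).T
    merged.index.name = values.index.name
    return merged


def clamp_outliers(values: pd.DataFrame, lo: float = -2.0, hi: float = 2.0) -> pd.DataFrame:
    """Set entries strictly outside (lo, hi) to missing (boundary values kept)."""
    if lo >= hi:
        raise ValueError("lo must be below hi")
    out = values.mask((values > hi) | (values < lo))
    n = int(out.isna().sum().sum() - values.isna().sum().sum())
    log.info("clamp_outliers: %d entries set missing outside (%s, %s)", n, lo, hi)
    return out


def knn_impute(values: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Impute missing entries from the k nearest genes (samples x genes in).

    Neighbours are genes, nearest by Euclidean distance over their shared
    observed samples; the imputed entry is the plain mean of the neighbours'
    values in that sample. Genes with no observed value are removed with a
    warning. Delegates to scikit-learn's KNN imputer on the gene x sample
    orientation.
    """
    from sklearn.impute import KNNImputer

    all_missing = values.columns[values.isna().all(axis=0)]
    if len(all_missing):
        log.warning("removing %d genes with no observed values", len(all_missing))
        values = values.drop(columns=all_missing)
    if not values.isna().any().any():
        return values.copy()
    k_eff = min(k, values.shape[1] - 1)
    imputer = KNNImputer(n_neighbors=k_eff, weights="uniform")
    imputed = imputer.fit_transform(values.T.to_numpy(dtype=float))
    return pd.DataFrame(imputed.T, index=values.index, columns=values.columns)


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (row) to the common distribution of sorted means.

    After normalization each sample's sorted vector equals the across-sample
    mean of sorted vectors; ties within a sample receive the mean of the
    quantile values their ranks span (average-rank convention), which makes
    the operation deterministic and idempotent.
    """
    x = values.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("quantile normalization requires a complete matrix")
    target = np.sort(x, axis=1).mean(axis=0)
    out = np.empty_like(x)
    for i in range(x.shape[0]):
        row = x[i]
        assigned = np.empty_like(row)
        assigned[np.argsort(row, kind="mergesort")] = target
        # tied entries share the mean of the quantile values their ranks span
        out[i] = pd.Series(assigned).groupby(row).transform("mean").to_numpy()
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def combat_correct(
    values: pd.DataFrame,
    batch_labels: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Parametric empirical-Bayes location/scale batch correction.

    Standardizes each gene, estimates per-batch additive and multiplicative
    batch parameters shrunk toward normal / inverse-gamma priors fitted
    across genes, adjusts and back-transforms. With a single batch the input
    is returned unchanged. Delegates to scanpy's ComBat implementation.
    """
    batch_labels = batch_labels.reindex(values.index)
    if batch_labels.isna().any():
        raise ValueError("every sample needs a batch label")
    counts = batch_labels.value_counts()
    if (counts < 2).any():
        raise ValueError(f"batches with <2 samples: {list(counts[counts < 2].index)}")
    if values.isna().any().any():
        raise ValueError("batch correction requires a complete matrix")
    if counts.size == 1:
        return values.copy()

    import anndata as ad
    import scanpy as sc

    adata = ad.AnnData(
        values.to_numpy(dtype=float),
        obs=pd.DataFrame({"batch": batch_labels.astype(str).to_numpy()}, index=values.index.astype(str)),
    )
    if covariates is not None:
        for col in covariates.columns:
            adata.obs[col] = covariates.reindex(values.index)[col].to_numpy()
        sc.pp.combat(adata, key="batch", covariates=list(covariates.columns))
    else:
        sc.pp.combat(adata, key="batch")
    return pd.DataFrame(np.asarray(adata.X), index=values.index, columns=values.columns)


def normalize_studies(
    per_study: dict[str, ExpressionMatrix | ProbeMatrix],
    *,
    clamp_studies: tuple[str, ...] = (),
    replicate_groups: dict[str, dict[str, list[str]]] | None = None,
    knn_k: int = 10,
    already_log2: bool = True,
) -> ExpressionMatrix:
    """Full cross-study normalization to one complete gene x sample matrix.

    Probe-level inputs are collapsed to genes; studies named in
    ``clamp_studies`` have extreme raw values blanked; only genes observed in
    every study survive the merge (others cannot be imputed across studies);
    the merged matrix is KNN-imputed, quantile normalized and batch corrected.
    """
    frames, labels = [], []
    for study, data in per_study.items():
        if isinstance(data, ProbeMatrix):
            data = collapse_probes(data)
        values = data.values if isinstance(data, ExpressionMatrix) else data
        if not already_log2:
            values = log2_transform(values)
        if replicate_groups and study in replicate_groups:
            values = merge_replicates(values, replicate_groups[study])
        if study in clamp_studies:
            values = clamp_outliers(values)
        frames.append(values)
        labels.append(pd.Series(study, index=values.index))
        log.info("normalize: study %s -> %s samples x %s genes", study, *values.shape)

    common = frames[0].columns
    for f in frames[1:]:
        common = common.intersection(f.columns)
    observed = [f.loc[:, common].notna().any(axis=0) for f in frames]
    usable = common[np.logical_and.reduce([o.to_numpy() for o in observed])]
    dropped = len(common) - len(usable)
    if dropped:
        log.info("normalize: dropped %d genes unobserved in at least one study", dropped)

    merged = pd.concat([f.loc[:, usable] for f in frames], axis=0)
    batch = pd.concat(labels)
    complete = knn_impute(merged, k=knn_k)
    qn = quantile_normalize(complete)
    corrected = combat_correct(qn, batch)
    return ExpressionMatrix(corrected, batch)
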