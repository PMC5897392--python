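"""cis-eQTL mapping: OLS of expression on allele dosage with covariates.

The scan residualizes expression and dosages against the covariate design
once (Frisch-Waugh partialling-out) and then computes per-pair slopes,
standard errors, t statistics and two-sided p-values in bulk; results are
numerically identical to fitting the full OLS model per pair. The false
discovery rate is controlled jointly over all cis tests (one q-value scale
for the whole scan, not per gene).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, GenotypeMatrix


class MonomorphicError(ValueError):
    """Dosage is constant in the analysed samples."""


class AlignmentError(ValueError):
    """Expression / genotype / covariate samples do not match."""


# ---------------------------------------------------------------------------
# cis pair definition
# ---------------------------------------------------------------------------

def define_cis_pairs(
    genes: pd.DataFrame,
    variants: pd.DataFrame,
    window: int = 1_000_000,
) -> pd.DataFrame:
    """All gene-variant pairs within ``window`` bp of the gene span (inclusive).

    ``genes`` uses the internal 1-based inclusive convention (chrom, start,
    end, strand); a variant qualifies iff it sits on the gene's chromosome
    with position in [start - window, end + window]. The signed TSS distance
    is strand-aware: pos - TSS on the + strand (TSS = start) and TSS - pos on
    the - strand (TSS = end), so negative means upstream of transcription.
    """
    if genes["strand"].isna().any():
        raise ValueError("every gene needs a strand")
    out = []
    for chrom, chrom_vars in variants.groupby("chrom", sort=False):
        pos = chrom_vars["pos"].to_numpy()
        order = np.argsort(pos, kind="mergesort")
        pos_sorted = pos[order]
        ids_sorted = chrom_vars.index.to_numpy()[order]
        for gene, row in genes[genes["chrom"] == chrom].iterrows():
            lo = np.searchsorted(pos_sorted, row["start"] - window, side="left")
            hi = np.searchsorted(pos_sorted, row["end"] + window, side="right")
            if hi <= lo:
                continue
            vpos = pos_sorted[lo:hi]
            tss = row["start"] if row["strand"] == "+" else row["end"]
            dist = vpos - tss if row["strand"] == "+" else tss - vpos
            out.append(
                pd.DataFrame(
                    {
                        "gene": gene,
                        "variant": ids_sorted[lo:hi],
                        "pos": vpos,
                        "tss_distance": dist,
                    }
                )
            )
    if not out:
        return pd.DataFrame(columns=["gene", "variant", "pos", "tss_distance"])
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# regression primitives
# ---------------------------------------------------------------------------

def _covariate_design(covariates: pd.DataFrame | np.ndarray | None, n: int) -> np.ndarray:
    """Intercept plus covariate columns; raises on rank deficiency."""
    if covariates is None:
        c = np.ones((n, 1))
    else:
        arr = np.asarray(covariates, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        c = np.column_stack([np.ones(len(arr)), arr])
    if np.linalg.matrix_rank(c) < c.shape[1]:
        raise ValueError("covariate design is rank deficient (with intercept)")
    return c


def _residualize(m: np.ndarray, design: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(design)
    return m - q @ (q.T @ m)


def fit_cis_regression(
    expression: np.ndarray | pd.Series,
    dosage: np.ndarray | pd.Series,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> tuple[float, float, float, float]:
    """OLS of expression on dosage with intercept and covariates.

    Returns (beta, se, t, p) for the dosage term; p is two-sided from the t
    distribution with n - p degrees of freedom. Constant dosage raises
    :class:`MonomorphicError` ("monomorphic in sample").
    """
    y = np.asarray(expression, dtype=float)
    g = np.asarray(dosage, dtype=float)
    if np.ptp(g) == 0:
        raise MonomorphicError("variant is monomorphic in sample")
    c = _covariate_design(covariates, len(y))
    if len(y) < c.shape[1] + 2:
        raise ValueError("too few samples for the number of predictors")
    yr = _residualize(y[:, None], c)[:, 0]
    xr = _residualize(g[:, None], c)[:, 0]
    df = len(y) - c.shape[1] - 1
    xx = float(xr @ xr)
    xy = float(xr @ yr)
    yy = float(yr @ yr)
    beta = xy / xx
    sigma2 = max(yy - beta * xy, 0.0) / df
    se = np.sqrt(sigma2 / xx)
    if se == 0:  # exact fit: p underflows to the smallest positive float
        return beta, 0.0, np.inf if beta != 0 else 0.0, float(np.finfo(float).tiny)
    t = beta / se
    p = 2 * stats.t.sf(abs(t), df)
    return beta, se, t, float(max(p, np.finfo(float).tiny))


def bh_fdr(p_values, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, preserving input order.

    ``method='storey'`` additionally scales by an estimated null proportion
    pi0 (lambda = 0.5).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    q = multipletests(p, method="fdr_bh")[1]
    if method == "storey":
        pi0 = min(1.0, float((p > 0.5).mean()) / 0.5) if p.size else 1.0
        q = np.minimum(q * pi0, 1.0)
    elif method != "bh":
        raise ValueError(f"unknown FDR method {method!r}")
    return q


def compute_ld(dosage_a, dosage_b) -> float:
    """Squared Pearson correlation (r^2) of two dosage vectors."""
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise MonomorphicError("LD undefined for a constant dosage vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def genotype_pcs(genotypes: GenotypeMatrix, n_pcs: int = 5) -> pd.DataFrame:
    """First genotype principal components (mean-imputed, standardized dosages)."""
    from sklearn.decomposition import PCA

    x = genotypes.dosages.to_numpy(dtype=float)
    x = x[:, ~np.isnan(x).all(axis=0)]
    col_mean = np.nanmean(x, axis=0)
    inds = np.where(np.isnan(x))
    x[inds] = np.take(col_mean, inds[1])
    keep = x.std(axis=0) > 0
    x = x[:, keep]
    x = (x - x.mean(axis=0)) / x.std(axis=0)
    n_pcs = min(n_pcs, x.shape[0] - 1, x.shape[1])
    pcs = PCA(n_components=n_pcs, svd_solver="randomized", random_state=0).fit_transform(x)
    return pd.DataFrame(
        pcs, index=genotypes.samples, columns=[f"PC{i + 1}" for i in range(n_pcs)]
    )


def build_covariates(
    sample_covariates: pd.DataFrame,
    genotypes: GenotypeMatrix | None = None,
    n_pcs: int = 5,
) -> pd.DataFrame:
    """Age, sex and (optionally) the first genotype PCs, aligned on samples."""
    cov = sample_covariates.loc[:, [c for c in ("age", "sex") if c in sample_covariates]]
    cov = cov.astype(float)
    if genotypes is not None and n_pcs > 0:
        pcs = genotype_pcs(genotypes, n_pcs=n_pcs)
        cov = cov.join(pcs.reindex(cov.index))
    if cov.isna().any().any():
        raise ValueError("covariates contain missing values")
    return cov


# ---------------------------------------------------------------------------
# bulk scan
# ---------------------------------------------------------------------------

def _prepare_dosages(dosages: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Mean-impute missing dosages per variant; returns (matrix, n_used)."""
    x = dosages.to_numpy(dtype=float)
    n_used = np.isfinite(x).sum(axis=0)
    col_mean = np.nanmean(np.where(np.isfinite(x), x, np.nan), axis=0)
    inds = np.where(~np.isfinite(x))
    x[inds] = np.take(col_mean, inds[1])
    return x, n_used


def map_all(
    expression: ExpressionMatrix,
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame | None,
    genes: pd.DataFrame,
    window: int = 1_000_000,
    q_threshold: float = 1e-3,
    fdr_method: str = "bh",
) -> pd.DataFrame:
    """Fit every cis pair and control the FDR jointly over all tests.

    Returns one row per testable pair: gene, variant, pos, tss_distance,
    beta, se, t_stat, p_value, q_value, n_used, significant (q < threshold)
    and top (the gene's most significant variant, ties broken by smallest p,
    then largest \\|t\\|, then smallest position). Missing dosages are
    mean-imputed per variant; ``n_used`` records the genotyped count.
    Monomorphic variants are excluded from testing.
    """
    if not expression.samples.equals(genotypes.samples):
        common = expression.samples.intersection(genotypes.samples)
        if len(common) == 0 or len(common) < len(expression.samples):
            raise AlignmentError("expression and genotype samples do not match")
    pairs = define_cis_pairs(genes, genotypes.variants, window=window)
    pairs = pairs[pairs["gene"].isin(expression.genes)]
    if pairs.empty:
        return pd.DataFrame(
            columns=["gene", "variant", "pos", "tss_distance", "beta", "se",
                     "t_stat", "p_value", "q_value", "n_used", "significant", "top"]
        )

    cov = None if covariates is None else covariates.reindex(expression.samples)
    if cov is not None and cov.isna().any().any():
        raise AlignmentError("covariates missing for some samples")
    c = _covariate_design(cov, expression.values.shape[0])
    df = expression.values.shape[0] - c.shape[1] - 1

    x_raw, n_used_all = _prepare_dosages(genotypes.dosages)
    var_index = pd.Index(genotypes.dosages.columns)
    poly = np.ptp(x_raw, axis=0) > 0
    xr = _residualize(x_raw - x_raw.mean(axis=0), c)
    xx = np.einsum("ij,ij->j", xr, xr)

    y = expression.values.to_numpy(dtype=float)
    yr = _residualize(y - y.mean(axis=0), c)
    gene_index = pd.Index(expression.genes)

    chunks = []
    for gene, sub in pairs.groupby("gene", sort=False):
        gi = gene_index.get_loc(gene)
        vi = var_index.get_indexer(sub["variant"])
        ok = poly[vi]
        if not ok.any():
            continue
        sub = sub[ok]
        vi = vi[ok]
        ygene = yr[:, gi]
        xy = xr[:, vi].T @ ygene
        yy = float(ygene @ ygene)
        beta = xy / xx[vi]
        sigma2 = np.maximum(yy - beta * xy, 0.0) / df
        se = np.sqrt(sigma2 / xx[vi])
        with np.errstate(divide="ignore"):
            t = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.inf * np.sign(beta))
        p = np.maximum(2 * stats.t.sf(np.abs(t), df), np.finfo(float).tiny)
        res = sub.copy()
        res["beta"], res["se"], res["t_stat"], res["p_value"] = beta, se, t, p
        res["n_used"] = n_used_all[vi]
        chunks.append(res)

    results = pd.concat(chunks, ignore_index=True)
    results["q_value"] = bh_fdr(results["p_value"].to_numpy(), method=fdr_method)
    results["significant"] = results["q_value"] < q_threshold
    results["top"] = False
    ranked = results.assign(t_abs=-results["t_stat"].abs()).sort_values(
        ["gene", "p_value", "t_abs", "pos"], kind="mergesort"
    )
    top_idx = ranked.groupby("gene", sort=False).head(1).index
    results.loc[top_idx, "top"] = True
    return results
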