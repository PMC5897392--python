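"""Iterative conditional detection of independent cis signals per gene.

Round r regresses expression on each remaining cis variant with the
covariates plus the dosages of all previously selected variants; the variant
with the smallest conditional p is selected if p < 1e-6 (nominal, applied to
the conditional slope), and the search repeats until nothing passes or a
safety cap on rounds is reached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, GenotypeMatrix
from .eqtl import _covariate_design, _prepare_dosages, _residualize, define_cis_pairs

log = logging.getLogger(__name__)

COLLINEAR_R2 = 0.99


@dataclass
class IndependentSignal:
    """One conditional discovery: the variant, its round and the model context."""

    gene: str
    round: int
    variant: str
    beta: float
    se: float
    p_value: float
    conditioning_set: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.conditioning_set) != self.round - 1:
            raise ValueError("round r must condition on exactly r-1 variants")


def find_independent_signals(
    gene: str,
    expression: np.ndarray | pd.Series,
    cis_dosages: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    p_threshold: float = 1e-6,
    max_rounds: int = 10,
    positions: pd.Series | None = None,
) -> list[IndependentSignal]:
    """Stepwise conditional scan for one gene.

    ``cis_dosages`` is samples x cis variants (missing entries mean-imputed).
    Ties on the minimum p are broken by larger \\|t\\| then smaller position
    (``positions``, else panel order). Candidate variants collinear with a
    selected variant (r^2 > 0.99) are skipped with a warning.
    """
    y = np.asarray(expression, dtype=float)
    x, _ = _prepare_dosages(cis_dosages)
    var_ids = list(cis_dosages.columns)
    pos = (
        positions.reindex(cis_dosages.columns).to_numpy(dtype=float)
        if positions is not None
        else np.arange(len(var_ids), dtype=float)
    )
    base = _covariate_design(covariates, len(y))

    selected: list[IndependentSignal] = []
    available = np.ptp(x, axis=0) > 0
    while len(selected) < max_rounds:
        cond_ids = [s.variant for s in selected]
        cond_cols = [var_ids.index(v) for v in cond_ids]
        design = np.column_stack([base, x[:, cond_cols]]) if cond_cols else base
        if np.linalg.matrix_rank(design) < design.shape[1]:
            log.warning("%s: conditioning design rank-deficient; stopping", gene)
            break
        df = len(y) - design.shape[1] - 1
        if df <= 0:
            break

        cand = np.where(available)[0]
        if cond_cols:
            a = x[:, cand] - x[:, cand].mean(axis=0)
            b = x[:, cond_cols] - x[:, cond_cols].mean(axis=0)
            denom = np.sqrt(np.einsum("ij,ij->j", a, a)[:, None]
                            * np.einsum("ij,ij->j", b, b)[None, :])
            with np.errstate(invalid="ignore", divide="ignore"):
                r2 = np.where(denom > 0, (a.T @ b) / denom, 1.0) ** 2
            collinear = r2.max(axis=1) > COLLINEAR_R2
            for j in cand[collinear]:
                log.warning("%s: skipping %s (r^2 > %.2f with conditioning set)",
                            gene, var_ids[j], COLLINEAR_R2)
                available[j] = False
            cand = cand[~collinear]
        if cand.size == 0:
            break

        yr = _residualize(y[:, None], design)[:, 0]
        xr = _residualize(x[:, cand], design)
        xx = np.einsum("ij,ij->j", xr, xr)
        ok = xx > 1e-12
        cand, xr, xx = cand[ok], xr[:, ok], xx[ok]
        if cand.size == 0:
            break
        xy = xr.T @ yr
        yy = float(yr @ yr)
        beta = xy / xx
        sigma2 = np.maximum(yy - beta * xy, 0.0) / df
        se = np.sqrt(sigma2 / xx)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.inf)
        p = np.maximum(2 * stats.t.sf(np.abs(t), df), np.finfo(float).tiny)

        order = np.lexsort((pos[cand], -np.abs(t), p))
        best = order[0]
        if p[best] >= p_threshold:
            break
        j = cand[best]
        selected.append(
            IndependentSignal(
                gene=gene,
                round=len(selected) + 1,
                variant=var_ids[j],
                beta=float(beta[best]),
                se=float(se[best]),
                p_value=float(p[best]),
                conditioning_set=tuple(cond_ids),
            )
        )
        available[j] = False
    return selected


def run_conditional_scan(
    primary_hits: pd.DataFrame,
    expression: ExpressionMatrix,
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame | None,
    genes: pd.DataFrame,
    window: int = 1_000_000,
    p_threshold: float = 1e-6,
    max_rounds: int = 10,
) -> tuple[pd.DataFrame, dict]:
    """Conditional scan over every gene significant in the primary pass.

    Returns the signals table (gene, round, variant, beta, se, p_value,
    conditioning_set) and summary counts: genes scanned, genes with at least
    two signals, and the number of secondary (round >= 2) signals.
    """
    sig_genes = sorted(primary_hits.loc[primary_hits["significant"], "gene"].unique())
    cov = None if covariates is None else covariates.reindex(expression.samples)
    pairs = define_cis_pairs(genes, genotypes.variants, window=window)
    records: list[IndependentSignal] = []
    for gene in sig_genes:
        vids = pairs.loc[pairs["gene"] == gene, "variant"]
        if vids.empty:
            continue
        cis = genotypes.dosages.loc[expression.samples, vids]
        records.extend(
            find_independent_signals(
                gene,
                expression.values[gene].to_numpy(),
                cis,
                cov,
                p_threshold=p_threshold,
                max_rounds=max_rounds,
                positions=genotypes.variants["pos"],
            )
        )
    table = pd.DataFrame(
        [
            {
                "gene": s.gene,
                "round": s.round,
                "variant": s.variant,
                "beta": s.beta,
                "se": s.se,
                "p_value": s.p_value,
                "conditioning_set": ",".join(s.conditioning_set),
            }
            for s in records
        ],
        columns=["gene", "round", "variant", "beta", "se", "p_value", "conditioning_set"],
    )
    n_secondary = int((table["round"] >= 2).sum()) if len(table) else 0
    summary = {
        "n_genes_scanned": len(sig_genes),
        "n_genes_multi_signal": int(
            table.groupby("gene")["round"].max().ge(2).sum()
        ) if len(table) else 0,
        "n_secondary_signals": n_secondary,
        "n_signals_total": int(len(table)),
    }
    return table, summary
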