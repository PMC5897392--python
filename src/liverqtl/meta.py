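"""Random-effects meta-analysis of per-study eQTL estimates and the
meta-vs-mega replication cross-tabulation.

The between-study variance tau^2 uses the DerSimonian-Laird method-of-moments
estimator; the combined effect is the tau^2-inflated inverse-variance mean and
its z statistic is referred to the standard normal, as in classic DL practice.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .eqtl import bh_fdr


class OrientationError(ValueError):
    """Per-study tables disagree on allele orientation for a shared variant."""


def dersimonian_laird(betas, ses) -> dict:
    """DerSimonian-Laird random-effects combination of k study estimates.

    Fixed-effect weights w_i = 1/se_i^2 give the heterogeneity statistic
    Q = sum w_i (beta_i - beta_FE)^2; tau^2 = max(0, (Q - (k-1)) / (sum w -
    sum w^2 / sum w)); random-effects weights 1/(se_i^2 + tau^2) yield the
    combined beta and SE; p is two-sided normal on z = beta/SE.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size == 0:
        raise ValueError("meta-analysis requires at least one study")
    if np.any(s <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / s**2
    beta_fe = float((w * b).sum() / w.sum())
    het_q = float((w * (b - beta_fe) ** 2).sum())
    k = b.size
    if k > 1:
        denom = w.sum() - (w**2).sum() / w.sum()
        tau2 = max(0.0, (het_q - (k - 1)) / denom) if denom > 0 else 0.0
    else:
        tau2 = 0.0
    w_star = 1.0 / (s**2 + tau2)
    beta = float((w_star * b).sum() / w_star.sum())
    se = float(w_star.sum() ** -0.5)
    z = beta / se
    p = float(max(2 * stats.norm.sf(abs(z)), np.finfo(float).tiny))
    return {
        "combined_beta": beta,
        "combined_se": se,
        "tau2": tau2,
        "het_q": het_q,
        "k": k,
        "z": z,
        "p_value": p,
    }


def _check_orientation(tables: dict[str, pd.DataFrame]) -> None:
    ref_alt: dict[str, tuple] = {}
    for study, tab in tables.items():
        if not {"ref", "alt"} <= set(tab.columns):
            return  # no allele columns to verify; harmonization is upstream
        for vid, ref, alt in tab[["variant", "ref", "alt"]].itertuples(index=False):
            pair = (ref, alt)
            if vid in ref_alt and ref_alt[vid] != pair:
                raise OrientationError(
                    f"variant {vid}: alleles {pair} vs {ref_alt[vid]} across studies"
                )
            ref_alt[vid] = pair


def meta_map(
    per_study_results: dict[str, pd.DataFrame],
    min_studies: int = 2,
    q_threshold: float = 1e-3,
) -> pd.DataFrame:
    """Combine per-study eQTL tables pair-by-pair with the DL model.

    Pairs present in fewer than ``min_studies`` studies are excluded.
    BH q-values are computed over all combined tests. Raises
    :class:`OrientationError` when two studies report conflicting ref/alt
    alleles for the same variant (sign flips must be fixed upstream).
    """
    _check_orientation(per_study_results)
    stacked = pd.concat(
        [t.assign(study=s) for s, t in per_study_results.items()], ignore_index=True
    )
    rows = []
    for (gene, variant), grp in stacked.groupby(["gene", "variant"], sort=False):
        if len(grp) < min_studies:
            continue
        res = dersimonian_laird(grp["beta"].to_numpy(), grp["se"].to_numpy())
        res["gene"], res["variant"] = gene, variant
        if "tss_distance" in grp:
            res["tss_distance"] = grp["tss_distance"].iloc[0]
        rows.append(res)
    if not rows:
        return pd.DataFrame(
            columns=["gene", "variant", "combined_beta", "combined_se", "tau2",
                     "het_q", "k", "z", "p_value", "q_value", "significant"]
        )
    out = pd.DataFrame(rows)
    out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    out["significant"] = out["q_value"] < q_threshold
    lead = ["gene", "variant", "combined_beta", "combined_se", "tau2", "het_q",
            "k", "z", "p_value", "q_value", "significant"]
    return out[lead + [c for c in out.columns if c not in lead]]


def replication_crosstab(
    per_study_significant: dict[str, set],
    combined_significant: set,
    label: str = "combined",
) -> pd.DataFrame:
    """Per-study overlap counts and percentages against a combined gene set.

    Percentages are 100 * \\|overlap\\| / \\|study set\\| rounded half-even to
    two decimals; an empty study set reports NA.
    """
    rows = []
    for study, genes in per_study_significant.items():
        overlap = len(set(genes) & set(combined_significant))
        pct = round(100.0 * overlap / len(genes), 2) if genes else np.nan
        rows.append(
            {
                "study": study,
                "n_significant": len(genes),
                f"n_overlap_{label}": overlap,
                f"pct_overlap_{label}": pct,
            }
        )
    return pd.DataFrame(rows)
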