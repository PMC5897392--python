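"""Characterization of eQTL variant sets: matched random controls,
regulatory-class enrichment tests and TSS-distance summaries.

Annotations (ordinal regulatory classes 1-7 and consequence categories) are
consumed as a precomputed per-variant table; per-class enrichment compares
eQTL variants against controls in a 2x2 table with Fisher's exact test
(chi-square with continuity correction once any cell exceeds 10^4).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

FISHER_CELL_MAX = 10_000


def draw_control_variants(
    variants: pd.DataFrame,
    genes: pd.DataFrame,
    n: int = 200_000,
    window: int = 1_000_000,
    seed: int = 0,
) -> pd.Index:
    """Uniform random control variants within ``window`` of any gene span.

    Sampling is without replacement and deterministic per seed; if fewer
    variants are eligible than requested, all of them are returned with a
    warning.
    """
    eligible = np.zeros(len(variants), dtype=bool)
    for chrom, sub in variants.groupby("chrom", sort=False):
        gsub = genes[genes["chrom"] == chrom]
        if gsub.empty:
            continue
        pos = sub["pos"].to_numpy()
        hit = np.zeros(len(sub), dtype=bool)
        for _, g in gsub.iterrows():
            hit |= (pos >= g["start"] - window) & (pos <= g["end"] + window)
        eligible[variants.index.get_indexer(sub.index)] = hit
    pool = variants.index[eligible]
    if len(pool) < n:
        log.warning("only %d eligible control variants (< %d requested)", len(pool), n)
        return pool
    rng = np.random.default_rng(seed)
    return pd.Index(rng.choice(pool.to_numpy(), size=n, replace=False), name="variant")


def class_enrichment_test(
    eqtl_annotations: pd.Series,
    control_annotations: pd.Series,
    class_subset=None,
) -> pd.DataFrame:
    """Per-class enrichment of eQTL vs control variants.

    For each class: in-class/out-of-class counts in both sets, proportions,
    odds ratio and a two-sided p (Fisher exact, or chi-square with Yates
    correction when any cell exceeds 10^4). Zero margins report p = 1 and an
    NA odds ratio.
    """
    if len(eqtl_annotations) == 0 or len(control_annotations) == 0:
        raise ValueError("both annotation sets must be non-empty")
    classes = (
        sorted(set(eqtl_annotations) | set(control_annotations))
        if class_subset is None
        else list(class_subset)
    )
    n_e, n_c = len(eqtl_annotations), len(control_annotations)
    rows = []
    for cls in classes:
        a = int((eqtl_annotations == cls).sum())     # eQTL, in class
        b = n_e - a
        c = int((control_annotations == cls).sum())  # control, in class
        d = n_c - c
        if min(a + c, b + d, a + b, c + d) == 0:
            orr, p = np.nan, 1.0
        elif max(a, b, c, d) <= FISHER_CELL_MAX:
            orr, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        else:
            p = stats.chi2_contingency([[a, b], [c, d]], correction=True)[1]
            orr = (a * d) / (b * c) if b * c > 0 else np.nan
        rows.append(
            {
                "class": cls,
                "n_eqtl": a,
                "n_control": c,
                "proportion_eqtl": a / n_e,
                "proportion_control": c / n_c,
                "odds_ratio": orr,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def tss_distance_summary(distances, threshold: int = 100_000) -> tuple[int, int, float]:
    """(n within, n total, fraction) of signals with \\|TSS distance\\| <= threshold.

    The boundary is inclusive: a signal exactly at the threshold counts as
    within.
    """
    d = np.asarray(distances, dtype=float)
    n_total = d.size
    n_within = int((np.abs(d) <= threshold).sum())
    return n_within, n_total, (n_within / n_total if n_total else np.nan)
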