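"""Genotype harmonization and QC: allele matching, AF concordance, MAF/HWE
filters, PCA ancestry outlier removal and cross-study panel merging.

Variant metadata lives in DataFrames indexed by variant id with columns
``chrom``, ``pos``, ``ref``, ``alt`` and, where computed, ``af`` (study
alternate. . . reference-allele conventions are documented per function),
``reference_af``, ``maf``, ``hwe_p`` and ``n_genotyped``.

The filters are pointwise predicates, so the cascade's result does not
depend on the order in which they are applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .containers import GenotypeMatrix

log = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMES = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_AUTOSOMES = {str(i) for i in range(1, 23)}


def _complement(allele: str) -> str:
    return _COMPLEMENT.get(allele, "N")


def is_autosome(chrom: str) -> bool:
    return str(chrom).removeprefix("chr") in _AUTOSOMES


@dataclass
class QcReport:
    """Per-filter removal bookkeeping; counts must reconcile with sizes."""

    n_variants_in: int = 0
    n_variants_out: int = 0
    removed: dict[str, int] = field(default_factory=dict)
    samples_removed_ancestry: int = 0

    def add(self, reason: str, count: int) -> None:
        self.removed[reason] = self.removed.get(reason, 0) + int(count)

    def reconciles(self) -> bool:
        return self.n_variants_in - self.n_variants_out == sum(self.removed.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [{"filter": k, "n_removed": v} for k, v in sorted(self.removed.items())]
        rows.append({"filter": "TOTAL_removed", "n_removed": sum(self.removed.values())})
        rows.append({"filter": "variants_in", "n_removed": self.n_variants_in})
        rows.append({"filter": "variants_out", "n_removed": self.n_variants_out})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# allele harmonization
# ---------------------------------------------------------------------------

def harmonize_alleles(
    study: GenotypeMatrix,
    reference: pd.DataFrame,
    *,
    palindrome_maf_max: float = 0.4,
    palindrome_af_tol: float = 0.10,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Match each study variant's allele pair to the reference panel.

    Kept as-is when the pair equals the reference pair; strand-flipped
    (both alleles complemented, dosages and AF untouched) when the
    complemented pair matches; allele-swapped (dosage -> 2 - dosage) when
    the pair matches in reversed order, with or without complementing.
    Multi-allelic and unmatched variants are removed. Palindromic A/T and
    C/G pairs carry no strand information, so they are kept only when the
    study MAF is below ``palindrome_maf_max`` and the alternate-allele
    frequency agrees with the reference within ``palindrome_af_tol``.

    Returns the harmonized matrix and a per-variant action log with one row
    per input variant (action in {kept, strand_flip, swap, strand_flip_swap,
    palindromic_kept, removed_multi_allelic, removed_palindromic,
    removed_unmatched, removed_not_in_reference}).
    """
    variants = study.variants
    dosages = study.dosages.copy()
    study_af = dosages.mean(axis=0, skipna=True) / 2.0

    actions: dict[str, str] = {}
    new_meta = variants.copy()
    ref_af_out = pd.Series(np.nan, index=variants.index)

    for vid, row in variants.iterrows():
        ref, alt = str(row["ref"]), str(row["alt"])
        if "," in alt or "," in ref or len(ref) != 1 or len(alt) != 1:
            actions[vid] = "removed_multi_allelic"
            continue
        if vid not in reference.index:
            actions[vid] = "removed_not_in_reference"
            continue
        rref, ralt = str(reference.loc[vid, "ref"]), str(reference.loc[vid, "alt"])
        if "," in ralt or len(rref) != 1 or len(ralt) != 1:
            actions[vid] = "removed_multi_allelic"
            continue
        panel_af = reference.loc[vid].get("af", np.nan)

        if (ref, alt) in _PALINDROMES:
            af = study_af.get(vid, np.nan)
            maf = min(af, 1 - af) if np.isfinite(af) else np.nan
            consistent = (
                {ref, alt} == {rref, ralt}
                and np.isfinite(maf)
                and maf < palindrome_maf_max
                and (not np.isfinite(panel_af) or abs(af - panel_af) <= palindrome_af_tol)
            )
            if consistent:
                actions[vid] = "palindromic_kept"
                new_meta.loc[vid, ["ref", "alt"]] = [rref, ralt]
                if (ref, alt) != (rref, ralt):
                    dosages[vid] = 2.0 - dosages[vid]
                ref_af_out[vid] = panel_af
            else:
                actions[vid] = "removed_palindromic"
            continue

        cref, calt = _complement(ref), _complement(alt)
        if (ref, alt) == (rref, ralt):
            actions[vid] = "kept"
        elif (cref, calt) == (rref, ralt):
            actions[vid] = "strand_flip"
            new_meta.loc[vid, ["ref", "alt"]] = [rref, ralt]
        elif (alt, ref) == (rref, ralt):
            actions[vid] = "swap"
            new_meta.loc[vid, ["ref", "alt"]] = [rref, ralt]
            dosages[vid] = 2.0 - dosages[vid]
        elif (calt, cref) == (rref, ralt):
            actions[vid] = "strand_flip_swap"
            new_meta.loc[vid, ["ref", "alt"]] = [rref, ralt]
            dosages[vid] = 2.0 - dosages[vid]
        else:
            actions[vid] = "removed_unmatched"
            continue
        ref_af_out[vid] = panel_af

    log_frame = pd.DataFrame(
        {"action": pd.Series(actions).reindex(variants.index)}
    ).rename_axis("variant")
    keep = log_frame.index[~log_frame["action"].str.startswith("removed")]
    new_meta = new_meta.loc[keep]
    new_meta["reference_af"] = ref_af_out.loc[keep]
    out = GenotypeMatrix(dosages.loc[:, keep], new_meta, study=study.study)
    return out, log_frame


# ---------------------------------------------------------------------------
# pointwise variant filters
# ---------------------------------------------------------------------------

def reference_af_filter(variants: pd.DataFrame, max_diff: float = 0.10) -> pd.DataFrame:
    """Drop variants whose study AF differs from the reference panel AF by
    strictly more than ``max_diff`` (a 10% discordance rule; a difference of
    exactly ``max_diff`` is kept). Variants with no reference AF are kept
    with a warning."""
    af = variants["af"].to_numpy(dtype=float)
    ref = variants["reference_af"].to_numpy(dtype=float)
    no_ref = ~np.isfinite(ref)
    if no_ref.any():
        log.warning("%d variants lack a reference AF; skipped by the AF filter", no_ref.sum())
    diff = np.abs(af - ref)
    keep = no_ref | ~(diff > max_diff)
    return variants.loc[keep]


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy-Weinberg test probability.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts no more likely than the observed one. Monomorphic
    input returns 1.0.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("at least one genotyped sample required")
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0

    # unnormalized probabilities over all het counts with the parity of n_rare
    mid = n_rare * (2 * n - n_rare) // (2 * n)
    if mid % 2 != n_rare % 2:
        mid += 1
    probs = {mid: 1.0}
    # downward recurrence: P(h-2)/P(h) = h(h-1) / (4 (r+1) (c+1))
    h, cur = mid, 1.0
    while h >= 2:
        rare_hom = (n_rare - h) // 2
        common_hom = n - rare_hom - h
        cur *= h * (h - 1) / (4.0 * (rare_hom + 1) * (common_hom + 1))
        h -= 2
        probs[h] = cur
    # upward recurrence: P(h+2)/P(h) = 4 r c / ((h+2)(h+1))
    h, cur = mid, 1.0
    while h + 2 <= min(n_rare, 2 * n - n_rare):
        rare_hom = (n_rare - h) // 2
        common_hom = n - rare_hom - h
        cur *= 4.0 * rare_hom * common_hom / ((h + 2) * (h + 1))
        h += 2
        probs[h] = cur

    total = sum(probs.values())
    p_obs = probs[n_het] / total
    p = sum(v for v in probs.values() if v / total <= p_obs * (1 + 1e-12)) / total
    return min(1.0, p)


def genotype_counts(dosages: pd.Series | np.ndarray) -> tuple[int, int, int]:
    """Hard-call genotype counts (hom-ref, het, hom-alt) from dosages."""
    d = np.asarray(dosages, dtype=float)
    d = d[np.isfinite(d)]
    calls = np.rint(d).astype(int)
    return int((calls == 0).sum()), int((calls == 1).sum()), int((calls == 2).sum())


def compute_variant_stats(gm: GenotypeMatrix) -> pd.DataFrame:
    """Annotate variants with observed af, maf and exact HWE p."""
    variants = gm.variants.copy()
    af = gm.dosages.mean(axis=0, skipna=True) / 2.0
    variants["af"] = af
    variants["maf"] = np.minimum(af, 1 - af)
    variants["hwe_p"] = [
        hwe_exact_test(*genotype_counts(gm.dosages[vid])) if gm.dosages[vid].notna().any() else 1.0
        for vid in variants.index
    ]
    variants["n_genotyped"] = gm.dosages.notna().sum(axis=0).to_numpy()
    return variants


def maf_hwe_filter(
    variants: pd.DataFrame,
    maf_min: float = 0.05,
    hwe_p_min: float = 1e-6,
    autosomes_only: bool = True,
) -> pd.DataFrame:
    """Drop variants with MAF strictly below ``maf_min`` (0.05 itself is
    kept), HWE exact P strictly below ``hwe_p_min``, or off the autosomes."""
    keep = (variants["maf"] >= maf_min) & (variants["hwe_p"] >= hwe_p_min)
    if autosomes_only:
        keep &= variants["chrom"].map(is_autosome)
    return variants.loc[keep]


# ---------------------------------------------------------------------------
# ancestry filter
# ---------------------------------------------------------------------------

def pca_ancestry_filter(
    study: GenotypeMatrix,
    reference: GenotypeMatrix,
    reference_populations: pd.Series,
    target_population: str = "EUR",
    n_variants: int = 30_000,
    seed: int = 0,
    distance_expansion: float = 1.5,
) -> pd.Index:
    """Retain study samples clustering with the target reference population.

    A PCA is computed on study and reference samples jointly at ``n_variants``
    randomly chosen shared variants (all shared variants, with a warning, if
    fewer are available). A study sample is retained iff its PC1-PC2 distance
    to the target-population centroid is at most ``distance_expansion`` times
    the largest distance of any target-population reference sample.
    """
    shared = study.dosages.columns.intersection(reference.dosages.columns)
    if len(shared) == 0:
        raise ValueError("no shared variants between study and reference")
    rng = np.random.default_rng(seed)
    if len(shared) < n_variants:
        log.warning(
            "only %d shared variants available (< %d requested); using all",
            len(shared), n_variants,
        )
        chosen = shared
    else:
        chosen = pd.Index(rng.choice(shared.to_numpy(), size=n_variants, replace=False))

    combined = pd.concat(
        [study.dosages.loc[:, chosen], reference.dosages.loc[:, chosen]], axis=0
    )
    x = combined.to_numpy(dtype=float)
    col_mean = np.nanmean(x, axis=0)
    inds = np.where(np.isnan(x))
    x[inds] = np.take(col_mean, inds[1])
    x -= x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    x /= sd

    pcs = PCA(n_components=2, svd_solver="randomized", random_state=0).fit_transform(x)
    pcs = pd.DataFrame(pcs, index=combined.index, columns=["PC1", "PC2"])

    ref_target = pcs.loc[reference_populations.index[reference_populations == target_population]]
    centroid = ref_target.mean(axis=0)
    radius = np.sqrt(((ref_target - centroid) ** 2).sum(axis=1)).max()
    study_pcs = pcs.loc[study.samples]
    dist = np.sqrt(((study_pcs - centroid) ** 2).sum(axis=1))
    return study.samples[dist <= distance_expansion * radius]


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def merge_panels(
    studies: list[GenotypeMatrix],
    min_genotyped: int = 100,
    cross_study_af_max_diff: float = 0.15,
) -> tuple[GenotypeMatrix, QcReport]:
    """Union of samples over the union of (harmonized) variant panels.

    Variants absent from a study are missing for its samples. Variants
    genotyped in fewer than ``min_genotyped`` samples overall are dropped,
    as are variants whose alternate-allele frequency differs by strictly
    more than ``cross_study_af_max_diff`` between any two studies.
    """
    all_samples = pd.Index(np.concatenate([s.samples for s in studies]))
    if all_samples.duplicated().any():
        raise ValueError("duplicate sample ids across studies")

    meta: dict[str, pd.Series] = {}
    for s in studies:
        for vid, row in s.variants.iterrows():
            if vid in meta:
                if (meta[vid]["ref"], meta[vid]["alt"]) != (row["ref"], row["alt"]):
                    raise ValueError(f"allele mismatch across studies at {vid}; harmonize first")
            else:
                meta[vid] = row
    variants = pd.DataFrame(meta).T.rename_axis("variant")

    dosages = pd.concat([s.dosages for s in studies], axis=0).reindex(
        index=all_samples, columns=variants.index
    )
    report = QcReport(n_variants_in=len(variants))

    n_genotyped = dosages.notna().sum(axis=0)
    low = n_genotyped < min_genotyped
    report.add("min_genotyped", low.sum())

    afs = pd.DataFrame(
        {s.study or f"study{i}": s.dosages.mean(axis=0, skipna=True) / 2.0
         for i, s in enumerate(studies)}
    ).reindex(variants.index)
    spread = afs.max(axis=1, skipna=True) - afs.min(axis=1, skipna=True)
    discordant = (spread > cross_study_af_max_diff) & ~low
    report.add("cross_study_af", discordant.sum())

    keep = variants.index[~(low | discordant)]
    variants = variants.loc[keep]
    variants["n_genotyped"] = n_genotyped.loc[keep]
    for col in afs.columns:
        variants[f"af_{col}"] = afs.loc[keep, col]
    report.n_variants_out = len(keep)
    merged = GenotypeMatrix(dosages.loc[:, keep], variants, study=None)
    return merged, report


# ---------------------------------------------------------------------------
# per-study cascade
# ---------------------------------------------------------------------------

def run_study_qc(
    study: GenotypeMatrix,
    reference: pd.DataFrame,
    maf_min: float = 0.05,
    hwe_p_min: float = 1e-6,
    reference_af_max_diff: float = 0.10,
) -> tuple[GenotypeMatrix, QcReport]:
    """Harmonize alleles then apply the AF-concordance and MAF/HWE filters."""
    report = QcReport(n_variants_in=study.n_variants)
    harmonized, flip_log = harmonize_alleles(study, reference)
    for action, count in flip_log["action"].value_counts().items():
        if action.startswith("removed"):
            report.add(action, count)

    stats_frame = compute_variant_stats(harmonized)
    kept_af = reference_af_filter(stats_frame, max_diff=reference_af_max_diff)
    report.add("reference_af", len(stats_frame) - len(kept_af))
    kept = maf_hwe_filter(kept_af, maf_min=maf_min, hwe_p_min=hwe_p_min)
    report.add("maf_hwe_autosome", len(kept_af) - len(kept))
    report.n_variants_out = len(kept)
    out = GenotypeMatrix(harmonized.dosages.loc[:, kept.index], kept, study=study.study)
    return out, report
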