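"""Allele harmonization, HWE exact test, frequency filters, ancestry PCA and
panel merging."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from liverqtl import simulate
from liverqtl.config import SimulationConfig
from liverqtl.containers import GenotypeMatrix
from liverqtl.genotype_qc import (
    QcReport,
    compute_variant_stats,
    genotype_counts,
    harmonize_alleles,
    hwe_exact_test,
    maf_hwe_filter,
    merge_panels,
    pca_ancestry_filter,
    reference_af_filter,
    run_study_qc,
)
from tests.conftest import make_genotype_frame


def _gm(allele_rows, dosages):
    """GenotypeMatrix from a list of (ref, alt) and a samples x variants array."""
    d = np.asarray(dosages, dtype=float)
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": 1000 + 100 * np.arange(len(allele_rows)),
            "ref": [a for a, _ in allele_rows],
            "alt": [b for _, b in allele_rows],
        },
        index=pd.Index([f"v{j + 1}" for j in range(len(allele_rows))], name="variant"),
    )
    dos = pd.DataFrame(
        d, index=pd.Index([f"s{i + 1}" for i in range(d.shape[0])], name="sample"),
        columns=variants.index,
    )
    return GenotypeMatrix(dos, variants)


def _reference(pairs, af=None):
    ref = pd.DataFrame(
        {"ref": [a for a, _ in pairs], "alt": [b for _, b in pairs]},
        index=pd.Index([f"v{j + 1}" for j in range(len(pairs))], name="variant"),
    )
    if af is not None:
        ref["af"] = af
    return ref


class TestHarmonizeAlleles:
    def test_matching_flipping_and_swapping(self):
        # v1 identical; v2 on opposite strand; v3 swapped; v4 strand+swap
        study = _gm(
            [("A", "G"), ("T", "C"), ("G", "A"), ("C", "T")],
            [[0, 1, 2, 0], [1, 2, 0, 1], [2, 0, 1, 2]],
        )
        reference = _reference([("A", "G")] * 4)
        out, log = harmonize_alleles(study, reference)
        assert log["action"].tolist() == ["kept", "strand_flip", "swap", "strand_flip_swap"]
        assert (out.variants["ref"] == "A").all() and (out.variants["alt"] == "G").all()
        # strand flip leaves dosages alone; swaps reverse them
        np.testing.assert_array_equal(out.dosages["v2"], study.dosages["v2"])
        np.testing.assert_array_equal(out.dosages["v3"], 2 - study.dosages["v3"])
        np.testing.assert_array_equal(out.dosages["v4"], 2 - study.dosages["v4"])

    def test_multiallelic_and_unmatched_removed(self):
        study = _gm([("A", "C,G"), ("A", "C")], [[0, 1], [1, 2]])
        reference = _reference([("A", "G"), ("A", "G")])
        out, log = harmonize_alleles(study, reference)
        assert out.n_variants == 0
        assert log["action"].tolist() == ["removed_multi_allelic", "removed_unmatched"]

    def test_palindromic_policy(self):
        # common A/T variant is ambiguous -> removed; rare C/G with matching
        # AF is retained
        study = _gm([("A", "T"), ("C", "G")], [[1, 0], [1, 1], [1, 1], [1, 0]])
        reference = _reference([("A", "T"), ("C", "G")], af=[0.5, 0.25])
        out, log = harmonize_alleles(study, reference)
        assert log.loc["v1", "action"] == "removed_palindromic"
        assert log.loc["v2", "action"] == "palindromic_kept"
        assert list(out.dosages.columns) == ["v2"]


class TestFrequencyFilters:
    @pytest.mark.parametrize(
        "af,ref_af,kept",
        [(0.30, 0.45, False), (0.30, 0.35, True), (0.40, 0.50, True)],
    )
    def test_reference_af_boundaries(self, af, ref_af, kept):
        variants = pd.DataFrame(
            {"af": [af], "reference_af": [ref_af]}, index=pd.Index(["v1"], name="variant")
        )
        out = reference_af_filter(variants, max_diff=0.10)
        assert ("v1" in out.index) == kept

    def test_missing_reference_af_skipped(self):
        variants = pd.DataFrame(
            {"af": [0.2], "reference_af": [np.nan]}, index=pd.Index(["v1"], name="variant")
        )
        assert "v1" in reference_af_filter(variants).index

    @pytest.mark.parametrize(
        "maf,hwe_p,chrom,kept",
        [
            (0.049, 1.0, "1", False),
            (0.05, 1.0, "1", True),
            (0.3, 9e-7, "1", False),
            (0.3, 1e-6, "1", True),
            (0.3, 1.0, "X", False),
            (0.3, 1.0, "chr22", True),
        ],
    )
    def test_maf_hwe_autosome_boundaries(self, maf, hwe_p, chrom, kept):
        variants = pd.DataFrame(
            {"maf": [maf], "hwe_p": [hwe_p], "chrom": [chrom]},
            index=pd.Index(["v1"], name="variant"),
        )
        assert ("v1" in maf_hwe_filter(variants).index) == kept


def _hwe_enumeration(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Independent oracle: full enumeration of the conditional distribution."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab

    def prob(h):
        a = (na - h) // 2
        b = n - a - h
        if a < 0 or b < 0 or (na - h) % 2:
            return 0.0
        return math.exp(
            math.lgamma(n + 1) - math.lgamma(a + 1) - math.lgamma(h + 1)
            - math.lgamma(b + 1) + h * math.log(2)
            + math.lgamma(na + 1) + math.lgamma(2 * n - na + 1) - math.lgamma(2 * n + 1)
        )
    probs = {h: prob(h) for h in range(min(na, 2 * n - na) + 1)}
    p_obs = probs[n_ab]
    return sum(v for v in probs.values() if v <= p_obs * (1 + 1e-12))


class TestHweExact:
    def test_monomorphic_returns_one(self):
        assert hwe_exact_test(100, 0, 0) == 1.0
        assert hwe_exact_test(0, 0, 57) == 1.0

    def test_all_heterozygous_fails_threshold(self):
        assert hwe_exact_test(0, 100, 0) < 1e-6

    @pytest.mark.parametrize(
        "counts",
        [(57, 38, 5), (10, 5, 3), (20, 50, 30), (1, 1, 1), (68, 28, 4), (0, 3, 97)],
    )
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(_hwe_enumeration(*counts), abs=1e-12)

    def test_enumeration_equivalence_over_small_grid(self):
        """Exhaustive agreement with the oracle for all totals <= 12."""
        for n in range(1, 13):
            for n_aa in range(n + 1):
                for n_ab in range(n - n_aa + 1):
                    n_bb = n - n_aa - n_ab
                    got = hwe_exact_test(n_aa, n_ab, n_bb)
                    want = _hwe_enumeration(n_aa, n_ab, n_bb)
                    assert got == pytest.approx(want, abs=1e-12), (n_aa, n_ab, n_bb)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)


def test_genotype_counts_rounds_dosages():
    assert genotype_counts(pd.Series([0.1, 0.9, 2.0, np.nan])) == (1, 1, 1)


class TestMergePanels:
    def _study(self, name, samples, variants, dosage_value=1.0):
        d = np.full((samples, len(variants)), dosage_value)
        gm = make_genotype_frame(d)
        gm.dosages.columns = pd.Index(variants, name="variant")
        gm.variants.index = gm.dosages.columns
        gm.dosages.index = pd.Index([f"{name}_{i}" for i in range(samples)], name="sample")
        return GenotypeMatrix(gm.dosages, gm.variants, study=name)

    def test_union_min_genotyped_and_af_spread(self):
        a = self._study("A", 120, ["v1", "v2"], dosage_value=0.6)
        b = self._study("B", 90, ["v1", "v3"], dosage_value=0.96)
        merged, report = merge_panels([a, b], min_genotyped=100,
                                      cross_study_af_max_diff=0.15)
        # v2 is genotyped in 120 samples -> kept; v3 only 90 -> dropped;
        # v1 AFs 0.30 vs 0.48 differ by 0.18 -> dropped
        assert list(merged.dosages.columns) == ["v2"]
        assert report.removed == {"min_genotyped": 1, "cross_study_af": 1}
        assert report.reconciles()
        assert merged.dosages.loc["B_0", "v2"] != merged.dosages.loc["B_0", "v2"]  # NaN

    def test_duplicate_sample_ids_error(self):
        a = self._study("A", 10, ["v1"])
        with pytest.raises(ValueError, match="duplicate sample"):
            merge_panels([a, a])

    def test_full_overlap_has_no_missing(self):
        a = self._study("A", 60, ["v1", "v2"])
        b = self._study("B", 60, ["v1", "v2"])
        merged, _ = merge_panels([a, b], min_genotyped=100)
        assert not merged.dosages.isna().any().any()


class TestQcCascade:
    def test_filter_order_is_irrelevant(self, rng):
        """The MAF/HWE/reference-AF filters are pointwise predicates, so any
        application order yields the same surviving variant set."""
        variants = pd.DataFrame(
            {
                "chrom": rng.choice(["1", "2", "X"], 60),
                "af": rng.uniform(0.01, 0.99, 60),
                "reference_af": rng.uniform(0.01, 0.99, 60),
                "hwe_p": 10 ** rng.uniform(-9, 0, 60),
            },
            index=pd.Index([f"v{j}" for j in range(60)], name="variant"),
        )
        variants["maf"] = np.minimum(variants["af"], 1 - variants["af"])
        filters = [reference_af_filter, maf_hwe_filter]
        results = set()
        for perm in itertools.permutations(filters):
            out = variants
            for f in perm:
                out = f(out)
            results.add(tuple(out.index))
        assert len(results) == 1

    def test_report_reconciles(self, tiny_cohort, tiny_config):
        panel = simulate.variant_panel(tiny_config)
        reference = panel[["chrom", "pos", "ref", "alt"]].copy()
        reference["af"] = panel["maf"]
        out, report = run_study_qc(tiny_cohort.genotypes["study1"], reference)
        assert report.reconciles()
        assert report.n_variants_out == out.n_variants
        assert out.n_variants > 0

    def test_qcreport_bookkeeping(self):
        r = QcReport(n_variants_in=10, n_variants_out=7)
        r.add("maf_hwe_autosome", 2)
        r.add("reference_af", 1)
        assert r.reconciles()
        r.add("reference_af", 1)
        assert not r.reconciles()


class TestAncestryFilter:
    def _cohorts(self, seed, outlier_fraction=0.1, n_variants=30_000):
        cfg = SimulationConfig(
            n_studies=1, samples_per_study=(100,), n_variants=n_variants,
            n_genes=2, panel_overlap=1.0, outlier_pop_fraction=outlier_fraction,
            outlier_fst=0.1, seed=seed,
        )
        study = simulate.simulate_genotypes(cfg, 0)
        ref, pops = simulate.simulate_reference_cohort(cfg)
        truth = set(simulate.outlier_sample_ids(cfg, 0))
        return study, ref, pops, truth

    def test_planted_outliers_removed(self):
        """Over 20 replicates at the default 30,000-variant design, >=95% of
        drifted-population (Fst ~ 0.1) samples are removed while <=2% of
        in-population samples are lost."""
        removed_out, removed_in, n_out, n_in = 0, 0, 0, 0
        for seed in range(20):
            study, ref, pops, truth = self._cohorts(seed)
            kept = set(pca_ancestry_filter(study, ref, pops, seed=seed))
            dropped = set(study.samples) - kept
            removed_out += len(dropped & truth)
            removed_in += len(dropped - truth)
            n_out += len(truth)
            n_in += study.n_samples - len(truth)
        assert removed_out / n_out >= 0.95
        assert removed_in / n_in <= 0.02

    def test_homogeneous_study_fully_retained(self):
        study, ref, pops, _ = self._cohorts(seed=77, outlier_fraction=0.0,
                                            n_variants=5000)
        kept = pca_ancestry_filter(study, ref, pops, n_variants=5000, seed=1)
        assert len(kept) == study.n_samples

    def test_deterministic_given_seed(self):
        study, ref, pops, _ = self._cohorts(seed=3, n_variants=5000)
        a = pca_ancestry_filter(study, ref, pops, n_variants=4000, seed=42)
        b = pca_ancestry_filter(study, ref, pops, n_variants=4000, seed=42)
        assert list(a) == list(b)


def test_compute_variant_stats_matches_hand_counts():
    gm = _gm([("A", "G")], [[0], [1], [1], [2]])
    stats = compute_variant_stats(gm)
    assert stats.loc["v1", "af"] == pytest.approx(0.5)
    assert stats.loc["v1", "maf"] == pytest.approx(0.5)
    assert stats.loc["v1", "hwe_p"] == pytest.approx(_hwe_enumeration(1, 2, 1), abs=1e-12)
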