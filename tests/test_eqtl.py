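"""cis-eQTL engine: window/strand conventions, OLS exactness, FDR and LD."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from liverqtl.containers import ExpressionMatrix, GenotypeMatrix
from liverqtl.eqtl import (
    AlignmentError,
    MonomorphicError,
    bh_fdr,
    build_covariates,
    compute_ld,
    define_cis_pairs,
    fit_cis_regression,
    map_all,
)
from tests.conftest import make_genotype_frame


def _genes(rows):
    return pd.DataFrame(
        rows, index=pd.Index([f"g{i + 1}" for i in range(len(rows))], name="gene")
    )


def _variants(positions, chrom="1"):
    return pd.DataFrame(
        {"chrom": chrom, "pos": positions, "ref": "A", "alt": "G"},
        index=pd.Index([f"v{j + 1}" for j in range(len(positions))], name="variant"),
    )


class TestCisPairs:
    def test_window_boundary_inclusive(self):
        genes = _genes([{"chrom": "1", "start": 2_000_000, "end": 2_010_000, "strand": "+"}])
        variants = _variants([999_999, 1_000_000, 2_000_000, 3_010_000, 3_010_001])
        pairs = define_cis_pairs(genes, variants)
        assert set(pairs["variant"]) == {"v2", "v3", "v4"}

    def test_tss_distance_plus_strand(self):
        genes = _genes([{"chrom": "1", "start": 2_000_000, "end": 2_010_000, "strand": "+"}])
        pairs = define_cis_pairs(genes, _variants([2_000_000, 1_990_000, 2_020_000]))
        d = pairs.set_index("variant")["tss_distance"]
        assert d["v1"] == 0
        assert d["v2"] == -10_000  # upstream of a + strand TSS
        assert d["v3"] == 20_000

    def test_tss_distance_minus_strand(self):
        # TSS of a - strand gene is its end coordinate; positions beyond it
        # are upstream, hence negative
        genes = _genes([{"chrom": "1", "start": 4_990_000, "end": 5_000_000, "strand": "-"}])
        pairs = define_cis_pairs(genes, _variants([5_010_000, 4_995_000]))
        d = pairs.set_index("variant")["tss_distance"]
        assert d["v1"] == -10_000
        assert d["v2"] == 5_000

    def test_other_chromosome_excluded(self):
        genes = _genes([{"chrom": "1", "start": 100, "end": 200, "strand": "+"}])
        pairs = define_cis_pairs(genes, _variants([150], chrom="2"))
        assert pairs.empty

    def test_missing_strand_rejected(self):
        genes = _genes([{"chrom": "1", "start": 100, "end": 200, "strand": None}])
        with pytest.raises(ValueError):
            define_cis_pairs(genes, _variants([150]))


class TestFitCisRegression:
    def test_noiseless_exact_fit(self):
        g = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        y = 1 + 0.5 * g
        beta, se, t, p = fit_cis_regression(y, g)
        assert beta == pytest.approx(0.5)
        assert se == 0.0
        assert p < 1e-300

    def test_matches_statsmodels(self, rng):
        for _ in range(5):
            g = rng.integers(0, 3, 30).astype(float)
            cov = rng.standard_normal((30, 2))
            y = 0.3 * g + cov @ [0.5, -0.2] + rng.standard_normal(30)
            beta, se, t, p = fit_cis_regression(y, g, cov)
            fit = sm.OLS(y, sm.add_constant(np.column_stack([cov, g]))).fit()
            assert beta == pytest.approx(fit.params[-1], abs=1e-10)
            assert se == pytest.approx(fit.bse[-1], abs=1e-10)
            assert t == pytest.approx(fit.tvalues[-1], abs=1e-8)
            assert p == pytest.approx(fit.pvalues[-1], abs=1e-10)

    def test_frisch_waugh_equivalence(self, rng):
        """Pre-orthogonalizing the dosage against covariates leaves beta
        unchanged (partialling-out equivalence)."""
        g = rng.integers(0, 3, 40).astype(float)
        cov = rng.standard_normal((40, 3))
        y = 0.4 * g + cov @ [1.0, 0.5, -0.5] + rng.standard_normal(40)
        beta_full, *_ = fit_cis_regression(y, g, cov)
        c = np.column_stack([np.ones(40), cov])
        g_orth = g - c @ np.linalg.lstsq(c, g, rcond=None)[0]
        beta_orth, *_ = fit_cis_regression(y, g_orth, cov)
        assert beta_full == pytest.approx(beta_orth, abs=1e-10)

    def test_monomorphic_and_rank_deficient_errors(self, rng):
        y = rng.standard_normal(20)
        with pytest.raises(MonomorphicError):
            fit_cis_regression(y, np.ones(20))
        cov = np.column_stack([np.arange(20.0), np.arange(20.0)])
        with pytest.raises(ValueError, match="rank deficient"):
            fit_cis_regression(y, rng.integers(0, 3, 20).astype(float), cov)

    def test_scaling_equivariance(self, rng):
        g = rng.integers(0, 3, 50).astype(float)
        y = 0.3 * g + rng.standard_normal(50)
        b1, s1, t1, p1 = fit_cis_regression(y, g)
        b2, s2, t2, p2 = fit_cis_regression(3.5 * y, g)
        assert b2 == pytest.approx(3.5 * b1, abs=1e-10)
        assert s2 == pytest.approx(3.5 * s1, abs=1e-10)
        assert t2 == pytest.approx(t1, abs=1e-10)
        assert p2 == pytest.approx(p1, abs=1e-12)


class TestBhFdr:
    def test_single_p_identity(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_step_up_oracle(self):
        q = bh_fdr([0.005, 0.009, 0.02, 0.8])
        np.testing.assert_allclose(q, [0.018, 0.018, 4 * 0.02 / 3, 0.8], atol=1e-12)

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_fdr([1.5])

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=40))
    def test_monotone_in_sorted_p_and_dominates_p(self, ps):
        q = bh_fdr(ps)
        order = np.argsort(ps)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= np.asarray(ps) - 1e-12)
        assert np.all(q <= 1 + 1e-12)

    def test_storey_never_exceeds_bh(self, rng):
        ps = rng.uniform(size=200)
        assert np.all(bh_fdr(ps, method="storey") <= bh_fdr(ps) + 1e-12)


class TestComputeLd:
    def test_identity_and_affine_invariance(self, rng):
        a = rng.integers(0, 3, 100).astype(float)
        assert compute_ld(a, a) == pytest.approx(1.0)
        assert compute_ld(a, -a + 2) == pytest.approx(1.0)

    def test_independent_dosages_near_zero(self, rng):
        a = rng.binomial(2, 0.3, 10_000).astype(float)
        b = rng.binomial(2, 0.3, 10_000).astype(float)
        assert compute_ld(a, b) < 0.001

    def test_constant_rejected(self):
        with pytest.raises(MonomorphicError):
            compute_ld(np.ones(10), np.arange(10.0))


class TestMapAll:
    def _setup(self, rng, n=120, v=60, g=4):
        gm = make_genotype_frame(rng.binomial(2, 0.3, size=(n, v)).astype(float))
        genes = _genes(
            [{"chrom": "1", "start": 1000 + 1500 * i, "end": 1500 + 1500 * i,
              "strand": "+"} for i in range(g)]
        )
        expr = pd.DataFrame(
            rng.standard_normal((n, g)), index=gm.samples, columns=genes.index
        )
        em = ExpressionMatrix(expr, pd.Series("s", index=gm.samples))
        cov = pd.DataFrame(rng.standard_normal((n, 2)), index=gm.samples,
                           columns=["age", "sex"])
        return gm, em, cov, genes

    def test_engine_equals_per_pair_fit(self, rng):
        gm, em, cov, genes = self._setup(rng)
        res = map_all(em, gm, cov, genes, window=10_000)
        assert len(res) > 0
        sample = res.sample(25, random_state=0)
        for row in sample.itertuples(index=False):
            beta, se, t, p = fit_cis_regression(
                em.values[row.gene], gm.dosages[row.variant], cov
            )
            assert row.beta == pytest.approx(beta, abs=1e-10)
            assert row.se == pytest.approx(se, abs=1e-10)
            assert row.p_value == pytest.approx(p, abs=1e-10)

    def test_empty_variant_set(self, rng):
        gm, em, cov, genes = self._setup(rng)
        empty = GenotypeMatrix(gm.dosages.iloc[:, :0], gm.variants.iloc[:0])
        res = map_all(em, empty, cov, genes)
        assert res.empty

    def test_sample_mismatch_raises(self, rng):
        gm, em, cov, genes = self._setup(rng)
        em_bad = ExpressionMatrix(
            em.values.rename(index={"s1": "zzz"}),
            pd.Series("s", index=em.values.rename(index={"s1": "zzz"}).index),
        )
        with pytest.raises(AlignmentError):
            map_all(em_bad, gm, cov, genes)

    def test_missing_dosages_mean_imputed_and_counted(self, rng):
        gm, em, cov, genes = self._setup(rng)
        gm.dosages.iloc[:30, 0] = np.nan
        res = map_all(em, gm, cov, genes, window=10_000)
        v1 = res[res["variant"] == "v1"]
        assert (v1["n_used"] == 90).all()

    def test_top_flag_unique_per_gene(self, rng):
        gm, em, cov, genes = self._setup(rng)
        res = map_all(em, gm, cov, genes, window=10_000)
        tops = res[res["top"]].groupby("gene").size()
        assert (tops == 1).all()
        for gene, sub in res.groupby("gene"):
            assert sub.loc[sub["top"], "p_value"].iloc[0] == sub["p_value"].min()


def test_build_covariates_includes_pcs(tiny_cohort):
    gm = tiny_cohort.genotypes["study1"]
    cov = build_covariates(
        tiny_cohort.covariates.loc[gm.samples], gm, n_pcs=3
    )
    assert list(cov.columns) == ["age", "sex", "PC1", "PC2", "PC3"]
    assert not cov.isna().any().any()
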