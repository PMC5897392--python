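"""Expression harmonization: transforms, probe collapsing, imputation,
quantile normalization and batch correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from liverqtl.containers import ProbeMatrix
from liverqtl.expression import (
    clamp_outliers,
    collapse_probes,
    combat_correct,
    knn_impute,
    log2_transform,
    merge_replicates,
    normalize_studies,
    quantile_normalize,
)


def _frame(arr, prefix="s"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=pd.Index([f"{prefix}{i + 1}" for i in range(arr.shape[0])], name="sample"),
        columns=[f"g{j + 1}" for j in range(arr.shape[1])],
    )


class TestLog2Transform:
    def test_closed_forms(self):
        out = log2_transform(np.array([[0.0, 1.023]]), offset=0.001)
        assert out[0, 0] == pytest.approx(np.log2(0.001))
        assert out[0, 1] == pytest.approx(np.log2(1.024))
        assert log2_transform(np.array([[1.0]]), offset=0.0)[0, 0] == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log2_transform(np.array([[-0.5]]))


class TestCollapseProbes:
    def _probes(self, values, mapping):
        vals = _frame(values)
        vals.columns = list(mapping)
        return ProbeMatrix(vals, pd.Series(mapping))

    def test_variance_weighted_mean_oracle(self):
        # p1=(1,2,3) var 1, p2=(2,4,6) var 4 -> (1.8, 3.6, 5.4)
        probes = self._probes([[1, 2], [2, 4], [3, 6]], {"p1": "gA", "p2": "gA"})
        out = collapse_probes(probes)
        np.testing.assert_allclose(out["gA"], [1.8, 3.6, 5.4])

    def test_single_probe_identity_and_equal_variance_mean(self):
        probes = self._probes(
            [[1, 10, 20], [2, 11, 23], [3, 12, 20]],
            {"p1": "gA", "p2": "gB", "p3": "gB"},
        )
        out = collapse_probes(probes)
        np.testing.assert_allclose(out["gA"], [1, 2, 3])
        # var(p2) != var(p3); weighted mean must lie between the probes
        assert ((out["gB"] - np.minimum(probes.values["p2"], probes.values["p3"])) >= 0).all()

    def test_equal_variance_reduces_to_mean(self):
        probes = self._probes([[1, 3], [2, 4], [3, 5]], {"p1": "gA", "p2": "gA"})
        np.testing.assert_allclose(collapse_probes(probes)["gA"], [2, 3, 4])

    def test_zero_variance_probes_fall_back_to_mean(self):
        probes = self._probes([[1, 5], [1, 5], [1, 5]], {"p1": "gA", "p2": "gA"})
        np.testing.assert_allclose(collapse_probes(probes)["gA"], [3, 3, 3])

    def test_invariant_to_probe_order(self, rng):
        vals = rng.standard_normal((8, 6))
        mapping = {f"p{j}": f"g{j % 2}" for j in range(6)}
        probes = self._probes(vals, mapping)
        shuffled_cols = list(rng.permutation(list(mapping)))
        probes2 = ProbeMatrix(probes.values[shuffled_cols], pd.Series(mapping))
        pd.testing.assert_frame_equal(
            collapse_probes(probes).sort_index(axis=1),
            collapse_probes(probes2).sort_index(axis=1),
        )


class TestReplicatesAndClamping:
    def test_merge_replicates(self):
        vals = _frame([[1.0], [3.0], [1.0], [2.0], [6.0]])
        groups = {"indA": ["s1", "s2"], "indB": ["s3", "s4", "s5"]}
        out = merge_replicates(vals, groups)
        assert out.loc["indA", "g1"] == 2.0
        assert out.loc["indB", "g1"] == 3.0
        with pytest.raises(ValueError):
            merge_replicates(vals, {"indC": []})

    def test_clamp_boundaries(self):
        vals = _frame([[1.9, 2.5, -2.0, 2.0, -2.1]])
        out = clamp_outliers(vals)
        np.testing.assert_array_equal(
            out.iloc[0].isna().to_numpy(), [False, True, False, False, True]
        )
        with pytest.raises(ValueError):
            clamp_outliers(vals, lo=2, hi=-2)


class TestKnnImpute:
    def test_nearest_identical_gene_copies_value(self):
        # gene B identical to A on observed samples; A missing in s3, k=1
        vals = _frame([[1.0, 1.0, 5.0], [2.0, 2.0, 6.0], [np.nan, 3.0, 7.0]])
        vals.columns = ["gA", "gB", "gC"]
        out = knn_impute(vals, k=1)
        assert out.loc["s3", "gA"] == pytest.approx(3.0)

    def test_no_missing_identity_and_large_k(self):
        vals = _frame([[1.0, 2.0], [3.0, 4.0]])
        pd.testing.assert_frame_equal(knn_impute(vals, k=10), vals)
        vals.iloc[0, 0] = np.nan
        out = knn_impute(vals, k=50)  # k larger than available genes
        assert np.isfinite(out.to_numpy()).all()

    def test_all_missing_gene_removed(self):
        vals = _frame([[np.nan, 1.0], [np.nan, 2.0]])
        out = knn_impute(vals)
        assert list(out.columns) == ["g2"]


class TestQuantileNormalize:
    def test_sort_and_average_oracle(self):
        vals = _frame([[2.0, 4.0, 6.0], [3.0, 6.0, 9.0]])
        out = quantile_normalize(vals)
        np.testing.assert_allclose(out.iloc[0], [2.5, 5.0, 7.5])
        np.testing.assert_allclose(out.iloc[1], [2.5, 5.0, 7.5])

    def test_identical_samples_unchanged(self):
        vals = _frame([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        pd.testing.assert_frame_equal(quantile_normalize(vals), vals)

    def test_ties_share_mean_of_rank_quantiles(self):
        vals = _frame([[1.0, 1.0, 5.0], [2.0, 3.0, 4.0]])
        out = quantile_normalize(vals)
        # target = (1.5, 2, 4.5); the tied pair shares (1.5 + 2) / 2
        np.testing.assert_allclose(out.iloc[0], [1.75, 1.75, 4.5])
        np.testing.assert_allclose(out.iloc[1], [1.5, 2.0, 4.5])

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_idempotent_and_distribution_identical(self, seed):
        rng = np.random.default_rng(seed)
        vals = _frame(rng.standard_normal((6, 40)))
        once = quantile_normalize(vals)
        twice = quantile_normalize(once)
        assert np.max(np.abs(once.to_numpy() - twice.to_numpy())) < 1e-10
        sorted_rows = np.sort(once.to_numpy(), axis=1)
        assert np.allclose(sorted_rows, sorted_rows[0])


class TestCombat:
    def test_single_batch_identity(self, rng):
        vals = _frame(rng.standard_normal((10, 20)))
        batch = pd.Series("A", index=vals.index)
        out = combat_correct(vals, batch)
        np.testing.assert_allclose(out.to_numpy(), vals.to_numpy(), atol=1e-8)

    def test_removes_planted_location_shift(self, rng):
        vals = _frame(rng.standard_normal((50, 200)))
        batch = pd.Series(["A"] * 25 + ["B"] * 25, index=vals.index)
        shifted = vals.copy()
        shifted.loc[batch == "B"] += 2.0
        out = combat_correct(shifted, batch)
        resid = (out[batch == "A"].mean() - out[batch == "B"].mean()).mean()
        assert abs(resid) < 0.05

    def test_removes_planted_scale(self, rng):
        vals = _frame(rng.standard_normal((50, 200)))
        batch = pd.Series(["A"] * 25 + ["B"] * 25, index=vals.index)
        scaled = vals.copy()
        b = scaled.loc[batch == "B"]
        scaled.loc[batch == "B"] = (b - b.mean()) * 3.0 + b.mean()
        out = combat_correct(scaled, batch)
        ratio = (out[batch == "B"].var() / out[batch == "A"].var()).mean()
        assert 0.8 <= ratio <= 1.25

    def test_preserves_grand_means_on_balanced_design(self, rng):
        """Empirical-Bayes shrinkage perturbs gene means only at the scale of
        the shrunk batch estimates, so grand means survive the correction up
        to that (small) wobble on a balanced null design."""
        vals = _frame(rng.standard_normal((40, 60)))
        batch = pd.Series(["A"] * 20 + ["B"] * 20, index=vals.index)
        out = combat_correct(vals, batch)
        shift = np.abs(out.mean() - vals.mean())
        assert shift.mean() < 0.01
        assert shift.max() < 0.05

    def test_small_batch_rejected(self, rng):
        vals = _frame(rng.standard_normal((5, 10)))
        batch = pd.Series(["A"] * 4 + ["B"], index=vals.index)
        with pytest.raises(ValueError, match="batches with <2"):
            combat_correct(vals, batch)


def test_full_normalization_chain(tiny_cohort):
    """End-to-end: merged studies come out complete, distribution-aligned
    and batch-balanced."""
    out = normalize_studies(tiny_cohort.expression, knn_k=5)
    assert out.is_complete()
    sorted_rows = np.sort(out.values.to_numpy(), axis=1)
    # quantile normalization ran before ComBat, so rows are no longer exactly
    # identical, but per-study means must be close after correction
    means = out.values.groupby(out.study).mean()
    spread = (means.max() - means.min()).mean()
    assert spread < 0.25
    assert sorted_rows.shape == out.values.shape
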