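import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vesselmark import (
    ExpressionMatrix,
    ValidationError,
    filter_missingness,
    merge_platforms,
    standardize_genes,
)


def matrix(data: dict, genes: list[str]) -> ExpressionMatrix:
    return ExpressionMatrix(pd.DataFrame(data, index=genes, dtype=float))


class TestMerge:
    def test_union_of_identical_gene_sets(self):
        m1 = matrix({"a1": [1, 2], "a2": [3, 4]}, ["g1", "g2"])
        m2 = matrix({"b1": [5, 6], "b2": [7, 8], "b3": [9, 0]}, ["g1", "g2"])
        merged = merge_platforms({"P1": m1, "P2": m2})
        assert merged.shape == (2, 5)
        assert not merged.values.isna().any().any()

    def test_platform_absent_gene_is_missing(self):
        m1 = matrix({"a1": [1, 2]}, ["g1", "g2"])
        m2 = matrix({"b1": [5]}, ["g1"])
        merged = merge_platforms({"P1": m1, "P2": m2})
        assert np.isnan(merged.values.loc["g2", "b1"])
        assert merged.values.loc["g2", "a1"] == 2

    def test_multi_probe_collapse_by_mean(self):
        m = matrix({"a1": [4.0, 6.0]}, ["probeA", "probeB"])
        merged = merge_platforms([m], gene_map={"probeA": "GENE", "probeB": "GENE"})
        assert merged.values.loc["GENE", "a1"] == 5.0

    def test_collapse_ignores_missing(self):
        m = matrix({"a1": [4.0, np.nan]}, ["probeA", "probeB"])
        merged = merge_platforms([m], gene_map={"probeA": "GENE", "probeB": "GENE"})
        assert merged.values.loc["GENE", "a1"] == 4.0

    def test_duplicate_sample_across_platforms_rejected(self):
        m1 = matrix({"s": [1]}, ["g1"])
        m2 = matrix({"s": [2]}, ["g1"])
        with pytest.raises(ValidationError, match="duplicate sample"):
            merge_platforms({"P1": m1, "P2": m2})

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError, match="no matrices"):
            merge_platforms({})


class TestFilter:
    @pytest.mark.parametrize("n_obs, kept", [(4, True), (3, False), (10, True)])
    def test_forty_percent_boundary_inclusive(self, n_obs, kept):
        row = [1.0 * i for i in range(n_obs)] + [np.nan] * (10 - n_obs)
        m = ExpressionMatrix(
            pd.DataFrame([row], index=["g"], columns=[f"s{i}" for i in range(10)])
        )
        out = filter_missingness(m, 0.40)
        assert ("g" in out.gene_ids) is kept

    def test_fully_observed_is_identity(self, small_matrix):
        full = ExpressionMatrix(small_matrix.values.dropna())
        assert filter_missingness(full, 0.40).values.equals(full.values)

    def test_samples_unchanged_and_provenance_recorded(self):
        m = ExpressionMatrix(
            pd.DataFrame(
                {"s1": [1.0, np.nan], "s2": [2.0, np.nan], "s3": [3.0, 1.0]},
                index=["keep", "drop"],
            )
        )
        prov = []
        out = filter_missingness(m, 0.40, provenance=prov)
        assert out.sample_ids == m.sample_ids
        assert out.gene_ids == ["keep"]
        assert prov == [("drop", "filter_missingness", "observed fraction < 0.4")]


class TestStandardize:
    def test_hand_example(self):
        m = matrix({"s1": [1.0], "s2": [2.0], "s3": [3.0]}, ["g"])
        out = standardize_genes(m)
        assert list(out.values.loc["g"]) == [-1.0, 0.0, 1.0]

    def test_constant_gene_dropped_with_reason(self):
        m = matrix({"s1": [5.0, 1.0], "s2": [5.0, 2.0], "s3": [5.0, 3.0]}, ["flat", "g"])
        out = standardize_genes(m)
        assert out.gene_ids == ["g"]
        assert ("flat", "standardize_genes", "zero variance") in out.provenance

    def test_single_observation_dropped(self):
        m = ExpressionMatrix(
            pd.DataFrame({"s1": [1.0], "s2": [np.nan], "s3": [np.nan]}, index=["g"])
        )
        out = standardize_genes(m)
        assert out.gene_ids == []
        assert out.provenance[0][2] == "fewer than 2 observed values"

    def test_missing_propagates(self):
        m = ExpressionMatrix(
            pd.DataFrame({"s1": [1.0], "s2": [np.nan], "s3": [3.0], "s4": [5.0]}, index=["g"])
        )
        out = standardize_genes(m)
        assert np.isnan(out.values.loc["g", "s2"])
        assert out.values.loc["g"].count() == 3

    def test_median_zero_sd_one_invariants(self, small_matrix):
        out = standardize_genes(filter_missingness(small_matrix, 0.4))
        med = out.values.median(axis=1)
        sd = out.values.std(axis=1, ddof=1)
        assert np.abs(med).max() < 1e-9
        assert np.abs(sd - 1).max() < 1e-9

    def test_idempotent(self, small_matrix):
        once = standardize_genes(small_matrix)
        twice = standardize_genes(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    @given(
        st.lists(
            st.integers(min_value=-100, max_value=100).map(float),
            min_size=3,
            max_size=12,
            unique=True,
        ),
        st.floats(min_value=-1000, max_value=1000, allow_nan=False),
    )
    def test_shift_invariance(self, values, shift):
        cols = [f"s{i}" for i in range(len(values))]
        base = ExpressionMatrix(pd.DataFrame([values], index=["g"], columns=cols))
        shifted = ExpressionMatrix(pd.DataFrame([[v + shift for v in values]], index=["g"], columns=cols))
        a = standardize_genes(base).values
        b = standardize_genes(shifted).values
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-7)

    def test_even_count_median_is_midpoint(self):
        m = matrix({"s1": [1.0], "s2": [2.0], "s3": [4.0], "s4": [5.0]}, ["g"])
        out = standardize_genes(m)
        # median 3, sd = sqrt(10/3)
        sd = np.sqrt(10 / 3)
        assert out.values.loc["g", "s1"] == pytest.approx(-2 / sd)


class TestPlatformEffectRemoval:
    def test_standardization_shrinks_blockwise_offsets(self):
        # one gene, two equal-size platform blocks with a constant additive
        # offset between them: after median/SD scaling the block means must
        # differ by less than the raw offset
        rng = np.random.default_rng(0)
        offset = 3.0
        block1 = rng.normal(7.0, 0.5, size=10)
        block2 = rng.normal(7.0, 0.5, size=10) + offset
        cols = [f"s{i}" for i in range(20)]
        m = ExpressionMatrix(
            pd.DataFrame([np.concatenate([block1, block2])], index=["g"], columns=cols)
        )
        out = standardize_genes(m).values.loc["g"].to_numpy()
        gap = abs(out[:10].mean() - out[10:].mean())
        assert gap < offset

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(5, 8))
        values[0, 3] = np.nan
        cols = [f"s{i}" for i in range(8)]
        genes = [f"g{i}" for i in range(5)]
        m = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=cols))
        perm = ["s3", "s7", "s0", "s1", "s5", "s2", "s6", "s4"]
        direct = standardize_genes(filter_missingness(m)).values[perm]
        permuted = standardize_genes(
            filter_missingness(ExpressionMatrix(m.values[perm]))
        ).values
        pd.testing.assert_frame_equal(direct, permuted)
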