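import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from vesselmark import (
    ExpressionMatrix,
    SampleAnnotation,
    SimulationConfig,
    ValidationError,
    differential_table,
    generate_dataset,
    log2_fold_change,
    robust_fdr,
    significant_genes,
    welch_t,
)

groups = st.lists(
    st.floats(min_value=-50, max_value=50, allow_nan=False).map(lambda x: round(x, 4)),
    min_size=2,
    max_size=15,
)


class TestWelch:
    def test_identical_groups_null(self):
        t, df, p = welch_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0
        assert p == 1.0

    def test_hand_example(self):
        # equal variances, equal n=3: t = -3/sqrt(2/3), df = 4
        t, df, p = welch_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3 / np.sqrt(2 / 3), abs=1e-12)
        assert df == pytest.approx(4.0, abs=1e-12)
        assert p == pytest.approx(0.0213, abs=5e-4)

    @given(groups, groups)
    def test_matches_scipy(self, a, b):
        t, df, p = welch_t(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        if np.isnan(t):
            # degenerate: both groups constant at different levels
            assert np.var(a) == 0 and np.var(b) == 0
        elif t == 0.0 and np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
            pass  # identical constant groups: scipy returns nan, we define p=1
        else:
            assert t == pytest.approx(ref.statistic, rel=1e-9)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    @given(groups, groups)
    def test_antisymmetry(self, a, b):
        t1, _, p1 = welch_t(a, b)
        t2, _, p2 = welch_t(b, a)
        if not np.isnan(t1):
            assert t2 == pytest.approx(-t1, abs=1e-12)
            assert p2 == pytest.approx(p1, abs=1e-12)

    def test_small_group_untestable(self):
        t, df, p = welch_t([1.0], [1, 2, 3])
        assert np.isnan(p)

    def test_constant_groups_unequal_means_untestable(self):
        t, df, p = welch_t([2, 2, 2], [3, 3, 3])
        assert np.isnan(t) and np.isnan(p)


class TestFoldChange:
    @pytest.mark.parametrize(
        "a, b, expected",
        [([8, 8], [7, 7], 1.0), ([5, 5], [5, 5], 0.0), ([7.0], [8.5], -1.5)],
    )
    def test_log2_differences(self, a, b, expected):
        assert log2_fold_change(a, b) == pytest.approx(expected)

    def test_empty_group_missing(self):
        assert np.isnan(log2_fold_change([], [1, 2]))

    def test_missing_values_ignored(self):
        assert log2_fold_change([4.0, np.nan], [1.0, 3.0]) == pytest.approx(2.0)


class TestRobustFdr:
    def test_saturated_null(self):
        r = robust_fdr([1.0, 1.0, 1.0])
        assert r.pi0 == 1.0
        assert (r.q_values == 1.0).all()

    def test_hand_example(self):
        r = robust_fdr([0.01, 0.02, 0.5, 0.9])
        assert r.pi0 == pytest.approx(0.715)
        assert r.q_values == pytest.approx([0.0286, 0.0286, 0.476667, 0.6435], abs=1e-4)

    def test_uniform_null_pi0_near_one(self):
        rng = np.random.default_rng(5)
        p = rng.random(10_000)
        r = robust_fdr(p)
        # pi0 = min(1, 2*mean(p)); under U(0,1), 2*mean has SE 2/sqrt(12n)
        se = 2.0 / np.sqrt(12 * p.size)
        assert r.pi0 >= min(1.0, 1.0 - 3 * se)
        assert (r.q_values <= 0.05).mean() <= 0.05 + 3 / np.sqrt(p.size)

    def test_bh_option_matches_statsmodels(self):
        rng = np.random.default_rng(7)
        p = rng.beta(0.4, 3.0, size=500)
        ours = robust_fdr(p, pi0=1.0).q_values
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, ref, atol=1e-12)

    def test_robust_q_is_pi0_scaled_bh(self):
        rng = np.random.default_rng(8)
        p = rng.random(200)
        r = robust_fdr(p)
        ref = np.minimum(multipletests(p, method="fdr_bh")[1] * r.pi0, 1.0)
        assert np.allclose(r.q_values, ref, atol=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=60))
    def test_monotone_in_p(self, pvals):
        q = robust_fdr(pvals).q_values
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()
        assert ((q >= 0) & (q <= 1)).all()

    @pytest.mark.parametrize("bad", [[-0.1], [1.5], [np.nan]])
    def test_rejects_invalid_p(self, bad):
        with pytest.raises(ValidationError):
            robust_fdr(bad)


def make_matrix(array, prefix_a="a", prefix_b="b", n_a=None):
    n_a = n_a if n_a is not None else array.shape[1] // 2
    cols = [f"{prefix_a}{i}" for i in range(n_a)] + [
        f"{prefix_b}{i}" for i in range(array.shape[1] - n_a)
    ]
    genes = [f"g{i}" for i in range(array.shape[0])]
    m = ExpressionMatrix(pd.DataFrame(array, index=genes, columns=cols))
    anns = [SampleAnnotation(c, "GPL570", "BEC", frozenset("A"), "s") for c in cols[:n_a]] + [
        SampleAnnotation(c, "GPL570", "LEC", frozenset("A"), "s") for c in cols[n_a:]
    ]
    return m, anns


class TestDifferentialTable:
    def test_null_matrix_calls_almost_nothing(self):
        rng = np.random.default_rng(2)
        m, anns = make_matrix(rng.normal(7, 1, size=(500, 24)), n_a=14)
        table = differential_table(m, anns)
        assert table["significant"].sum() <= 0.05 * len(table) + 5

    def test_planted_marker_called_with_direction(self):
        rng = np.random.default_rng(3)
        x = rng.normal(7, 0.5, size=(200, 24))
        x[0, :14] += 2.0  # 4-fold up in class A
        m, anns = make_matrix(x, n_a=14)
        table = differential_table(m, anns)
        assert bool(table.loc["g0", "significant"])
        assert table.loc["g0", "direction"] == "A_UP"
        assert "g0" in significant_genes(table, "A_UP")

    def test_gene_in_one_class_untestable(self):
        x = np.random.default_rng(4).normal(size=(3, 8))
        x[0, 4:] = np.nan  # no LEC observations
        m, anns = make_matrix(x, n_a=4)
        table = differential_table(m, anns)
        assert bool(table.loc["g0", "untestable"])
        assert np.isnan(table.loc["g0", "q"])
        assert not table.loc["g0", "significant"]

    def test_significance_invariant(self):
        rng = np.random.default_rng(6)
        x = rng.normal(7, 0.5, size=(300, 20))
        x[:30, :10] += rng.uniform(0.5, 3, size=(30, 1))
        m, anns = make_matrix(x, n_a=10)
        table = differential_table(m, anns, fc_threshold=2.0, q_threshold=0.05)
        testable = ~table["untestable"]
        expected = testable & (table["log2fc"].abs() >= 1.0) & (table["q"] <= 0.05)
        assert (table["significant"] == expected).all()
        up = table["significant"] & (table["log2fc"] > 0)
        assert (table.loc[up, "direction"] == "A_UP").all()
        assert (table.loc[~table["significant"], "direction"] == "NONE").all()

    def test_permuting_samples_within_class_changes_nothing(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(50, 12))
        m, anns = make_matrix(x, n_a=6)
        t1 = differential_table(m, anns)
        perm_cols = ["a3", "a1", "a0", "a5", "a4", "a2", "b2", "b0", "b1", "b3", "b5", "b4"]
        t2 = differential_table(ExpressionMatrix(m.values[perm_cols]), anns)
        pd.testing.assert_frame_equal(t1, t2)

    def test_missing_class_is_error(self):
        m, anns = make_matrix(np.zeros((2, 4)), n_a=2)
        with pytest.raises(ValidationError, match="HMEC1"):
            differential_table(m, anns, class_a="HMEC1", class_b="LEC")

    def test_matches_scalar_path(self):
        # the vectorized table must agree with the scalar welch_t / fold
        # change / robust_fdr route gene by gene
        rng = np.random.default_rng(10)
        x = rng.normal(7, 1, size=(40, 10))
        x[rng.random(x.shape) < 0.1] = np.nan
        m, anns = make_matrix(x, n_a=5)
        table = differential_table(m, anns)
        ps = {}
        for g in m.gene_ids:
            a = m.values.loc[g, [c for c in m.sample_ids if c.startswith("a")]]
            b = m.values.loc[g, [c for c in m.sample_ids if c.startswith("b")]]
            t, df, p = welch_t(a, b)
            fc = log2_fold_change(a, b)
            if np.isnan(t):
                assert bool(table.loc[g, "untestable"])
            else:
                assert table.loc[g, "t_stat"] == pytest.approx(t, rel=1e-9)
                assert table.loc[g, "df"] == pytest.approx(df, rel=1e-9)
                assert table.loc[g, "p"] == pytest.approx(p, rel=1e-9)
                ps[g] = p
            if not (np.isnan(fc) and np.isnan(table.loc[g, "log2fc"])):
                assert table.loc[g, "log2fc"] == pytest.approx(fc, rel=1e-9)
        ref_q = robust_fdr(list(ps.values())).q_values
        ours = table.loc[list(ps), "q"].to_numpy()
        assert np.allclose(ours, ref_q, atol=1e-12)
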