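"""DTK pairwise comparisons, TMM, dispersion, NB exact test, BH, intersection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binomtest, studentized_range, t as tdist

from mrequant.stats import (
    GroupDesign,
    bh_adjust,
    de_exact_test,
    dtk_pairwise,
    estimate_common_dispersion,
    intersect_selections,
    nb_exact_test,
    select_target_specific,
    tmm_factors,
)


def _values(data_by_group):
    """rows x samples frame from {group: 2D array (rows x n_i)}."""
    cols, mats, s2g = [], [], {}
    for g, mat in data_by_group.items():
        mat = np.atleast_2d(np.asarray(mat, dtype=float))
        for j in range(mat.shape[1]):
            cols.append(f"{g}_s{j}")
            s2g[f"{g}_s{j}"] = g
        mats.append(mat)
    df = pd.DataFrame(np.hstack(mats), columns=cols)
    return df, s2g


class TestDTK:
    def test_identical_constant_groups_nothing_significant(self):
        df, s2g = _values({g: np.ones((5, 4)) for g in "abc"})
        res = dtk_pairwise(df, s2g)
        assert not res.significant.to_numpy().any()
        assert not res.degenerate.to_numpy().any()

    def test_k2_equal_variance_matches_t_interval(self, rng):
        # with k=2 and equal n, s2: q(alpha,2,v) = sqrt(2) t_{alpha/2,v}, so the
        # DTK half-width equals the two-sample unpooled t half-width
        a = rng.normal(size=(50, 8))
        b = rng.normal(size=(50, 8))
        df, s2g = _values({"a": a, "b": b})
        res = dtk_pairwise(df, s2g, alpha=0.05)
        se = np.sqrt(a.var(axis=1, ddof=1) / 8 + b.var(axis=1, ddof=1) / 8)
        # Dunnett's C with equal df reduces to q*(alpha,2,7): compare to t on
        # the rows where both group variances are equal-df (always here)
        q = studentized_range.ppf(0.95, 2, 7)
        expected = q * se / np.sqrt(2)
        assert np.allclose(res.halfwidth.iloc[:, 0].to_numpy(), expected)
        assert np.allclose(q, np.sqrt(2) * tdist.ppf(0.975, 7), rtol=1e-10)

    def test_zero_variance_degenerate_flagging(self):
        df, s2g = _values({"a": [[1.0, 1.0, 1.0]], "b": [[2.0, 2.0, 2.0]]})
        res = dtk_pairwise(df, s2g)
        assert res.significant.iloc[0, 0] and res.degenerate.iloc[0, 0]
        df2, s2g2 = _values({"a": [[1.0, 1.0, 1.0]], "b": [[1.0, 1.0, 1.0]]})
        res2 = dtk_pairwise(df2, s2g2)
        assert not res2.significant.iloc[0, 0]

    def test_group_too_small_rejected(self):
        df, s2g = _values({"a": [[1.0]], "b": [[1.0, 2.0]]})
        with pytest.raises(ValueError, match="n="):
            dtk_pairwise(df, s2g)


class TestSelectTargetSpecific:
    def _res(self, shifts, n=6, scale=1e-3, rng=None):
        rng = rng or np.random.default_rng(0)
        data = {
            g: shift + scale * rng.normal(size=(1, n)) for g, shift in shifts.items()
        }
        df, s2g = _values(data)
        return dtk_pairwise(df, s2g)

    def test_target_shifted_against_all_included(self):
        res = self._res({"t": 5.0, "a": 0.0, "b": 0.0, "c": 0.0})
        assert select_target_specific(res, "t").iloc[0]

    def test_target_equal_to_one_group_excluded(self):
        res = self._res({"t": 5.0, "a": 5.0, "b": 0.0, "c": 0.0})
        assert not select_target_specific(res, "t").iloc[0]

    def test_sign_inconsistency_excluded(self):
        res = self._res({"t": 5.0, "a": 0.0, "b": 0.0, "c": 10.0})
        assert not select_target_specific(res, "t").iloc[0]


class TestTMM:
    def test_identical_columns_unit_factors(self, rng):
        c = pd.DataFrame(np.tile(rng.poisson(50, size=(200, 1)), (1, 3)),
                         columns=list("abc"))
        f = tmm_factors(c)
        assert np.allclose(f, 1.0)

    def test_doubled_column(self, rng):
        base = rng.poisson(100, size=500)
        c = pd.DataFrame({"a": base, "b": 2 * base})
        f = tmm_factors(c, lib_sizes=pd.Series({"a": 1e6, "b": 1e6}), reference="a")
        assert np.allclose(f.to_numpy(), [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-6)

    def test_row_permutation_invariance(self, rng):
        c = pd.DataFrame(rng.poisson(40, size=(300, 4)), columns=list("abcd"))
        f1 = tmm_factors(c)
        f2 = tmm_factors(c.sample(frac=1.0, random_state=5))
        assert np.allclose(f1.to_numpy(), f2.to_numpy())

    def test_geometric_mean_is_one(self, rng):
        c = pd.DataFrame(rng.poisson(40, size=(300, 5)))
        f = tmm_factors(c)
        assert np.isclose(np.exp(np.mean(np.log(f))), 1.0)


class TestDispersion:
    def test_constant_counts_zero(self):
        c = pd.DataFrame(np.full((50, 8), 20))
        assert estimate_common_dispersion(c, list(range(4)), list(range(4, 8))) == 0.0

    def test_poisson_counts_near_zero(self, rng):
        c = pd.DataFrame(rng.poisson(100, size=(200, 26)))
        phi = estimate_common_dispersion(c, list(range(13)), list(range(13, 26)))
        assert phi <= 0.05

    def test_nb_counts_recovered(self, rng):
        r = 1 / 0.2
        c = pd.DataFrame(rng.negative_binomial(r, r / (r + 100), size=(2000, 26)))
        phi = estimate_common_dispersion(c, list(range(13)), list(range(13, 26)))
        assert 0.1 <= phi <= 0.3


class TestNBExactTest:
    def test_symmetry_gives_p_one(self):
        p, lfc = nb_exact_test(np.array([10, 10]), np.array([10, 10]), 0.1)
        assert p == pytest.approx(1.0) and lfc == 0.0

    def test_empty_row(self):
        p, lfc = nb_exact_test(np.zeros(3), np.zeros(3), 0.2)
        assert p == 1.0 and lfc == 0.0

    @pytest.mark.parametrize("T,N", [(30, 12), (7, 7), (55, 48), (3, 0)])
    def test_poisson_limit_matches_binomial_exact(self, T, N):
        p, _ = nb_exact_test(np.array([T]), np.array([N]), 0.0)
        assert p == pytest.approx(binomtest(T, T + N, 0.5).pvalue, abs=1e-10)

    def test_extreme_split_tiny_p(self):
        p, lfc = nb_exact_test(np.array([100]), np.array([0]), 0.0)
        assert p < 1e-25 and lfc > 0

    def test_dispersion_widens_the_null(self):
        t, n = np.array([150, 130]), np.array([100, 90])
        p0, _ = nb_exact_test(t, n, 0.0)
        p2, _ = nb_exact_test(t, n, 0.5)
        assert p2 > p0


class TestBH:
    def test_stepup_examples(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        assert np.allclose(bh_adjust([0.2]), [0.2])
        assert np.allclose(bh_adjust([0.1, 0.1, 0.1]), [0.1, 0.1, 0.1])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(
        ps=st.lists(st.floats(0, 1), min_size=2, max_size=20),
        idx=st.integers(0, 19),
        bump=st.floats(0, 1),
    )
    @settings(max_examples=100, derandomize=True)
    def test_monotone_in_each_p(self, ps, idx, bump):
        idx = idx % len(ps)
        q1 = bh_adjust(ps)
        ps2 = list(ps)
        ps2[idx] = min(1.0, ps2[idx] + bump)
        q2 = bh_adjust(ps2)
        assert q2[idx] >= q1[idx] - 1e-12


class TestIntersection:
    def test_set_logic(self):
        sel = intersect_selections({"a", "b", "c"}, {"b", "c", "d"})
        assert sel.specific_set == {"b", "c"}
        assert sel.counts == {"dtk": 3, "de": 3, "intersection": 2}

    def test_empty(self):
        assert intersect_selections({"a"}, set()).specific_set == set()


class TestGroupDesign:
    def test_reference_group_inferred(self):
        d = GroupDesign(["TN_tumor", "TN_normal"], {"s1": "TN_tumor", "s2": "TN_normal"},
                        "TN_tumor")
        assert d.de_reference_group == "TN_normal"

    def test_unknown_target_rejected(self):
        with pytest.raises(ValueError):
            GroupDesign(["a", "b"], {}, "z")


class TestDEPipeline:
    def test_planted_fold_change_detected(self, rng):
        # 100 null rows plus 10 rows at 8x in 'tumor'
        n = 13
        base = rng.negative_binomial(5, 5 / (5 + 50), size=(110, 2 * n))
        base[:10, :n] = rng.negative_binomial(5, 5 / (5 + 400), size=(10, n))
        counts = pd.DataFrame(base, columns=[f"s{i}" for i in range(2 * n)])
        counts.index = pd.MultiIndex.from_tuples(
            [(f"g{i}", "m") for i in range(110)], names=["gene_id", "family_id"]
        )
        from mrequant.quantify import MRECountMatrix, SampleLibrary

        libs = [SampleLibrary(f"s{i}", "t" if i < n else "n", int(counts[f"s{i}"].sum()))
                for i in range(2 * n)]
        mx = MRECountMatrix(counts, libs)
        de = de_exact_test(mx, [f"s{i}" for i in range(n)], [f"s{i}" for i in range(n, 2 * n)])
        flags = de.selected(fdr=0.05, min_abs_lfc=2.0)
        planted = flags.iloc[:10]
        null = flags.iloc[10:]
        assert planted.mean() >= 0.9
        assert null.mean() <= 0.05
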