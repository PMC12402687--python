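"""Fibre-filtering statistics, profiles and their comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from axonmetrics.fibers import Fiber, MIRROR_ID_OFFSET, PathwayAtlas
from axonmetrics.group_stats import (FiberFilter, StatsError,
                                     compare_correlation_sets,
                                     compare_profiles_spearman, fiber_ttest,
                                     fold_mirrored_matrix, pathway_profile,
                                     prevalence_filter,
                                     top_fiber_distribution,
                                     weighted_fiber_ttest,
                                     weighted_odds_ratio)


def atlas_of(n_per_pathway):
    fibers, fid = [], 0
    for pathway, n in n_per_pathway.items():
        for _ in range(n):
            fibers.append(
                Fiber(fid, [[fid, 0, 0], [fid, 0, 5]], pathway, "right")
            )
            fid += 1
    return PathwayAtlas.from_fibers(fibers)


class TestPathwayProfile:
    def test_three_of_ten(self):
        atlas = atlas_of({"a": 10})
        acts = {i: 1.0 for i in range(3)}
        assert pathway_profile(atlas, acts) == {"a": 30.0}

    def test_none_activated(self):
        atlas = atlas_of({"a": 4, "b": 2})
        assert pathway_profile(atlas, {}) == {"a": 0.0, "b": 0.0}

    def test_cutoff_boundary_closed(self):
        atlas = atlas_of({"a": 2})
        assert pathway_profile(atlas, {0: 0.5, 1: 0.49}) == {"a": 50.0}

    def test_unknown_fiber_id(self):
        atlas = atlas_of({"a": 2})
        with pytest.raises(StatsError):
            pathway_profile(atlas, {99: 1.0})


class TestSpearman:
    def test_identical_profiles(self):
        p = {"a": 10.0, "b": 20.0, "c": 30.0}
        c = compare_profiles_spearman(p, p)
        assert c.rho == pytest.approx(1.0)

    def test_rank_reversed(self):
        a = {"a": 10.0, "b": 20.0, "c": 30.0, "d": 40.0}
        b = {"a": 40.0, "b": 30.0, "c": 20.0, "d": 10.0}
        assert compare_profiles_spearman(a, b).rho == pytest.approx(-1.0)

    def test_worked_example_rho(self):
        # brute-force rank correlation: a = [10,20,30,40] ranks [1,2,3,4],
        # b = [15,10,45,40] ranks [2,1,4,3]; d = [-1,1,-1,1],
        # rho = 1 - 6*sum(d^2)/(n(n^2-1)) = 1 - 24/60 = 0.6; cross-checked
        # against Pearson on the rank vectors
        a = {"p1": 10.0, "p2": 20.0, "p3": 30.0, "p4": 40.0}
        b = {"p1": 15.0, "p2": 10.0, "p3": 45.0, "p4": 40.0}
        ranks_a = sps.rankdata([a[k] for k in sorted(a)])
        ranks_b = sps.rankdata([b[k] for k in sorted(b)])
        expected = np.corrcoef(ranks_a, ranks_b)[0, 1]
        got = compare_profiles_spearman(a, b)
        assert got.rho == pytest.approx(expected, abs=1e-12)
        assert got.rho == pytest.approx(0.6)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 100, 6)
        a = {f"p{i}": v for i, v in enumerate(vals)}
        b = {f"p{i}": rng.uniform(0, 100) for i in range(6)}
        base = compare_profiles_spearman(a, b).rho
        warped = {k: np.exp(v / 30.0) for k, v in a.items()}
        assert compare_profiles_spearman(warped, b).rho == pytest.approx(
            base, abs=1e-12
        )

    def test_key_mismatch(self):
        with pytest.raises(StatsError):
            compare_profiles_spearman({"a": 1.0, "b": 2.0, "c": 3.0},
                                      {"a": 1.0, "b": 2.0, "d": 3.0})

    def test_constant_profile_undefined(self):
        with pytest.raises(StatsError):
            compare_profiles_spearman({"a": 5.0, "b": 5.0, "c": 5.0},
                                      {"a": 1.0, "b": 2.0, "c": 3.0})


class TestCorrelationSets:
    def test_identical_lists(self):
        t, p = compare_correlation_sets([0.2, 0.5, 0.8], [0.2, 0.5, 0.8])
        assert t == 0.0 and p == 1.0

    def test_worked_example(self):
        # hand evaluation: d_i = atanh(a_i) - atanh(b_i),
        # t = mean(d) / (sd(d)/sqrt(3))
        a, b = [0.5, 0.6, 0.7], [0.4, 0.5, 0.6]
        d = np.arctanh(a) - np.arctanh(b)
        expected = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        t, p = compare_correlation_sets(a, b)
        assert t == pytest.approx(expected, rel=1e-12)
        assert 0 < p < 1

    def test_unit_correlation_needs_clamp(self):
        with pytest.raises(StatsError):
            compare_correlation_sets([1.0, 0.5, 0.2], [0.3, 0.2, 0.1])
        t, _ = compare_correlation_sets([1.0, 0.5, 0.2], [0.3, 0.2, 0.1],
                                        clamp=True)
        assert np.isfinite(t)


class TestPrevalenceFilter:
    def _matrix(self, n_act, n_stim=30):
        col = np.zeros(n_stim)
        col[:n_act] = 1.0
        return pd.DataFrame({7: col})

    def test_exactly_20_percent_included(self):
        assert prevalence_filter(self._matrix(6)) == [7]

    def test_below_20_percent_excluded(self):
        assert prevalence_filter(self._matrix(5)) == []

    def test_always_activated_excluded(self):
        assert prevalence_filter(self._matrix(30)) == []
        assert prevalence_filter(self._matrix(29)) == []  # only 1 non-act

    def test_probabilistic_cutoff(self):
        col = np.full(30, 0.49)
        col[:10] = 0.51
        assert prevalence_filter(pd.DataFrame({1: col})) == [1]


class TestFiberTTest:
    def test_worked_example(self):
        # activated outcomes {60,50,40}, non-activated {20,30,10}:
        # means 50/20, pooled sd 10 -> T = 30 / (10 sqrt(2/3)) = 3.674
        mat = pd.DataFrame({0: [1, 1, 1, 0, 0, 0]}, dtype=float)
        outcomes = [60, 50, 40, 20, 30, 10]
        s = fiber_ttest(mat, outcomes)[0]
        assert s.t_value == pytest.approx(3.674, abs=1e-3)
        assert (s.n_act, s.n_nonact) == (3, 3)

    def test_matches_scipy_pooled(self):
        rng = np.random.default_rng(4)
        mat = pd.DataFrame(
            rng.integers(0, 2, (20, 5)).astype(float),
            columns=range(5),
        )
        y = rng.normal(30, 10, 20)
        for s in fiber_ttest(mat, y):
            if not s.defined:
                continue
            col = mat[s.fiber_id].to_numpy()
            ref = sps.ttest_ind(y[col == 1], y[col == 0],
                                equal_var=True).statistic
            assert s.t_value == pytest.approx(ref, rel=1e-12)

    def test_equal_means_zero_t(self):
        mat = pd.DataFrame({0: [1, 1, 0, 0]}, dtype=float)
        s = fiber_ttest(mat, [40, 20, 40, 20])[0]
        assert s.t_value == pytest.approx(0.0, abs=1e-12)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(8)
        mat = pd.DataFrame({0: [1, 0, 1, 0, 1, 0], 1: [0, 0, 1, 1, 0, 1]},
                           dtype=float)
        y = rng.normal(30, 10, 6)
        perm = rng.permutation(6)
        base = fiber_ttest(mat, y)
        shuffled = fiber_ttest(mat.iloc[perm].reset_index(drop=True), y[perm])
        for a, b in zip(base, shuffled):
            assert a.t_value == pytest.approx(b.t_value, rel=1e-12)

    def test_rejects_non_binary(self):
        with pytest.raises(StatsError):
            fiber_ttest(pd.DataFrame({0: [0.5, 1.0]}), [1, 2])


class TestWeightedTTest:
    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 10**6))
    def test_reduces_to_binary(self, seed):
        rng = np.random.default_rng(seed)
        mat = pd.DataFrame(
            rng.integers(0, 2, (16, 4)).astype(float), columns=range(4)
        )
        y = rng.normal(30, 12, 16)
        wt = weighted_fiber_ttest(mat, y)
        bt = fiber_ttest(mat, y)
        for a, b in zip(wt, bt):
            if a.defined and b.defined:
                assert a.t_value == pytest.approx(b.t_value, abs=1e-12)

    def test_uniform_half_weights_zero_t(self):
        mat = pd.DataFrame({0: [0.5] * 8})
        y = np.arange(8.0) * 3 + 10
        s = weighted_fiber_ttest(mat, y)[0]
        assert s.t_value == pytest.approx(0.0, abs=1e-12)

    def test_worked_example(self):
        # w = [1, .8, .2, 0], y = [60, 50, 30, 20]:
        # sum w = sum(1-w) = 2, Kish n_eff = 4/1.68 = 2.38095 (both groups),
        # weighted means 53 / 27, weighted variances (Bessel-adjusted by
        # n_eff) 139.655 each -> pooled t = 26 / sqrt(139.655 * 2/2.38095)
        mat = pd.DataFrame({0: [1.0, 0.8, 0.2, 0.0]})
        s = weighted_fiber_ttest(mat, [60.0, 50.0, 30.0, 20.0])[0]
        assert s.t_value == pytest.approx(2.4005, abs=1e-4)
        assert s.n_act == pytest.approx(4 / 1.68, rel=1e-9)

    def test_degenerate_weights_flagged(self):
        mat = pd.DataFrame({0: [1.0, 1.0, 1.0]})
        s = weighted_fiber_ttest(mat, [1.0, 2.0, 3.0])[0]
        assert not s.defined


class TestWeightedOddsRatio:
    def test_binary_table_example(self):
        # a=6 (activated, improved), b=2, c=2, d=6 -> OR = 36/4 = 9
        w = [1] * 6 + [1] * 2 + [0] * 2 + [0] * 6
        y = [1] * 6 + [0] * 2 + [1] * 2 + [0] * 6
        or_, (lo, hi) = weighted_odds_ratio(w, y)
        assert or_ == pytest.approx(9.0)
        assert lo < 9.0 < hi

    def test_uniform_weights_unit_or(self):
        w = [0.5] * 10
        y = [1, 0] * 5
        or_, _ = weighted_odds_ratio(w, y)
        assert or_ == pytest.approx(1.0)

    def test_zero_cell_correction(self):
        w = [1, 1, 0, 0]
        y = [1, 1, 0, 0]  # b = c = 0 without correction
        or_, _ = weighted_odds_ratio(w, y)
        assert np.isfinite(or_) and or_ > 1

    def test_degenerate_outcome(self):
        with pytest.raises(StatsError):
            weighted_odds_ratio([0.5, 0.5], [1, 1])


class TestTopFibers:
    def test_counts_conserved_and_ties_by_id(self):
        atlas = atlas_of({"a": 5, "b": 5})
        from axonmetrics.group_stats import FiberStat
        stats = [FiberStat(i, t, 3, 3, True) for i, t in
                 zip(range(10), [5, 4, 3, 3, 3, 2, 1, 0, -1, -2])]
        dist = top_fiber_distribution(stats, atlas, k=4)
        assert sum(dist.values()) == 4
        # rank-4 tie between ids 2,3,4 at T=3: ids 2 and 3 kept
        assert dist == {"a": 4, "b": 0}

    def test_fewer_than_k_uses_all(self):
        atlas = atlas_of({"a": 3})
        from axonmetrics.group_stats import FiberStat
        stats = [FiberStat(i, float(i), 3, 3, True) for i in range(3)]
        dist = top_fiber_distribution(stats, atlas, k=100)
        assert sum(dist.values()) == 3


class TestMirrorFold:
    def test_fold_renames_offset_columns(self):
        mat = pd.DataFrame(
            [[1.0, 0.0]], columns=[3, 3 + MIRROR_ID_OFFSET]
        )
        folded = fold_mirrored_matrix(mat)
        assert list(folded.columns) == [3, 3]

    def test_duplicated_hemispheres_change_t_by_recomputation(self):
        # identical data in both hemispheres = every row duplicated;
        # the T after mirroring must equal a direct recomputation on the
        # doubled sample (scipy as independent oracle)
        rng = np.random.default_rng(9)
        col = rng.integers(0, 2, 12).astype(float)
        y = rng.normal(30, 10, 12)
        mat2 = pd.DataFrame({0: np.concatenate([col, col])})
        y2 = np.concatenate([y, y])
        s = fiber_ttest(mat2, y2)[0]
        ref = sps.ttest_ind(y2[mat2[0] == 1], y2[mat2[0] == 0],
                            equal_var=True).statistic
        assert s.t_value == pytest.approx(ref, rel=1e-12)


class TestFiberFilterModel:
    def _setup(self):
        rng = np.random.default_rng(5)
        atlas = atlas_of({"a": 6, "b": 6})
        mat = pd.DataFrame(
            rng.uniform(0, 1, (20, 12)), columns=range(12)
        )
        # plant signal on pathway "a" fibres (ids 0-5)
        y = 20 + 30 * (mat.iloc[:, :6].to_numpy() >= 0.5).mean(axis=1)
        return atlas, mat, y

    def test_fit_recovers_planted_pathway(self):
        atlas, mat, y = self._setup()
        res = FiberFilter(mat, y, atlas).fit()
        top = res.top_pathways(6)
        assert top["a"] > top["b"]

    def test_weighted_fit_runs(self):
        atlas, mat, y = self._setup()
        res = FiberFilter(mat, y, atlas).fit(weighted=True)
        assert res.n_included > 0

    def test_summary_mentions_counts(self):
        atlas, mat, y = self._setup()
        s = FiberFilter(mat, y, atlas).fit().summary()
        assert "stimulations:        20" in s
        assert "Fibre filtering" in s

    def test_from_dataframe(self):
        atlas, mat, y = self._setup()
        df = mat.copy()
        df.columns = [str(c) for c in df.columns]
        df["outcome_percent"] = y
        model = FiberFilter.from_dataframe(df, atlas)
        assert model.matrix.shape == (20, 12)

    def test_mismatched_outcomes_rejected(self):
        atlas, mat, y = self._setup()
        with pytest.raises(StatsError):
            FiberFilter(mat, y[:-1], atlas)
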