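"""Correlation-to-seed scoring, Rank Product, permutation pfp, selection, sweep."""

import numpy as np
import pandas as pd
import pytest

import mircor as mc
from mircor.rankprod import CorrelationMatrix, rank_product, estimate_pfp

from conftest import make_expression
from oracles import (
    enumerate_pfp_single_column,
    naive_pfp,
    naive_rank_product,
)


def _corr_from_array(m, prefix="T"):
    G, K = m.shape
    return CorrelationMatrix(values=pd.DataFrame(
        m, index=[f"{prefix}{i}" for i in range(G)],
        columns=[f"S{k}" for k in range(K)]))


class TestCorrelateToSeeds:
    def test_seed_correlates_one_with_itself_and_negation_minus_one(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(10, 9))
        vals[3] = -(vals[0] - vals[0].mean()) + 5.0  # negation about the mean
        expr = make_expression(vals)
        corr = mc.correlate_to_seeds(expr, ["T0", "T1"])
        assert corr.values.loc["T0", "T0"] == pytest.approx(1.0)
        assert corr.values.loc["T1", "T1"] == pytest.approx(1.0)
        assert corr.values.loc["T3", "T0"] == pytest.approx(-1.0)

    def test_matches_closed_form_pearson(self):
        x = np.arange(1.0, 10.0)
        y = np.array([1, 2, 3, 4, 5, 6, 7, 8, 10.0])
        vals = np.vstack([x, y, np.random.default_rng(1).normal(size=(1, 9))])
        corr = mc.correlate_to_seeds(make_expression(vals), ["T0", "T1"])
        # closed form: r = cov(x,y) / (sd_x sd_y)
        xc, yc = x - x.mean(), y - y.mean()
        r = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert corr.values.loc["T1", "T0"] == pytest.approx(r, rel=1e-12)
        assert np.allclose(np.corrcoef(x, y)[0, 1], r)

    def test_zero_variance_rows_flagged_and_zeroed(self):
        vals = np.random.default_rng(2).normal(size=(5, 9))
        vals[2] = 7.0
        corr = mc.correlate_to_seeds(make_expression(vals), ["T0", "T1"])
        assert corr.zero_variance_ids == {"T2"}
        assert (corr.values.loc["T2"] == 0).all()

    def test_requires_two_seeds_present(self):
        vals = np.random.default_rng(3).normal(size=(5, 9))
        with pytest.raises(ValueError, match="2 seed"):
            mc.correlate_to_seeds(make_expression(vals), ["T0"])
        with pytest.raises(ValueError, match="absent"):
            mc.correlate_to_seeds(make_expression(vals), ["T0", "NOPE"])


class TestRankProduct:
    def test_top_ranked_everywhere_gives_rp_one(self):
        m = np.array([[0.9, 0.8], [0.1, 0.2], [0.5, 0.4]])
        rp = rank_product(_corr_from_array(m)).table["RP"]
        assert rp.loc["T0"] == pytest.approx(1.0)

    def test_geometric_mean_of_ranks(self):
        # ranks (1, 4) over two columns -> RP = sqrt(4) = 2
        m = np.array([[0.9, 0.1], [0.5, 0.6], [0.4, 0.7], [0.3, 0.8]])
        rp = rank_product(_corr_from_array(m)).table["RP"]
        assert rp.loc["T0"] == pytest.approx(2.0)

    def test_matches_brute_force_on_random_matrix(self):
        rng = np.random.default_rng(4)
        m = rng.uniform(-1, 1, size=(50, 4))
        res = rank_product(_corr_from_array(m))
        np.testing.assert_allclose(res.table["RP"], naive_rank_product(m), rtol=1e-12)
        np.testing.assert_allclose(res.table["mean_corr"], m.mean(axis=1), rtol=1e-12)

    def test_ties_get_average_ranks(self):
        m = np.array([[0.5, 0.5], [0.5, 0.5], [0.1, 0.1]])
        rp = rank_product(_corr_from_array(m)).table["RP"]
        assert rp.loc["T0"] == pytest.approx(1.5)
        assert rp.loc["T1"] == pytest.approx(1.5)


class TestEstimatePfp:
    def test_matches_naive_permutation_oracle_exactly(self):
        rng = np.random.default_rng(5)
        m = rng.uniform(-1, 1, size=(30, 3))
        corr = _corr_from_array(m)
        res = estimate_pfp(corr, rank_product(corr), n_perm=20, rng_seed=99)
        np.testing.assert_allclose(
            res.table["pfp"], naive_pfp(m, n_perm=20, rng_seed=99), rtol=1e-12
        )

    def test_single_column_pfp_is_one_by_enumeration(self):
        rng = np.random.default_rng(6)
        col = rng.uniform(-1, 1, size=(5, 1))
        exact = enumerate_pfp_single_column(col[:, 0])
        np.testing.assert_allclose(exact, np.ones(5))
        corr = _corr_from_array(col)
        # estimate_pfp needs K >= 1; any n_perm reproduces the exact value
        res = estimate_pfp(corr, rank_product(corr), n_perm=5, rng_seed=0)
        np.testing.assert_allclose(res.table["pfp"], exact, rtol=1e-12)

    def test_deterministic_under_seed_and_stable_in_n_perm(self):
        rng = np.random.default_rng(7)
        m = rng.uniform(-1, 1, size=(200, 5))
        corr = _corr_from_array(m)
        base = rank_product(corr)
        a = estimate_pfp(corr, base, n_perm=40, rng_seed=1)
        b = estimate_pfp(corr, base, n_perm=40, rng_seed=1)
        pd.testing.assert_frame_equal(a.table, b.table)
        c = estimate_pfp(corr, base, n_perm=80, rng_seed=2)
        from scipy import stats

        ks = stats.ks_2samp(a.table["pfp"], c.table["pfp"])
        assert ks.pvalue > 0.01

    def test_transcript_identical_to_seed_scores_minimal(self):
        # cohesive seeds sharing a latent factor, plus one transcript that
        # duplicates a seed exactly: the duplicate must sit at RP ~ 1 with
        # the smallest pfp observed
        rng = np.random.default_rng(12)
        factor = rng.normal(size=9)
        seeds_block = factor + 0.2 * rng.normal(size=(5, 9))
        noise = rng.normal(size=(200, 9))
        vals = np.vstack([seeds_block, noise, seeds_block[0]])
        expr = make_expression(vals)
        dup = expr.values.index[-1]
        seed_ids = list(expr.values.index[:5])
        corr = mc.correlate_to_seeds(expr, seed_ids)
        res = estimate_pfp(corr, rank_product(corr), n_perm=30, rng_seed=3)
        t = res.table
        assert t.loc[dup, "RP"] <= np.quantile(t["RP"], 0.05)
        assert t.loc[dup, "pfp"] <= t["pfp"].min() + 1e-12
        for s in seed_ids:
            assert t.loc[s, "RP"] <= np.quantile(t["RP"], 0.1)


class TestColumnOrderInvariance:
    def test_shuffled_seed_order_changes_nothing(self, small_expr):
        seeds = list(small_expr.values.index[:5])
        a = mc.correlate_to_seeds(small_expr, seeds)
        b = mc.correlate_to_seeds(small_expr, seeds[::-1])
        pd.testing.assert_frame_equal(a.values, b.values)
        ra = estimate_pfp(a, rank_product(a), n_perm=10, rng_seed=4)
        rb = estimate_pfp(b, rank_product(b), n_perm=10, rng_seed=4)
        pd.testing.assert_frame_equal(ra.table, rb.table)


class TestSeedCohesion:
    def test_identical_seeds_have_cohesion_one(self):
        m = np.ones((4, 4))
        rep = mc.seed_cohesion(pd.DataFrame(m, index=list("abcd"), columns=list("abcd")))
        assert rep.mean_offdiagonal == pytest.approx(1.0)
        assert sorted(rep.dendrogram_order) == list("abcd")

    def test_independent_noise_seeds_near_zero(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=(40, 30))
        z = (vals - vals.mean(1, keepdims=True)) / vals.std(1, keepdims=True)
        c = z @ z.T / 30
        np.fill_diagonal(c, 1.0)
        rep = mc.seed_cohesion(pd.DataFrame(c))
        assert abs(rep.mean_offdiagonal) < 3 / np.sqrt(30)

    def test_latent_factor_seeds_exceed_null(self, small_expr, small_dataset):
        _, truth = small_dataset
        targets = sorted(set(truth.target_ids) & set(small_expr.values.index))[:12]
        corr = mc.correlate_to_seeds(small_expr, targets)
        observed = mc.seed_cohesion(corr.seed_block()).mean_offdiagonal
        rng = np.random.default_rng(9)
        nulls = []
        non_targets = [t for t in small_expr.values.index
                       if t not in truth.target_ids]
        for _ in range(40):
            pick = rng.choice(non_targets, size=12, replace=False)
            c = mc.correlate_to_seeds(small_expr, list(pick))
            nulls.append(mc.seed_cohesion(c.seed_block()).mean_offdiagonal)
        assert observed > np.quantile(nulls, 0.95)


class TestSelectionAndSweep:
    def _result(self, mean_corr, pfp):
        n = len(mean_corr)
        t = pd.DataFrame({"mean_corr": mean_corr, "RP": 1.0,
                          "rank": np.arange(1, n + 1), "pfp": pfp},
                         index=[f"T{i}" for i in range(n)])
        return mc.rankprod.RankProductResult(table=t, n_perm=10)

    def test_zero_mean_corr_excluded_strictly(self):
        res = self._result([0.0, 0.1], [0.001, 0.001])
        assert mc.select_correlated(res) == {"T1"}

    def test_permissive_thresholds_select_all_positive(self):
        res = self._result([0.2, 0.3], [0.5, 0.9])
        assert mc.select_correlated(res, pfp_max=1.0) == {"T0", "T1"}

    def test_membership_matches_brute_force(self):
        rng = np.random.default_rng(10)
        mean_corr = rng.uniform(-1, 1, 50)
        pfp = rng.uniform(0, 0.05, 50)
        res = self._result(mean_corr, pfp)
        got = mc.select_correlated(res, pfp_max=0.01)
        expected = {f"T{i}" for i in range(50)
                    if mean_corr[i] > 0 and pfp[i] < 0.01}
        assert got == expected

    def test_pfp_missing_is_an_error(self):
        t = pd.DataFrame({"mean_corr": [0.5], "RP": [1.0], "rank": [1]}, index=["T0"])
        with pytest.raises(ValueError, match="pfp"):
            mc.select_correlated(mc.rankprod.RankProductResult(table=t))

    def test_sweep_counts_non_increasing_and_full_at_low_threshold(self, small_expr, small_de):
        seeds = list(small_expr.values.index[:5])
        corr = mc.correlate_to_seeds(small_expr, seeds)
        res = rank_product(corr)
        res.table["pfp"] = 1.0
        sweep = mc.threshold_sweep(res, small_de,
                                   grid=np.arange(-1.0, 1.01, 0.1))
        assert sweep["n_above"].iloc[0] == len(res.table)
        assert (np.diff(sweep["n_above"]) <= 0).all()
        frac = sweep[["frac_oe_down", "frac_kd_up"]].dropna()
        assert ((frac >= 0) & (frac <= 1)).all().all()

    def test_empty_stratum_reports_missing(self, small_de):
        t = pd.DataFrame({"mean_corr": [0.1], "RP": [1.0], "rank": [1], "pfp": [1.0]},
                         index=[small_de.table.index[0]])
        res = mc.rankprod.RankProductResult(table=t)
        sweep = mc.threshold_sweep(res, small_de, grid=[0.0, 0.5])
        assert sweep["n_above"].iloc[1] == 0
        assert np.isnan(sweep["frac_oe_down"].iloc[1])
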