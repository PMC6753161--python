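import numpy as np
import pandas as pd
import pytest
from scipy import stats

from grsanhedonia import (
    adjust_icv,
    adjusted_r2,
    bonferroni_threshold,
    build_results_table,
    delta_r2_adjusted,
    f_tail_p,
    gen_phenotypes,
    hierarchical_fit,
    residualize,
    unit_variance_summary,
)
from grsanhedonia.cohort import CohortConfig
from conftest import synthetic_grs_pcs


def normal_equations_oracle(y, blocks):
    """Brute-force nested least squares via explicit matrix inversion."""
    n = len(y)
    design = np.ones((n, 1))
    sst = np.sum((y - y.mean()) ** 2)
    out = []
    r2_prev, p_cum = 0.0, 0
    for x in blocks:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        x = x.T if x.shape[0] != n else x
        design = np.hstack([design, x])
        beta = np.linalg.inv(design.T @ design) @ design.T @ y
        resid = y - design @ beta
        r2 = 1 - resid @ resid / sst
        q = x.shape[1]
        p_cum += q
        df2 = n - p_cum - 1
        f = ((r2 - r2_prev) / q) / ((1 - r2) / df2)
        out.append((r2, r2 - r2_prev, f, q, df2, stats.f.sf(f, q, df2)))
        r2_prev = r2
    return out


class TestHierarchicalFit:
    def test_matches_normal_equations_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            n = rng.integers(15, 31)
            y = rng.normal(size=n)
            b1 = rng.normal(size=(n, 2))
            b2 = rng.normal(size=n)
            fit = hierarchical_fit(y, [("a", b1), ("b", b2)])
            oracle = normal_equations_oracle(y, [b1, b2])
            for i, (r2, dr2, f, q, df2, p) in enumerate(oracle):
                step = fit.step(i)
                assert step["r2_cumulative"] == pytest.approx(r2, abs=1e-10)
                assert step["delta_r2"] == pytest.approx(dr2, abs=1e-10)
                assert step["delta_f"] == pytest.approx(f, abs=1e-8)
                assert step["p"] == pytest.approx(p, abs=1e-10)
                assert (step["df1"], step["df2"]) == (q, df2)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(2)
        n = 60
        y = rng.normal(size=n)
        pcs = rng.normal(size=(n, 2))
        g = rng.normal(size=n)
        fit = hierarchical_fit(y, [("pcs", pcs), ("grs", g)])
        full = sm.OLS(y, sm.add_constant(np.column_stack([pcs, g]))).fit()
        red = sm.OLS(y, sm.add_constant(pcs)).fit()
        assert fit.step(1)["delta_r2"] == pytest.approx(full.rsquared - red.rsquared, abs=1e-12)
        cmp = full.compare_f_test(red)
        assert fit.step(1)["delta_f"] == pytest.approx(cmp[0], abs=1e-8)
        assert fit.step(1)["p"] == pytest.approx(cmp[1], abs=1e-10)

    @pytest.mark.parametrize("n,df2", [(73, 69), (62, 58)])
    def test_degrees_of_freedom_bookkeeping(self, n, df2):
        rng = np.random.default_rng(n)
        y = rng.normal(size=n)
        fit = hierarchical_fit(
            y, [("pcs", rng.normal(size=(n, 2))), ("grs", rng.normal(size=n))])
        assert (fit.step(1)["df1"], fit.step(1)["df2"]) == (1, df2)
        assert fit.n_used == n

    def test_delta_r2_additivity(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=40)
        fit = hierarchical_fit(
            y, [("a", rng.normal(size=40)), ("b", rng.normal(size=(40, 2))),
                ("c", rng.normal(size=40))])
        assert fit.steps["delta_r2"].sum() == pytest.approx(
            fit.steps["r2_cumulative"].iloc[-1], abs=1e-12)

    def test_outcome_in_span_of_first_block_gives_zero_increment(self):
        rng = np.random.default_rng(4)
        x1 = rng.normal(size=50)
        y = 2.0 + 3.0 * x1
        fit = hierarchical_fit(y, [("x1", x1), ("x2", rng.normal(size=50))])
        assert fit.step(1)["delta_r2"] == pytest.approx(0.0, abs=1e-12)

    def test_affine_invariance_of_statistics(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=50)
        pcs = rng.normal(size=(50, 2))
        g = rng.normal(size=50)
        a = hierarchical_fit(y, [("pcs", pcs), ("grs", g)])
        b = hierarchical_fit(y, [("pcs", 3.0 * pcs - 1.0), ("grs", -0.2 * g + 7.0)])
        for col in ("delta_r2", "delta_f", "p"):
            assert a.step(1)[col] == pytest.approx(b.step(1)[col], abs=1e-10)

    def test_listwise_deletion(self):
        rng = np.random.default_rng(6)
        y = rng.normal(size=30)
        y[:3] = np.nan
        fit = hierarchical_fit(y, [("x", rng.normal(size=30))])
        assert fit.n_used == 27

    def test_rank_deficiency_raises(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=30)
        with pytest.raises(ValueError, match="dup"):
            hierarchical_fit(rng.normal(size=30), [("x", x), ("dup", x)])


class TestFTail:
    @pytest.mark.parametrize("f,df1,df2,expected", [
        (5.14, 1, 58, 0.027),   # putamen RPE anchor
        (7.32, 1, 69, 0.009),   # putamen volume anchor
        (11.19, 1, 49, 0.002),  # final NAc-RPE model anchor
    ])
    def test_printed_anchors_to_three_decimals(self, f, df1, df2, expected):
        assert round(f_tail_p(f, df1, df2), 3) == expected

    def test_f_zero_gives_one(self):
        assert f_tail_p(0.0, 1, 10) == 1.0

    def test_equals_squared_t_two_sided(self):
        for f, df2 in [(2.5, 20), (5.14, 58), (0.3, 7)]:
            p_t = 2 * stats.t.sf(np.sqrt(f), df2)
            assert f_tail_p(f, 1, df2) == pytest.approx(p_t, abs=1e-12)

    def test_invalid_dfs(self):
        with pytest.raises(ValueError):
            f_tail_p(1.0, 0, 10)


class TestResidualize:
    def test_projection_orthogonality(self):
        rng = np.random.default_rng(8)
        y = rng.normal(size=40)
        x = rng.normal(size=(40, 3))
        r = residualize(y, x)
        assert np.abs(x.T @ r).max() < 1e-10
        assert abs(r.sum()) < 1e-10

    def test_outcome_in_span_gives_zero(self):
        x = np.arange(20.0)
        assert np.abs(residualize(1.5 * x - 2.0, x)).max() < 1e-10


class TestICV:
    def test_proportional_volume_flattens_to_mean(self):
        icv = np.linspace(1.2e6, 1.7e6, 30)
        vol = 0.001 * icv
        adj = adjust_icv(vol, icv)
        np.testing.assert_allclose(adj, vol.mean(), rtol=1e-10)

    def test_uncorrelated_icv_leaves_volume_nearly_unchanged(self):
        rng = np.random.default_rng(9)
        vol = rng.normal(1300, 120, size=5000)
        icv = rng.normal(1.45e6, 1e5, size=5000)
        adj = adjust_icv(vol, icv)
        assert np.corrcoef(adj, vol)[0, 1] > 0.99

    def test_adjusted_uncorrelated_with_icv(self):
        rng = np.random.default_rng(10)
        icv = rng.normal(1.45e6, 1e5, size=200)
        vol = 1000 + 0.0005 * icv + rng.normal(0, 50, 200)
        adj = adjust_icv(vol, icv)
        assert abs(np.corrcoef(adj, icv)[0, 1]) < 1e-10

    def test_missing_propagates(self):
        vol = np.array([1000.0, np.nan, 1200.0, 1100.0])
        icv = np.array([1.4e6, 1.5e6, 1.6e6, 1.45e6])
        adj = adjust_icv(vol, icv)
        assert np.isnan(adj[1]) and np.isfinite(adj[[0, 2, 3]]).all()


class TestBonferroni:
    @pytest.mark.parametrize("alpha,m,expected", [
        (0.05, 2, 0.025), (0.05, 1, 0.05), (0.05, 4, 0.0125)])
    def test_threshold(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == expected

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestAdjustedR2:
    def test_difference_recovers_generating_increment(self):
        # mean bias-adjusted dR2 over replicate cohorts stays within 0.01
        rng = np.random.default_rng(11)
        r2_true, n, reps = 0.095, 73, 800
        vals = []
        cfg = CohortConfig(n_individuals=n, per_unit_target_r2={"y": r2_true},
                           per_unit_n={}, seed=0)
        for _ in range(reps):
            grs, pcs = synthetic_grs_pcs(n, rng)
            pheno, _ = gen_phenotypes(grs, pcs, cfg, rng=rng)
            fit = hierarchical_fit(pheno["y"], [("pcs", pcs), ("grs", grs)])
            vals.append(fit.step(1)["delta_r2_adj"])
        assert np.mean(vals) == pytest.approx(r2_true, abs=0.01)

    def test_raw_delta_r2_is_inflated_relative_to_adjusted(self):
        rng = np.random.default_rng(12)
        n = 73
        grs, pcs = synthetic_grs_pcs(n, rng)
        y = rng.normal(size=n)
        fit = hierarchical_fit(y, [("pcs", pcs), ("grs", grs)])
        assert fit.step(1)["delta_r2"] > fit.step(1)["delta_r2_adj"]

    def test_ezekiel_formula(self):
        assert adjusted_r2(0.5, 50, 3, "ezekiel") == pytest.approx(
            1 - 0.5 * 49 / 46)

    def test_zero_predictors_identity(self):
        assert adjusted_r2(0.0, 50, 0) == 0.0


class TestResultsTable:
    def test_six_measures_with_per_row_listwise_n(self, default_cohort):
        table = build_results_table(
            default_cohort["phenotypes"], default_cohort["grs"]["score"],
            default_cohort["pcs"].scores, outlier_z=None)
        two = table[table["model"] == "two_step"].set_index("measure")
        assert len(two) == 6
        pheno = default_cohort["phenotypes"]
        for m in two.index:
            assert two.at[m, "n"] == pheno[m].notna().sum()
        # functional/structural rows carry the corrected threshold
        assert two.at["nac_rpe_change", "bonferroni_threshold"] == 0.025
        assert two.at["shaps", "bonferroni_threshold"] is None or np.isnan(
            two.at["shaps", "bonferroni_threshold"])

    def test_three_step_rows_present_for_circuits(self, default_cohort):
        table = build_results_table(
            default_cohort["phenotypes"], default_cohort["grs"]["score"],
            default_cohort["pcs"].scores)
        three = table[table["model"] == "three_step"]
        assert set(three["measure"]) == {
            "nac_rpe_change", "put_rpe_change", "nac_volume", "put_volume"}
        # the middle block adds two predictors, so df2 = n - 5 - 1
        for _, r in three.iterrows():
            assert r["df2"] == r["n"] - 6

    def test_volume_rows_use_icv_adjustment(self, default_cohort):
        pheno = default_cohort["phenotypes"]
        grs = default_cohort["grs"]["score"]
        pcs = default_cohort["pcs"].scores
        with_icv = build_results_table(pheno, grs, pcs, outlier_z=None)
        no_icv = build_results_table(pheno.drop(columns="icv"), grs, pcs,
                                     outlier_z=None)
        a = with_icv[(with_icv["measure"] == "put_volume")
                     & (with_icv["model"] == "two_step")]["delta_r2"].iloc[0]
        b = no_icv[(no_icv["measure"] == "put_volume")
                   & (no_icv["model"] == "two_step")]["delta_r2"].iloc[0]
        assert a != b

    def test_null_cohort_p_values_uniform(self):
        # type-I calibration of the GRS step at n=83 with 2 PCs
        rng = np.random.default_rng(13)
        cfg = CohortConfig(n_individuals=83, per_unit_target_r2={"y": 0.0},
                           per_unit_n={}, seed=0)
        pvals = []
        for _ in range(400):
            grs, pcs = synthetic_grs_pcs(83, rng)
            pheno, _ = gen_phenotypes(grs, pcs, cfg, rng=rng)
            fit = hierarchical_fit(pheno["y"], [("pcs", pcs), ("grs", grs)])
            pvals.append(fit.step(1)["p"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_missing_required_columns_rejected(self, default_cohort):
        with pytest.raises(ValueError):
            build_results_table(
                default_cohort["phenotypes"][["icv"]],
                default_cohort["grs"]["score"], default_cohort["pcs"].scores)


class TestUnitSummary:
    def test_published_delta_r2_inputs_reproduce_discussion_averages(self):
        from grsanhedonia import PUBLISHED_UNIT_DELTA_R2
        summary = unit_variance_summary(PUBLISHED_UNIT_DELTA_R2)
        assert summary["self_report"] == pytest.approx(1.70)
        assert summary["behavior"] == pytest.approx(3.50)
        assert summary["circuits_functional"] == pytest.approx(6.95)
        assert summary["circuits_structural"] == pytest.approx(7.95)
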