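"""Differential expression / usage statistics, against independent oracles."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import juncdiff as jd
from juncdiff.dje import (
    DesignSpec,
    FitResult,
    ModeratedStats,
    bh_adjust,
    classify_junctions,
    ebayes_moderate,
    fit_linear_model,
    gene_level_p,
    relative_usage,
)


def _matrix_from_counts(arr, samples=None):
    arr = np.asarray(arr)
    idx = [f"chr1:{i*100+1}:{i*100+50}:1" for i in range(arr.shape[0])]
    cols = samples or [f"s{i}" for i in range(arr.shape[1])]
    counts = pd.DataFrame(arr, index=idx, columns=cols)
    return jd.JunctionCountMatrix(
        counts, jd.JunctionCountMatrix.empty_meta(counts.index)
    )


class TestFilter:
    def test_mean_threshold_is_inclusive(self):
        m = _matrix_from_counts([[10, 10, 10, 10]])
        assert jd.filter_junctions(m, 10).n_junctions == 1

    def test_all_zero_removed(self):
        m = _matrix_from_counts([[0, 0, 0], [5, 5, 5]])
        assert jd.filter_junctions(m, 1).n_junctions == 1

    def test_hand_set_means(self):
        rows = [[2] * 10, [10] * 9 + [9], [10] * 10, [10] * 9 + [11], [50] * 10]
        means = [np.mean(r) for r in rows]
        assert means == [2, 9.9, 10, 10.1, 50]
        m = _matrix_from_counts(rows)
        assert jd.filter_junctions(m, 10).n_junctions == 3

    def test_empty_result_advises_threshold(self):
        m = _matrix_from_counts([[1, 1]])
        with pytest.raises(ValueError, match="mean-variance trend"):
            jd.filter_junctions(m, 100)


class TestLogCPM:
    def test_offsets_cancel_at_half_per_million(self):
        # count 0 with library 499,999: (0 + 0.5)/(499,999 + 1) * 1e6 = 1
        m = _matrix_from_counts([[0], [499_999]])
        y = jd.logcpm(m)
        assert y.iloc[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(0)
        arr = rng.integers(0, 1000, size=(20, 4))
        m = _matrix_from_counts(arr)
        y = jd.logcpm(m).to_numpy()
        lib = arr.sum(axis=0)
        expected = np.log2((arr + 0.5) / (lib + 1.0) * 1e6)
        np.testing.assert_allclose(y, expected, rtol=1e-12)

    def test_scale_invariance_up_to_offsets(self):
        rng = np.random.default_rng(1)
        arr = rng.integers(100, 5000, size=(50, 4))
        y1 = jd.logcpm(_matrix_from_counts(arr)).to_numpy()
        y2 = jd.logcpm(_matrix_from_counts(2 * arr)).to_numpy()
        assert np.abs(y1 - y2).max() < 2**-7  # offset perturbation only

    def test_zero_library_is_an_error(self):
        with pytest.raises(ValueError, match="library"):
            jd.logcpm(_matrix_from_counts([[0, 5], [0, 5]]))


def _two_group_design(n_per_group):
    groups = pd.Series(
        ["test"] * n_per_group + ["control"] * n_per_group,
        index=[f"s{i}" for i in range(2 * n_per_group)],
    )
    return jd.two_group_design(groups), groups


class TestMeanVarianceWeights:
    def test_flat_trend_gives_near_constant_weights(self):
        rng = np.random.default_rng(42)
        n = 500
        design, groups = _two_group_design(6)
        arr = rng.poisson(200, size=(n, 12))  # equal means, equal variances
        m = _matrix_from_counts(arr, samples=list(design.samples))
        y = jd.logcpm(m)
        w = jd.mean_variance_weights(y, m, design)
        ratio = w.to_numpy().max() / w.to_numpy().min()
        assert ratio < 1.5

    def test_weights_track_true_precision(self):
        # NB-like data: variance of logCPM decreases with the mean
        rng = np.random.default_rng(7)
        design, _ = _two_group_design(8)
        mu = np.geomspace(5, 2000, 300)
        disp = 0.05
        r = 1 / disp
        arr = rng.negative_binomial(r, r / (r + mu[:, None]), size=(300, 16))
        m = _matrix_from_counts(arr, samples=list(design.samples))
        y = jd.logcpm(m)
        w = jd.mean_variance_weights(y, m, design)
        # true precision of log2 counts ~ 1 / (1/mu + disp) (delta method)
        true_prec = 1.0 / (1.0 / mu + disp)
        rho = stats.spearmanr(w.mean(axis=1), true_prec).statistic
        assert rho > 0.8

    def test_identical_fitted_logcount_identical_weights(self):
        rng = np.random.default_rng(3)
        design, _ = _two_group_design(5)
        arr = rng.poisson(100, size=(30, 10))
        arr[1] = arr[0]  # duplicate junction -> same fit -> same weights
        m = _matrix_from_counts(arr, samples=list(design.samples))
        y = jd.logcpm(m)
        w = jd.mean_variance_weights(y, m, design)
        np.testing.assert_array_equal(w.iloc[0].to_numpy(), w.iloc[1].to_numpy())

    def test_too_few_junctions_error(self):
        design, _ = _two_group_design(3)
        m = _matrix_from_counts(np.full((4, 6), 50), samples=list(design.samples))
        with pytest.raises(ValueError, match="unweighted"):
            jd.mean_variance_weights(jd.logcpm(m), m, design)


def _brute_force_wls(Y, X, W, ci):
    """Normal-equations oracle at extended precision."""
    Y = Y.astype(np.longdouble)
    X = X.astype(np.longdouble)
    W = W.astype(np.longdouble)
    n, p = X.shape
    beta, u, s2 = [], [], []
    for j in range(len(Y)):
        A = X.T @ (np.diag(W[j]) @ X)
        Ainv = np.linalg.inv(A.astype(float)).astype(np.longdouble)
        b = Ainv @ (X.T @ (W[j] * Y[j]))
        r = Y[j] - X @ b
        beta.append(float(b[ci]))
        u.append(float(np.sqrt(Ainv[ci, ci])))
        s2.append(float((W[j] * r**2).sum() / (n - p)))
    return np.array(beta), np.array(u), np.array(s2)


class TestFitLinearModel:
    def test_two_group_beta_is_mean_difference(self):
        design, _ = _two_group_design(4)
        y = pd.DataFrame(
            [[5.0] * 4 + [3.0] * 4], index=["j"], columns=design.samples
        )
        w = pd.DataFrame(1.0, index=y.index, columns=y.columns)
        fit = fit_linear_model(y, design, w)
        assert fit.beta["j"] == pytest.approx(2.0)  # test minus control

    def test_residuals_orthogonal_to_design_under_weights(self):
        rng = np.random.default_rng(5)
        design, _ = _two_group_design(5)
        y = pd.DataFrame(
            rng.normal(size=(10, 10)), columns=design.samples,
            index=[f"j{i}" for i in range(10)],
        )
        w = pd.DataFrame(
            rng.uniform(0.5, 2.0, size=y.shape), index=y.index, columns=y.columns
        )
        fit = fit_linear_model(y, design, w)
        X = design.design.to_numpy()
        for j in range(10):
            coef = np.linalg.lstsq(
                X * np.sqrt(w.iloc[j].to_numpy())[:, None],
                y.iloc[j].to_numpy() * np.sqrt(w.iloc[j].to_numpy()),
                rcond=None,
            )[0]
            r = y.iloc[j].to_numpy() - X @ coef
            assert np.abs(X.T @ (w.iloc[j].to_numpy() * r)).max() < 1e-8

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(11)
        n, p, nj = 6, 3, 20
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        design = DesignSpec(
            pd.DataFrame(X, index=[f"s{i}" for i in range(n)],
                         columns=["intercept", "c1", "c2"]),
            "c1",
        )
        Y = rng.normal(size=(nj, n))
        W = rng.uniform(0.2, 3.0, size=(nj, n))
        y = pd.DataFrame(Y, columns=design.samples, index=[f"j{i}" for i in range(nj)])
        w = pd.DataFrame(W, columns=design.samples, index=y.index)
        fit = fit_linear_model(y, design, w)
        beta, u, s2 = _brute_force_wls(Y, X, W, ci=1)
        np.testing.assert_allclose(fit.beta.to_numpy(), beta, rtol=1e-10)
        np.testing.assert_allclose(fit.u.to_numpy(), u, rtol=1e-10)
        np.testing.assert_allclose(fit.s2.to_numpy(), s2, rtol=1e-10)

    def test_rank_deficient_design_rejected(self):
        idx = [f"s{i}" for i in range(4)]
        X = pd.DataFrame({"intercept": 1.0, "a": [1, 1, 0, 0], "b": [2, 2, 0, 0]},
                         index=idx)
        with pytest.raises(ValueError, match="rank"):
            DesignSpec(X, "a")


def _fit_from_arrays(beta, u, s2, df):
    idx = [f"j{i}" for i in range(len(beta))]
    dummy_design = DesignSpec(
        pd.DataFrame({"intercept": [1.0] * 4, "g": [0, 0, 1, 1]},
                     index=["a", "b", "c", "d"]),
        "g",
    )
    return FitResult(
        beta=pd.Series(beta, index=idx, dtype=float),
        u=pd.Series(u, index=idx, dtype=float),
        s2=pd.Series(s2, index=idx, dtype=float),
        df=pd.Series(df, index=idx, dtype=float),
        weights=pd.DataFrame(1.0, index=idx, columns=["a", "b", "c", "d"]),
        design=dummy_design,
    )


class TestEbayesModerate:
    def test_identical_variances_give_infinite_prior_df(self):
        fit = _fit_from_arrays([1, 2, 3], [1, 1, 1], [0.5, 0.5, 0.5], [4, 4, 4])
        mod = ebayes_moderate(fit)
        assert np.isinf(mod.d0)
        np.testing.assert_allclose(mod.s2_post.to_numpy(), 0.5, rtol=1e-9)

    def test_posterior_between_prior_and_observed(self):
        rng = np.random.default_rng(9)
        s2 = rng.chisquare(5, size=100) / 5
        fit = _fit_from_arrays(
            rng.normal(size=100), np.full(100, 0.5), s2, np.full(100, 6)
        )
        mod = ebayes_moderate(fit)
        lo = np.minimum(mod.s0_2, s2)
        hi = np.maximum(mod.s0_2, s2)
        assert ((mod.s2_post >= lo - 1e-12) & (mod.s2_post <= hi + 1e-12)).all()

    def test_prior_recovery_from_scaled_inv_chisq(self):
        # s2_j | sigma2_j ~ sigma2_j * chi2(df)/df with sigma2_j from a
        # scaled inverse chi-square prior (d0=4, s0_2=1)
        rng = np.random.default_rng(123)
        d0_true, s0_true, df = 4.0, 1.0, 10
        sigma2 = d0_true * s0_true / rng.chisquare(d0_true, size=200)
        s2 = sigma2 * rng.chisquare(df, size=200) / df
        fit = _fit_from_arrays(
            rng.normal(size=200), np.full(200, 1.0), s2, np.full(200, df)
        )
        mod = ebayes_moderate(fit)
        assert 2.0 <= mod.d0 <= 8.0
        assert 0.7 <= mod.s0_2 <= 1.4

    def test_degenerate_variances_error(self):
        fit = _fit_from_arrays([1, 2], [1, 1], [0.0, 0.0], [4, 4])
        with pytest.raises(ValueError, match="degenerate"):
            ebayes_moderate(fit)


def _mod_from_fit(fit, s2_post=1.0, df_total=np.inf):
    idx = fit.beta.index
    n = len(idx)
    return ModeratedStats(
        d0=np.inf,
        s0_2=s2_post,
        s2_post=pd.Series(s2_post, index=idx, dtype=float),
        t=pd.Series(0.0, index=idx),
        p=pd.Series(1.0, index=idx),
        fdr=pd.Series(1.0, index=idx),
        df_total=pd.Series(df_total, index=idx, dtype=float),
    )


class TestRelativeUsage:
    def test_two_junction_gene_equal_se(self):
        fit = _fit_from_arrays([3.0, 1.0], [1.0, 1.0], [1, 1], [4, 4])
        gene_map = pd.Series(["G", "G"], index=fit.beta.index)
        rel = relative_usage(fit, _mod_from_fit(fit), gene_map)
        np.testing.assert_allclose(rel["rel_logFC"].to_numpy(), [2.0, -2.0])

    def test_equal_betas_give_zero(self):
        fit = _fit_from_arrays([1.5] * 3, [0.7, 0.9, 1.1], [1] * 3, [4] * 3)
        gene_map = pd.Series(["G"] * 3, index=fit.beta.index)
        rel = relative_usage(fit, _mod_from_fit(fit), gene_map)
        np.testing.assert_allclose(rel["rel_logFC"].to_numpy(), 0.0, atol=1e-12)
        np.testing.assert_allclose(rel["rel_t"].to_numpy(), 0.0, atol=1e-12)

    def test_three_junction_weighted_leave_one_out(self):
        # v = 1/u^2 = (1, 1, 3), betas (4, 0, 0):
        # m_1 = 0 -> rel_1 = 4; m_2 = (1*4 + 3*0)/4 = 1 -> rel_2 = -1;
        # m_3 = (4 + 0)/2 = 2 -> rel_3 = -2
        u = 1.0 / np.sqrt([1.0, 1.0, 3.0])
        fit = _fit_from_arrays([4.0, 0.0, 0.0], u, [1] * 3, [4] * 3)
        gene_map = pd.Series(["G"] * 3, index=fit.beta.index)
        rel = relative_usage(fit, _mod_from_fit(fit), gene_map)
        np.testing.assert_allclose(
            rel["rel_logFC"].to_numpy(), [4.0, -1.0, -2.0], rtol=1e-12
        )

    def test_single_junction_gene_is_null_not_error(self):
        fit = _fit_from_arrays([1.0, 2.0, 3.0], [1, 1, 1], [1] * 3, [4] * 3)
        gene_map = pd.Series(["A", "B", "B"], index=fit.beta.index)
        rel = relative_usage(fit, _mod_from_fit(fit), gene_map)
        assert np.isnan(rel.loc["j0", "rel_logFC"])
        assert rel.loc[["j1", "j2"], "rel_logFC"].notna().all()

    def test_antisymmetry_in_spiked_cohort(self, spiked_run):
        """Every 2-junction gene with equal unscaled SEs has exactly
        antisymmetric relative logFC; with near-equal SEs, near-antisymmetric."""
        tbl = spiked_run.table
        genes = tbl.groupby("gene_id").size()
        two_j = genes[genes == 2].index
        checked = 0
        for g in two_j[:30]:
            rel = tbl.loc[tbl["gene_id"] == g, "rel_logFC"]
            if rel.notna().all():
                assert abs(rel.sum()) < 0.2 * abs(rel).max() + 1e-9
                checked += 1
        assert checked > 0


class TestGeneLevelP:
    def test_simes_arithmetic(self):
        rel = pd.DataFrame({"rel_p": [0.01, 0.5]}, index=["j0", "j1"])
        gm = pd.Series(["G", "G"], index=rel.index)
        out = gene_level_p(rel, gm)
        assert out.loc["G", "p"] == pytest.approx(0.02)

    def test_all_ones_stay_one(self):
        rel = pd.DataFrame({"rel_p": [1.0, 1.0, 1.0]}, index=["a", "b", "c"])
        gm = pd.Series(["G"] * 3, index=rel.index)
        assert gene_level_p(rel, gm).loc["G", "p"] == 1.0

    def test_single_tested_junction_passes_through(self):
        rel = pd.DataFrame({"rel_p": [0.03, np.nan]}, index=["a", "b"])
        gm = pd.Series(["G", "G"], index=rel.index)
        assert gene_level_p(rel, gm).loc["G", "p"] == pytest.approx(0.03)


class TestClassification:
    def _tbl(self, rows):
        df = pd.DataFrame(
            rows, columns=["abs_logFC", "abs_fdr", "rel_logFC", "rel_fdr"]
        )
        df.index = [f"j{i}" for i in range(len(df))]
        return df

    def test_exhaustive_truth_table(self):
        """Every (sigAbs, sigRel, |D| vs 2 sigma) cell maps to its group."""
        # background doubly significant junctions pinning sigma_D:
        # D values {0, 0.1, -0.1, 5.0} -> population SD 2.166, 2 sigma 4.33
        base = [
            (2.0, 0.01, 2.0, 0.01),        # D = 0   -> group 1
            (2.0, 0.01, 2.1, 0.01),        # D = 0.1 -> group 1
            (2.0, 0.01, 1.9, 0.01),        # D = -0.1-> group 1
            (2.0, 0.01, 7.0, 0.01),        # D = 5.0 -> group 3 (outside 2 SD)
            (0.5, 0.5, 0.5, 0.5),          # neither  -> group 0
            (2.0, 0.01, 0.5, 0.5),         # abs only -> group 2
            (0.5, 0.5, 2.0, 0.01),         # rel only -> group 2
            (2.0, 0.5, 2.0, 0.5),          # large but non-significant -> 0
            (2.0, 0.01, np.nan, np.nan),   # no rel stats -> abs only -> 2
        ]
        groups = classify_junctions(self._tbl(base))
        assert groups.tolist() == [1, 1, 1, 3, 0, 2, 2, 0, 2]

    def test_fewer_than_three_doubly_significant_warns_group1(self):
        rows = [(2.0, 0.01, 5.0, 0.01), (2.0, 0.01, 2.0, 0.01)]
        with pytest.warns(UserWarning, match="fewer than 3"):
            groups = classify_junctions(self._tbl(rows))
        assert groups.tolist() == [1, 1]

    def test_total_and_reproducible(self, spiked_run):
        tbl = spiked_run.table
        assert tbl["group"].isin([0, 1, 2, 3]).all()
        regroup = classify_junctions(tbl)
        pd.testing.assert_series_equal(regroup, tbl["group"], check_names=False)

    def test_raising_lfc_threshold_never_promotes_group0(self):
        rng = np.random.default_rng(2)
        rows = np.column_stack([
            rng.normal(0, 3, 200), rng.uniform(0, 1, 200),
            rng.normal(0, 3, 200), rng.uniform(0, 1, 200),
        ])
        tbl = self._tbl([tuple(r) for r in rows])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            g_low = classify_junctions(tbl, lfc_thresh=1.0)
            g_high = classify_junctions(tbl, lfc_thresh=2.0)
        promoted = (g_low == 0) & (g_high != 0)
        assert not promoted.any()


class TestNeojunctions:
    def _detect(self, control, test, **kw):
        arr = np.array([test + control])
        samples = [f"t{i}" for i in range(len(test))] + [
            f"c{i}" for i in range(len(control))
        ]
        m = _matrix_from_counts(arr, samples=samples)
        groups = pd.Series(
            ["test"] * len(test) + ["control"] * len(control), index=samples
        )
        return bool(jd.detect_neojunctions(m, groups, **kw).iloc[0])

    def test_absent_in_controls_present_in_tests(self):
        assert self._detect([0, 0, 0], [5, 8, 0], min_frac=0.25)

    def test_any_control_read_disqualifies(self):
        assert not self._detect([0, 0, 1], [5, 8, 9], min_frac=0.25)

    def test_all_zero_is_not_a_neojunction(self):
        assert not self._detect([0, 0, 0], [0, 0, 0], min_frac=0.25)

    def test_prevalence_threshold(self):
        assert not self._detect([0, 0, 0, 0], [7, 0, 0, 0], min_frac=0.5)
        assert self._detect([0, 0, 0, 0], [7, 7, 0, 0], min_frac=0.5)

    def test_missing_labels_error(self):
        m = _matrix_from_counts([[1, 2]], samples=["a", "b"])
        with pytest.raises(ValueError, match="label"):
            jd.detect_neojunctions(m, pd.Series({"a": "test"}))


class TestBHAdjust:
    def test_matches_textbook_step_up(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            p = rng.uniform(size=57)
            # independent step-up implementation
            n = len(p)
            order = np.argsort(p)
            adj = np.empty(n)
            running = 1.0
            for rank in range(n, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * n / rank)
                adj[i] = running
            np.testing.assert_allclose(bh_adjust(p), adj, rtol=1e-12)

    def test_monotone_in_rank(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=100)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestDJEAnalyze:
    def test_sample_permutation_invariance(self):
        cfg = jd.SimConfig(n_genes=40, n_test=6, n_control=6, seed=4)
        sim = jd.simulate_junction_counts(cfg)
        m = jd.filter_junctions(sim.matrix, 10)
        design = jd.two_group_design(sim.groups)
        res1 = jd.dje_analyze(m, design, sim.groups)
        perm = list(np.random.default_rng(0).permutation(m.samples))
        m2 = jd.JunctionCountMatrix(m.counts[perm], m.meta)
        res2 = jd.dje_analyze(m2, design, sim.groups)
        pd.testing.assert_frame_equal(res1.table, res2.table)

    def test_spiked_usage_events_recovered(self, spiked_run):
        truth = spiked_run.sim.truth
        tbl = spiked_run.table
        ev = truth[truth["class"] == "group1"]
        present = [j for j in ev["junction_id"] if j in tbl.index]
        assert len(present) >= 0.9 * len(ev)
        hits = tbl.loc[present]
        assert (hits["rel_fdr"] < 0.05).mean() >= 0.8
        assert (hits["group"] == 1).mean() >= 0.7

    def test_null_simulation_controls_fdr(self, null_run):
        tbl = null_run.table
        frac = (tbl["rel_fdr"] < 0.05).mean()
        n = tbl["rel_fdr"].notna().sum()
        assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n)

    def test_summaries_count_expressing_samples(self, spiked_run):
        tbl = spiked_run.table
        m = spiked_run.matrix
        jid = tbl.index[0]
        test_cols = [s for s in m.samples if s.startswith("test")]
        assert tbl.loc[jid, "n_expr_test"] == (m.counts.loc[jid, test_cols] > 0).sum()
        assert tbl.loc[jid, "mean_test"] == pytest.approx(
            m.counts.loc[jid, test_cols].mean()
        )


class TestSplicePlotData:
    def _table(self):
        idx = ["chr1:100:300:1", "chr1:50:80:1", "chr1:200:400:1"]
        return pd.DataFrame(
            {
                "gene_id": ["G"] * 3,
                "rel_logFC": [-2.0, 2.0, 1.8],
                "rel_fdr": [0.01, 0.2, 0.001],
                "neojunction": [False, False, True],
                "novel": [False, True, False],
            },
            index=idx,
        )

    def test_ordered_by_coordinate(self):
        data = jd.splice_plot_data(self._table(), "G")
        starts = [r["start"] for r in data["junctions"]]
        assert starts == sorted(starts) == [50, 100, 200]

    def test_color_classes(self):
        recs = {r["junction_id"]: r for r in jd.splice_plot_data(self._table(), "G")["junctions"]}
        assert recs["chr1:100:300:1"]["color_class"] == "down"
        assert recs["chr1:200:400:1"]["color_class"] == "up"
        assert recs["chr1:50:80:1"]["color_class"] == "suprathreshold-nonsignificant"

    def test_unknown_gene_lists_near_matches(self):
        with pytest.raises(KeyError, match="close matches"):
            jd.splice_plot_data(self._table(), "H")
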