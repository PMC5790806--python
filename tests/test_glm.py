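"""Ordered/binary logistic fits, two-way clustered sandwich, LR test, FDR,
deviation coding — each checked against an independent oracle."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import special
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.stats.multitest import multipletests

import neurodyad as nd
from neurodyad.glm import fit_linear, oneway_cluster_vcov, robust_vcov


def ordered_data(rng, n=400, beta=(-0.7, 0.3), cuts=(-1.0, 0.5, 1.5)):
    x = rng.standard_normal((n, len(beta)))
    latent = x @ np.asarray(beta) + rng.logistic(size=n)
    y = np.digitize(-latent, np.asarray(cuts)) + 1  # logit P(Y<=k) = tau_k - x'b
    return pd.DataFrame({"distance": y, "a": x[:, 0], "b": x[:, 1]})


class TestOrderedLogit:
    def test_matches_independent_mle(self):
        """Coefficients, thresholds and log-likelihood agree with an
        independently implemented proportional-odds fit."""
        tab = ordered_data(np.random.default_rng(0))
        fit = nd.fit_ordered_logit(tab, ["a", "b"], standardize=False, cluster="none")
        om = OrderedModel(tab["distance"], tab[["a", "b"]], distr="logit").fit(
            method="bfgs", disp=0
        )
        # statsmodels parameterizes P(Y<=k) = F(thresh_k + x'(-coef))
        assert np.allclose(fit.beta, om.params[:2], atol=1e-5)
        thresh = om.model.transform_threshold_params(om.params.to_numpy()[2:])[1:-1]
        assert np.allclose(fit.tau, thresh, atol=1e-4)
        assert fit.loglik == pytest.approx(om.llf, abs=1e-6)
        assert np.allclose(fit.se, om.bse[:2], rtol=1e-3)

    def test_two_category_fit_equals_binary_logit(self):
        rng = np.random.default_rng(1)
        tab = ordered_data(rng, cuts=(0.0,))
        tab["friend"] = (tab["distance"] == 1).astype(int)
        fo = nd.fit_ordered_logit(tab, ["a", "b"], standardize=False, cluster="none")
        fb = nd.fit_binary_logit(tab, ["a", "b"], standardize=False, cluster="none")
        # P(Y=1) = F(tau - x'b_ord) = F(intercept + x'b_bin) => b_bin = -b_ord
        assert np.allclose(fo.beta, -fb.beta, atol=1e-6)
        assert fo.loglik == pytest.approx(fb.loglik, abs=1e-8)

    def test_standardization_invariance(self):
        tab = ordered_data(np.random.default_rng(2))
        tab["a"] = 3.0 * tab["a"] + 5.0
        raw = nd.fit_ordered_logit(tab, ["a", "b"], standardize=False, cluster="none")
        std = nd.fit_ordered_logit(tab, ["a", "b"], standardize=True, cluster="none")
        sds = tab[["a", "b"]].std(ddof=1).to_numpy()
        assert np.allclose(std.beta, raw.beta * sds, atol=1e-8)

    def test_single_category_rejected(self):
        tab = pd.DataFrame({"distance": [2, 2, 2], "a": [0.1, 0.2, 0.3]})
        with pytest.raises(ValueError, match="categories"):
            nd.fit_ordered_logit(tab, ["a"], cluster="none")


class TestBinaryLogit:
    def test_matches_statsmodels(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((500, 2))
        y = (rng.random(500) < special.expit(0.4 * x[:, 0] - 0.2)).astype(int)
        tab = pd.DataFrame({"friend": y, "a": x[:, 0], "b": x[:, 1]})
        fit = nd.fit_binary_logit(tab, ["a", "b"], standardize=False, cluster="none")
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert np.allclose(fit.beta, ref.params[1:], atol=1e-8)
        assert fit.loglik == pytest.approx(ref.llf)

    def test_zero_predictor_gives_prevalence_intercept(self):
        tab = pd.DataFrame({"friend": [1, 0, 0, 0, 1, 0], "a": [0.0] * 6})
        with pytest.warns(UserWarning, match="rank deficient"):
            fit = nd.fit_binary_logit(tab, ["a"], standardize=False, cluster="none")
        assert fit.beta[0] == pytest.approx(0.0, abs=1e-10)
        assert fit.intercept == pytest.approx(special.logit(2 / 6), abs=1e-8)

    def test_perfect_separation_flagged(self):
        tab = pd.DataFrame(
            {"friend": [0, 0, 0, 1, 1, 1], "a": [-1.0, -1.0, -1.0, 1.0, 1.0, 1.0]}
        )
        with pytest.raises(nd.ConvergenceError):
            nd.fit_binary_logit(tab, ["a"], standardize=False, cluster="none")

    def test_recovers_planted_coefficient(self, simulate_ordered_logit):
        rng = np.random.default_rng(4)
        estimates = []
        for _ in range(20):
            x = rng.standard_normal((5000, 1))
            y = (rng.random(5000) < special.expit(0.4 * x[:, 0])).astype(int)
            tab = pd.DataFrame({"friend": y, "a": x[:, 0]})
            estimates.append(
                nd.fit_binary_logit(tab, ["a"], standardize=False,
                                    cluster="none").beta[0]
            )
        assert abs(np.mean(estimates) - 0.4) < 0.05


class TestTwowayClusterVcov:
    def _ols(self, x, y, tab):
        names = [f"b{k}" for k in range(x.shape[1])]
        return fit_linear(tab, x, y, names, cluster="robust")

    def test_singleton_clusters_reduce_to_hc0(self):
        rng = np.random.default_rng(5)
        x = np.column_stack([np.ones(30), rng.standard_normal(30)])
        y = x @ [1.0, 2.0] + rng.standard_normal(30)
        tab = pd.DataFrame(index=range(30))
        fit = self._ols(x, y, tab)
        ids = np.arange(30)
        v2 = nd.twoway_cluster_vcov(fit, ids, ids, psd_repair=False)
        assert np.allclose(v2, robust_vcov(fit), atol=1e-12)

    def test_matches_hand_computed_sandwich_on_six_observations(self):
        """Brute-force computation of the three sandwich components."""
        x = np.column_stack([np.ones(6), [0.5, -1.2, 0.3, 2.0, -0.7, 1.1]])
        y = np.array([1.0, 0.2, -0.5, 2.5, 0.0, 1.7])
        g1 = np.array(["a", "a", "b", "b", "c", "c"])
        g2 = np.array(["u", "v", "u", "v", "u", "v"])
        tab = pd.DataFrame(index=range(6))
        fit = self._ols(x, y, tab)
        coef = np.linalg.solve(x.T @ x, x.T @ y)
        resid = y - x @ coef
        scores = x * resid[:, None]
        binv = np.linalg.inv(x.T @ x)

        def meat(groups):
            m = np.zeros((2, 2))
            for g in np.unique(groups):
                s = scores[groups == g].sum(axis=0)
                m += np.outer(s, s)
            return m

        inter = np.array([a + b for a, b in zip(g1, g2)])
        expect = binv @ (meat(g1) + meat(g2) - meat(inter)) @ binv
        got = nd.twoway_cluster_vcov(fit, g1, g2, psd_repair=False)
        assert np.allclose(got, expect, atol=1e-12)

    def test_duplication_changes_naive_but_not_clustered_structure(self):
        """Duplicating every dyad halves naive variance (SE / sqrt(2)) but must
        not shrink clustered SEs the same way."""
        rng = np.random.default_rng(6)
        n = 80
        pairs = [(f"p{i}", f"p{j}") for i in range(10) for j in range(i + 1, 10)][:n]
        x = rng.standard_normal(len(pairs))
        y = 0.5 * x + rng.standard_normal(len(pairs))
        tab = pd.DataFrame(
            {"subject_i": [p[0] for p in pairs], "subject_j": [p[1] for p in pairs]}
        )
        design = np.column_stack([np.ones(len(pairs)), x])
        fit = fit_linear(tab, design, y, ["c", "x"], cluster="twoway")
        tab2 = pd.concat([tab, tab], ignore_index=True)
        fit2 = fit_linear(
            tab2, np.vstack([design, design]), np.concatenate([y, y]),
            ["c", "x"], cluster="twoway",
        )
        assert np.allclose(fit2.beta, fit.beta, atol=1e-10)
        naive1 = np.sqrt(np.diag(robust_vcov(fit)))[1]
        naive2 = np.sqrt(np.diag(robust_vcov(fit2)))[1]
        assert naive2 == pytest.approx(naive1 / np.sqrt(2), rel=1e-6)
        ratio = fit2.se[1] / fit.se[1]
        assert abs(ratio - 1 / np.sqrt(2)) > 0.05  # clustered SEs do not shrink by sqrt 2

    def test_mismatched_id_lengths_rejected(self):
        rng = np.random.default_rng(7)
        x = np.column_stack([np.ones(10), rng.standard_normal(10)])
        fit = self._ols(x, rng.standard_normal(10), pd.DataFrame(index=range(10)))
        with pytest.raises(ValueError, match="length|match"):
            nd.twoway_cluster_vcov(fit, np.arange(9), np.arange(10))

    def test_vcov_is_psd_after_repair(self):
        rng = np.random.default_rng(8)
        tab = ordered_data(rng, n=200)
        tab["subject_i"] = [f"s{k % 14}" for k in range(200)]
        tab["subject_j"] = [f"t{k % 11}" for k in range(200)]
        fit = nd.fit_ordered_logit(tab, ["a", "b"], standardize=False)
        assert np.linalg.eigvalsh(fit.vcov).min() >= -1e-10


class TestLrTest:
    def test_identical_models_give_zero(self):
        tab = ordered_data(np.random.default_rng(9))
        fit = nd.fit_ordered_logit(tab, ["a"], standardize=False, cluster="none")
        chi2, df, p = nd.lr_test(fit, fit)
        assert chi2 == 0.0 and df == 0 and p == 1.0

    def test_strong_predictor_highly_significant(self):
        tab = ordered_data(np.random.default_rng(10), n=800, beta=(-0.8, 0.0))
        full = nd.fit_ordered_logit(tab, ["a", "b"], standardize=False, cluster="none")
        red = nd.fit_ordered_logit(tab, ["b"], standardize=False, cluster="none")
        chi2, df, p = nd.lr_test(full, red)
        assert df == 1 and p < 1e-6

    def test_non_nested_rejected(self):
        tab = ordered_data(np.random.default_rng(11))
        fa = nd.fit_ordered_logit(tab, ["a"], standardize=False, cluster="none")
        fb = nd.fit_ordered_logit(tab, ["b"], standardize=False, cluster="none")
        with pytest.raises(ValueError, match="nested"):
            nd.lr_test(fa, fb)


def brute_force_bh(pvals):
    """Step-up BH written from the definition."""
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


class TestFdr:
    def test_hand_computed_example(self):
        adj = brute_force_bh([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, 0.04)
        _, sm_adj, *_ = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")
        assert np.allclose(sm_adj, adj)

    def test_bh_agrees_with_step_up_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            m = rng.integers(1, 7)
            p = rng.random(m)
            _, adj, *_ = multipletests(p, method="fdr_bh")
            assert np.allclose(adj, brute_force_bh(p), atol=1e-12)

    def test_per_roi_regressions_single_roi_adjusted_equals_raw(self, dyad_table):
        out = nd.per_roi_regressions(
            dyad_table, ["diff_gender", "age_diff"], roi_columns=[dyad_table.columns[10]]
        )
        assert out["p_fdr"].iloc[0] == pytest.approx(out["p_raw"].iloc[0])

    def test_identical_columns_give_identical_betas(self, dyad_table):
        tab = dyad_table.copy()
        col = [c for c in tab.columns if c.startswith("z_")][0]
        tab["z_copy1"] = tab[col]
        tab["z_copy2"] = tab[col]
        out = nd.per_roi_regressions(
            tab, ["diff_gender"], roi_columns=["z_copy1", "z_copy2"]
        )
        assert out["beta"].iloc[0] == pytest.approx(out["beta"].iloc[1], abs=1e-8)

    def test_adjusted_p_monotone_and_at_least_raw(self, dyad_table):
        out = nd.per_roi_regressions(dyad_table, ["diff_gender"])
        ok = out.dropna(subset=["p_fdr"]).sort_values("p_raw")
        assert (ok["p_fdr"].to_numpy() >= ok["p_raw"].to_numpy() - 1e-12).all()
        assert (np.diff(ok["p_fdr"].to_numpy()) >= -1e-12).all()


class TestOddsInterpretation:
    @pytest.mark.parametrize(
        "beta,expected",
        [(0.0, 0), (np.log(2), 100)],
    )
    def test_reference_points(self, beta, expected):
        assert round(nd.odds_interpretation(beta)) == expected


class TestDeviationCoding:
    def _table(self, sims, cats, extra=None):
        n = len(sims)
        tab = pd.DataFrame(
            {
                "similarity": sims,
                "distance": cats,
                "subject_i": [f"a{k}" for k in range(n)],
                "subject_j": [f"b{k}" for k in range(n)],
            }
        )
        if extra is not None:
            tab["ctrl"] = extra
        return tab

    def test_constant_similarity_gives_zero_estimates(self):
        tab = self._table([0.5] * 12, [1, 2, 3, 4] * 3)
        out = nd.deviation_coded_estimates(tab)
        assert np.allclose(out["estimate"], 0.0, atol=1e-12)

    def test_two_category_contrast_arithmetic(self):
        tab = self._table([1.0, 1.0, -1.0, -1.0], [1, 1, 2, 2])
        out = nd.deviation_coded_estimates(tab)
        assert np.allclose(out["estimate"], [2.0, -2.0])

    def test_orthogonal_control_leaves_estimates_unchanged(self):
        rng = np.random.default_rng(13)
        cats = np.repeat([1, 2, 3], 12)
        sims = rng.standard_normal(36) + 0.3 * cats
        # control orthogonal to the category dummies: zero mean in each category
        ctrl = np.tile([1.0, -1.0] * 6, 3)
        base = nd.deviation_coded_estimates(self._table(sims, cats))
        with_ctrl = nd.deviation_coded_estimates(
            self._table(sims, cats, extra=ctrl), controls=["ctrl"]
        )
        assert np.allclose(base["estimate"], with_ctrl["estimate"], atol=1e-10)

    def test_single_category_rejected(self):
        with pytest.raises(ValueError, match="categories"):
            nd.deviation_coded_estimates(self._table([1.0, 2.0], [1, 1]))
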