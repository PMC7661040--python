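"""Feature PCA, OLS against the normal-equations oracle, attenuation
arithmetic, caloric-restriction models, and the Kruskal-Wallis test."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

import methclock as mc


def ols_oracle(y, X):
    """Closed-form normal equations with classical standard errors."""
    X = np.column_stack([np.ones(len(y)), X])
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    sigma2 = resid @ resid / (len(y) - X.shape[1])
    se = np.sqrt(np.diag(XtX_inv) * sigma2)
    t = beta / se
    p = 2 * scipy.stats.t.sf(np.abs(t), len(y) - X.shape[1])
    return beta, se, t, p


class TestFeaturePCA:
    def test_dominant_shared_factor(self):
        # features are z-scored, so dominance means shared structure: a
        # latent factor loading on most features is what PC1 must recover
        rng = np.random.default_rng(0)
        n = 30
        factor = rng.normal(size=n)
        table = pd.DataFrame({
            f"f{j}": factor + rng.normal(0, 0.1, size=n) for j in range(5)
        } | {"noise": rng.normal(size=n)}, index=[f"S{i}" for i in range(n)])
        scores = mc.pca_reduce(table, table.index, n_pcs=1)
        assert abs(np.corrcoef(scores["PC1"], factor)[0, 1]) > 0.99

    def test_loadings_match_dense_eigensolver(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(rng.normal(size=(25, 6)),
                             index=[f"S{i}" for i in range(25)])
        est = mc.FeaturePCA(n_components=3).fit(table)
        Z = (table.to_numpy() - est.mean_) / est.sd_
        evals, evecs = np.linalg.eigh(np.cov(Z.T, bias=True))
        top = evecs[:, np.argsort(evals)[::-1][:3]]
        P1 = est.loadings_ @ est.loadings_.T
        P2 = top @ top.T
        np.testing.assert_allclose(P1, P2, atol=1e-8)

    def test_scores_standardised_and_age_oriented(self, small_bundle, sample_frames):
        rats, _ = sample_frames
        pheno = small_bundle.pheno
        ages = rats.loc[pheno.index, "age_months"].to_numpy()
        scores = mc.pca_reduce(pheno, pheno.index, n_pcs=2, train_ages=ages)
        assert scores["PC1"].std(ddof=0) == pytest.approx(1.0)
        assert np.corrcoef(scores["PC1"], ages)[0, 1] > 0

    def test_facs_pc1_outranks_pheno_pc1_in_age_correlation(
            self, small_bundle, sample_frames):
        """Cell composition tracks age more tightly than behaviour."""
        rats, _ = sample_frames
        ages = rats.loc[small_bundle.facs.index, "age_months"].to_numpy()
        facs_pc1 = mc.pca_reduce(small_bundle.facs, small_bundle.facs.index,
                                 n_pcs=1, train_ages=ages)["PC1"]
        pheno_pc1 = mc.pca_reduce(small_bundle.pheno, small_bundle.pheno.index,
                                  n_pcs=1, train_ages=ages)["PC1"]
        r_facs = mc.bicor(facs_pc1.to_numpy(), ages)
        r_pheno = mc.bicor(pheno_pc1.to_numpy(), ages)
        assert r_facs > 0 and r_pheno > 0
        assert r_facs > r_pheno

    def test_zero_variance_feature_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame({"a": rng.normal(size=10),
                              "b": np.ones(10),
                              "c": rng.normal(size=10)})
        est = mc.FeaturePCA(n_components=2)
        est.fit(table)
        assert "b" not in est.feature_names_


class TestOLS:
    def test_exact_linear_relationship(self):
        x = np.arange(10.0)
        y = 3.0 + 2.0 * x
        fit = mc.ols(y, pd.DataFrame({"x": x}))
        assert fit.terms["x"] == pytest.approx(2.0, abs=1e-10)
        assert fit.terms["const"] == pytest.approx(3.0, abs=1e-10)
        assert fit.p["x"] < 1e-12

    def test_six_point_hand_dataset(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.0, 4.1, 5.9, 8.2, 9.8, 12.1])
        fit = mc.ols(y, pd.DataFrame({"x": x}))
        beta, se, t, p = ols_oracle(y, x[:, None])
        assert fit.terms["const"] == pytest.approx(beta[0], abs=1e-10)
        assert fit.terms["x"] == pytest.approx(beta[1], abs=1e-10)
        assert fit.se["x"] == pytest.approx(se[1], abs=1e-10)
        assert fit.p["x"] == pytest.approx(p[1], rel=1e-8)

    def test_matches_normal_equations_on_random_designs(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = int(rng.integers(8, 30))
            k = int(rng.integers(1, 4))
            X = rng.normal(size=(n, k))
            y = rng.normal(size=n)
            fit = mc.ols(y, pd.DataFrame(X, columns=[f"x{j}" for j in range(k)]))
            beta, se, *_ = ols_oracle(y, X)
            np.testing.assert_allclose(fit.terms.to_numpy(), beta, atol=1e-8)
            np.testing.assert_allclose(fit.se.to_numpy(), se, atol=1e-8)

    def test_residuals_sum_to_zero_with_intercept(self):
        rng = np.random.default_rng(4)
        fit = mc.ols(rng.normal(size=20),
                     pd.DataFrame({"x": rng.normal(size=20)}))
        assert fit.residuals.sum() == pytest.approx(0.0, abs=1e-9)

    def test_rank_deficiency_names_collinear_term(self):
        x = np.arange(8.0)
        with pytest.raises(ValueError, match="x2"):
            mc.ols(np.ones(8), pd.DataFrame({"x1": x, "x2": 2 * x}))


class TestAttenuation:
    def test_table_one_worked_example(self):
        assert mc.attenuation(0.75, 0.63) == pytest.approx(16.0)

    def test_no_change_is_zero(self):
        assert mc.attenuation(1.0, 1.0) == 0.0

    def test_model_three_arithmetic(self):
        assert mc.attenuation(0.75, 0.42) == pytest.approx(44.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(-10, 10), st.floats(-10, 10),
           st.floats(-5, 5).filter(lambda c: abs(c) > 1e-3))
    def test_scale_invariance(self, b1, b2, c):
        if abs(b1) < 1e-6:
            return
        assert mc.attenuation(c * b1, c * b2) == pytest.approx(
            mc.attenuation(b1, b2), rel=1e-6, abs=1e-6)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ZeroDivisionError):
            mc.attenuation(0.0, 0.5)


def _cr_cohort(rng, n=160, n_cr=24, effect=-1.2):
    ages = rng.uniform(4, 30, size=n)
    cr = np.zeros(n, bool)
    cr[rng.choice(n, size=n_cr, replace=False)] = True
    diet = np.where(cr, "CR", "AL")
    dnam = 0.8 * ages + 3 + effect * cr + rng.normal(0, 1.2, size=n)
    return dnam, ages, diet


class TestCREffect:
    def test_planted_shift_recovered_within_two_se(self):
        """Planted -1.2 month CR shift recovered in >= 18/20 seeds."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            dnam, ages, diet = _cr_cohort(rng)
            fit = mc.cr_effect(dnam, ages, diet)
            if abs(fit.terms["CR"] - (-1.2)) <= 2 * fit.se["CR"]:
                hits += 1
        assert hits >= 18

    def test_null_effect_calibration(self):
        """No planted effect: |t| < 2 in at least 90% of 50 seeds."""
        calm = 0
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            dnam, ages, diet = _cr_cohort(rng, effect=0.0)
            fit = mc.cr_effect(dnam, ages, diet)
            if abs(fit.t["CR"]) < 2:
                calm += 1
        assert calm >= 45

    def test_single_diet_group_rejected(self):
        rng = np.random.default_rng(5)
        dnam, ages, _ = _cr_cohort(rng)
        with pytest.raises(ValueError, match="diet"):
            mc.cr_effect(dnam, ages, np.repeat("AL", len(ages)))


class TestCRInteraction:
    def test_duration_scaled_effect_gives_negative_interaction(self):
        recovered = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 170
            ages = rng.uniform(4, 30, size=n)
            cr = np.zeros(n, bool); cr[:25] = True
            dnam = 0.8 * ages + 3 - 0.12 * ages * cr + rng.normal(0, 1.0, size=n)
            fit = mc.cr_interaction(dnam, ages, np.where(cr, "CR", "AL"))
            if abs(fit.terms["age_x_CR"] - (-0.12)) <= 2 * fit.se["age_x_CR"]:
                recovered += 1
        assert recovered >= 9

    def test_centering_age_leaves_interaction_unchanged(self):
        rng = np.random.default_rng(6)
        dnam, ages, diet = _cr_cohort(rng)
        fit = mc.cr_interaction(dnam, ages, diet)
        fit_centred = mc.cr_interaction(dnam, ages - ages.mean(), diet)
        assert fit.terms["age_x_CR"] == pytest.approx(
            fit_centred.terms["age_x_CR"], abs=1e-10)


class TestCRDurationResidual:
    def test_duration_proportional_effect_gives_negative_correlation(self):
        rng = np.random.default_rng(7)
        n, n_cr = 120, 20
        ages = rng.uniform(4, 30, size=n)
        duration = np.zeros(n)
        cr = np.zeros(n, bool); cr[:n_cr] = True
        duration[cr] = rng.uniform(6.5, 23, size=n_cr)
        dnam = 0.8 * ages + 3 - 0.12 * duration + rng.normal(0, 0.8, size=n)
        r, p = mc.cr_duration_residual(dnam, ages, np.where(cr, "CR", "AL"), duration)
        assert r < 0

    def test_null_correlation_within_sampling_bounds(self):
        rs = []
        for seed in range(30):
            rng = np.random.default_rng(2000 + seed)
            n, n_cr = 120, 20
            ages = rng.uniform(4, 30, size=n)
            duration = np.zeros(n)
            cr = np.zeros(n, bool); cr[:n_cr] = True
            duration[cr] = rng.uniform(6.5, 23, size=n_cr)
            dnam = 0.8 * ages + 3 + rng.normal(0, 0.8, size=n)
            r, _ = mc.cr_duration_residual(dnam, ages, np.where(cr, "CR", "AL"),
                                           duration)
            rs.append(r)
        assert abs(np.mean(rs)) < 2 / np.sqrt(20)

    def test_equal_durations_rejected(self):
        rng = np.random.default_rng(8)
        dnam, ages, diet = _cr_cohort(rng)
        duration = np.where(np.asarray(diet) == "CR", 10.0, 0.0)
        with pytest.raises(ValueError, match="equal"):
            mc.cr_duration_residual(dnam, ages, diet, duration)


class TestKruskalWallis:
    def test_hand_computed_three_group_example(self):
        values = np.array([27.0, 2.0, 4.0, 18.0, 7.0, 9.0, 1.0, 5.0, 11.0])
        groups = np.array(list("aaabbbccc"))
        # ranks: 9,2,3 | 8,5,6 | 1,4,7 -> H by the textbook formula
        ranks = scipy.stats.rankdata(values)
        n = len(values)
        h = 12 / (n * (n + 1)) * sum(
            len(ranks[groups == g]) * ranks[groups == g].mean() ** 2
            for g in "abc") - 3 * (n + 1)
        got_h, got_p = mc.kruskal_wallis(values, groups)
        assert got_h == pytest.approx(h, abs=1e-10)
        assert got_p == pytest.approx(scipy.stats.chi2.sf(h, 2), abs=1e-12)

    def test_two_group_consistency_with_rank_sum(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=14)
        groups = np.repeat(["a", "b"], 7)
        h, p = mc.kruskal_wallis(x, groups)
        # H for two groups equals the squared standardised rank-sum statistic
        ranks = scipy.stats.rankdata(x)
        ra = ranks[:7].sum()
        n, n1, n2 = 14, 7, 7
        expected = (ra - n1 * (n + 1) / 2) ** 2 / (n1 * n2 * (n + 1) / 12)
        assert h == pytest.approx(expected, abs=1e-10)

    def test_null_rarely_rejects(self):
        calm = 0
        for seed in range(40):
            rng = np.random.default_rng(3000 + seed)
            values = rng.permutation(np.arange(1.0, 25.0))
            groups = np.repeat(["a", "b", "c"], 8)
            _, p = mc.kruskal_wallis(values, groups)
            calm += p > 0.05
        assert calm >= 36

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mc.kruskal_wallis(np.arange(5.0), np.repeat("a", 5))

    def test_module_loadings_differ_across_modules(self, small_bundle, rat_matrix,
                                                   sample_frames):
        """PC1 loadings grouped by planted module separate from grey."""
        rats, _ = sample_frames
        model = mc.fit_pca(rat_matrix.X, n_components=1, sites=rat_matrix.site_ids)
        loadings = pd.Series(model.loadings[:, 0], index=rat_matrix.site_ids)
        labels = pd.Series("grey", index=rat_matrix.site_ids, dtype=object)
        for name, members in small_bundle.manifest["module_members"].items():
            labels.loc[[m for m in members if m in labels.index]] = name
        h, p = mc.kruskal_wallis(np.abs(loadings.to_numpy()), labels.to_numpy())
        assert p < 0.05
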