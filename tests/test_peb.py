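import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from dcmerf.params import GaussianBelief
from dcmerf.peb import (DesignMatrix, PEBSettings, fit_peb, peb_log_evidence,
                        peb_of_pebs, threshold_effects)


def _beliefs_1d(rng, theta_means, post_var=0.01, prior_var=0.25):
    names = ("w",)
    prior = GaussianBelief(names, np.zeros(1), np.array([[prior_var]]))
    posts = [GaussianBelief(names, np.array([m]), np.array([[post_var]]))
             for m in theta_means]
    return posts, prior


class TestEvidenceOracle:
    def test_matches_numerical_quadrature(self):
        """Exact Gaussian-algebra evidence vs brute-force 1-D quadrature
        of the hierarchical integrals (p = 1)."""
        rng = np.random.default_rng(0)
        theta_means = [0.12, -0.05, 0.3]
        post_var, prior_var = 0.02, 0.25
        posts, prior = _beliefs_1d(rng, theta_means, post_var, prior_var)
        X = DesignMatrix.mean_only(3).add_contrast("c", [1.0, -1.0, 0.0])
        settings = PEBSettings()
        gamma = 1.3
        g_var = np.exp(-gamma) * prior_var
        b0 = settings.beta_prior_scale * prior_var

        th = np.linspace(-3, 3, 4001)
        dth = th[1] - th[0]

        def subject_factor(m_i, mu_i):
            # int q(th)/p0(th) N(th; m_i, g_var) dth by quadrature
            q = norm.pdf(th, mu_i, np.sqrt(post_var))
            p0 = norm.pdf(th, 0.0, np.sqrt(prior_var))
            g = norm.pdf(th, m_i, np.sqrt(g_var))
            return np.sum(q / p0 * g) * dth

        bs = np.linspace(-2.5, 2.5, 401)
        db = bs[1] - bs[0]
        total = 0.0
        for b_mean in bs:
            for b_c in bs[::8]:
                w = (norm.pdf(b_mean, 0, np.sqrt(b0))
                     * norm.pdf(b_c, 0, np.sqrt(b0)))
                prod = w
                for x, mu_i in zip(X.values, theta_means):
                    prod *= subject_factor(x[0] * b_mean + x[1] * b_c, mu_i)
                total += prod * db * (db * 8)
        oracle = np.log(total)
        ours = peb_log_evidence(posts, X, prior, gamma, settings)
        assert ours == pytest.approx(oracle, abs=5e-3)


class TestFitPEB:
    def test_degenerate_identical_subjects_recover_shared_mean(self):
        names = ("a", "b")
        mu = np.array([0.12, -0.08])
        prior = GaussianBelief(names, np.zeros(2), np.diag([1 / 16, 1 / 16]))
        posts = [GaussianBelief(names, mu.copy(), np.diag([1e-8, 1e-8]))
                 for _ in range(10)]
        m = fit_peb(posts, DesignMatrix.mean_only(10), prior)
        np.testing.assert_allclose(m.beta_mean[0], mu, atol=1e-6)

    def test_group_effect_recovered_with_sign(self):
        rng = np.random.default_rng(1)
        n = 40
        codes = np.array([1.0, -1.0] * (n // 2))
        theta = 0.1 * codes + rng.normal(0, 0.05, n)
        posts, prior = _beliefs_1d(rng, theta, post_var=0.0025)
        X = DesignMatrix.mean_only(n).add_contrast("grp", codes)
        m = fit_peb(posts, X, prior)
        i = m.columns.index("grp")
        assert m.Pp[i, 0] > 0.95
        assert m.beta_mean[i, 0] > 0

    def test_zero_effect_column_keeps_low_posterior_probability(self):
        rng = np.random.default_rng(2)
        posts, prior = _beliefs_1d(rng, rng.normal(0, 0.05, 12))
        X = DesignMatrix.mean_only(12).add_contrast("null", np.zeros(12))
        m = fit_peb(posts, X, prior)
        i = m.columns.index("null")
        assert np.all(m.Pp[i] <= 0.5)

    def test_rank_deficient_design_names_columns(self):
        rng = np.random.default_rng(3)
        posts, prior = _beliefs_1d(rng, rng.normal(0, 0.1, 6))
        codes = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        X = (DesignMatrix.mean_only(6).add_contrast("c1", codes)
             .add_contrast("c2", 2 * codes))
        with pytest.raises(ValueError, match="c1|c2"):
            fit_peb(posts, X, prior)

    def test_misaligned_inputs_rejected(self):
        rng = np.random.default_rng(4)
        posts, prior = _beliefs_1d(rng, [0.1, 0.2])
        with pytest.raises(ValueError, match="match"):
            fit_peb(posts, DesignMatrix.mean_only(3), prior)

    def test_covariates_are_centred_and_scaled(self):
        X = DesignMatrix.mean_only(5).add_covariate("g", [1, 2, 3, 4, 5])
        col = X.frame["g"].to_numpy()
        assert col.mean() == pytest.approx(0.0, abs=1e-12)
        assert col.std(ddof=0) == pytest.approx(1.0)

    def test_first_column_must_be_ones(self):
        with pytest.raises(ValueError, match="ones"):
            DesignMatrix(pd.DataFrame({"mean": [1.0, 0.5]}))


class TestPEBofPEBs:
    def _group_peb(self, rng, effect=0.0, n=16, seed_shift=0.0):
        codes = np.array([1.0, -1.0] * (n // 2))
        theta = effect * codes + rng.normal(0, 0.05, n) + seed_shift
        posts, prior = _beliefs_1d(rng, theta, post_var=0.0025)
        X = DesignMatrix.mean_only(n).add_contrast("drug", codes)
        return fit_peb(posts, X, prior)

    def test_identical_pebs_show_no_group_difference(self):
        rng = np.random.default_rng(5)
        peb = self._group_peb(rng)
        X2 = DesignMatrix.mean_only(2).add_contrast("diff", [1.0, -1.0])
        third = peb_of_pebs([peb, peb], X2)
        i = third.columns.index("diff")
        np.testing.assert_allclose(third.beta_mean[i], 0.0, atol=1e-8)
        assert np.all(third.Pp[i] <= 0.5)

    def test_opposing_drug_effects_yield_interaction(self):
        rng = np.random.default_rng(6)
        pebs = [self._group_peb(rng, effect=0.0),
                self._group_peb(rng, effect=+0.12),
                self._group_peb(rng, effect=-0.12)]
        X2 = (DesignMatrix.mean_only(3)
              .add_contrast("g1-g2", [0.0, 1.0, -1.0]))
        third = peb_of_pebs(pebs, X2)
        i = third.columns.index("g1-g2")
        j = third.parameters.index("drug|w")
        assert third.Pp[i, j] > 0.95
        assert third.beta_mean[i, j] > 0

    def test_relabelling_symmetry(self):
        rng = np.random.default_rng(7)
        pebs = [self._group_peb(rng, effect=0.1),
                self._group_peb(rng, effect=0.0),
                self._group_peb(rng, seed_shift=0.05)]
        X2 = DesignMatrix.mean_only(3).add_contrast("c", [1.0, 0.0, -1.0])
        a = peb_of_pebs(pebs, X2)
        perm = [2, 0, 1]
        X2p = DesignMatrix(
            X2.frame.iloc[perm].reset_index(drop=True))
        b = peb_of_pebs([pebs[i] for i in perm], X2p)
        np.testing.assert_allclose(a.beta_mean, b.beta_mean, atol=1e-6)
        np.testing.assert_allclose(a.F, b.F, atol=1e-6)

    def test_mismatched_structure_rejected(self):
        rng = np.random.default_rng(8)
        peb1 = self._group_peb(rng)
        posts, prior = _beliefs_1d(rng, rng.normal(0, 0.1, 4))
        peb2 = fit_peb(posts, DesignMatrix.mean_only(4), prior)
        with pytest.raises(ValueError, match="structure"):
            peb_of_pebs([peb1, peb2],
                        DesignMatrix.mean_only(2))


class TestThresholdEffects:
    def test_threshold_extremes(self):
        rng = np.random.default_rng(9)
        posts, prior = _beliefs_1d(rng, 0.2 + rng.normal(0, 0.02, 10))
        m = fit_peb(posts, DesignMatrix.mean_only(10), prior)
        assert threshold_effects(m, 1.0).empty
        assert len(threshold_effects(m, 0.0)) == len(m.effect_names)

    def test_table_columns(self):
        rng = np.random.default_rng(10)
        posts, prior = _beliefs_1d(rng, rng.normal(0.3, 0.02, 10))
        m = fit_peb(posts, DesignMatrix.mean_only(10), prior)
        t = threshold_effects(m, 0.95)
        assert {"effect", "parameter", "beta", "Pp", "sign"} <= set(t.columns)
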