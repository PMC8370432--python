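import numpy as np
import pytest
from scipy.stats import multivariate_normal as mvn

from dcmerf.erf import ERFDataset
from dcmerf.inversion import (ERFModel, FreeEnergyResult, InversionSettings,
                              free_energy, invert, predict)
from dcmerf.params import GaussianBelief, ParameterSet


class LinearToyModel:
    """Identity-dynamics toy: predictions are X @ theta reshaped to one
    'source' — a conjugate linear-Gaussian instance with known evidence."""

    likelihood_stride = 1
    condition = False

    def __init__(self, X):
        from types import SimpleNamespace

        self.X = np.asarray(X)
        self.n_sources = 1
        self.time_ms = np.arange(self.X.shape[0], dtype=float)
        self.net = SimpleNamespace(sources=("lA1",))

    def predict(self, params: ParameterSet):
        th = params.values
        if th.ndim == 1:
            return (self.X @ th)[None, :], True
        out = th @ self.X.T
        return out[:, None, :], np.ones(th.shape[0], dtype=bool)


def _toy_problem(seed=0, n=30, p=3):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    names = tuple(f"t{i}" for i in range(p))
    prior = GaussianBelief(names, rng.normal(0, 0.2, p),
                           np.diag(rng.uniform(0.1, 0.5, p)))
    theta = prior.mean + prior.sd() * rng.normal(size=p)
    lam = 1.5  # log noise precision
    s2 = np.exp(-lam)
    y = X @ theta + rng.normal(0, np.sqrt(s2), n)
    data = ERFDataset(subject="toy", group="control", session="placebo",
                      condition="deviant", time_ms=np.arange(n, dtype=float),
                      erf=y[None, :], sources=("lA1",), conditioned=True)
    return X, prior, data, lam, y


class TestFreeEnergyConjugate:
    def test_matches_closed_form_log_marginal(self):
        for seed in range(5):
            X, prior, data, lam, y = _toy_problem(seed)
            model = LinearToyModel(X)
            settings = InversionSettings(fix_noise=True)
            # posterior mode: conjugate solution
            s2 = np.exp(-lam)
            P0 = prior.precision()
            Sig = np.linalg.inv(X.T @ X / s2 + P0)
            mu = Sig @ (X.T @ y / s2 + P0 @ prior.mean)
            point = GaussianBelief(prior.names, mu, prior.cov,
                                   hyper=np.array([lam]))
            fe = free_energy(point, data, model, prior, settings)
            analytic = mvn.logpdf(y, X @ prior.mean,
                                  s2 * np.eye(len(y)) + X @ prior.cov @ X.T)
            assert fe.F == pytest.approx(analytic, abs=1e-6)

    def test_complexity_equals_gaussian_kl(self):
        X, prior, data, lam, y = _toy_problem(1)
        model = LinearToyModel(X)
        settings = InversionSettings(fix_noise=True)
        s2 = np.exp(-lam)
        P0 = prior.precision()
        Sig = np.linalg.inv(X.T @ X / s2 + P0)
        mu = Sig @ (X.T @ y / s2 + P0 @ prior.mean)
        fe = free_energy(GaussianBelief(prior.names, mu, prior.cov,
                                        hyper=np.array([lam])),
                         data, model, prior, settings)
        d = mu - prior.mean
        kl = 0.5 * (np.trace(P0 @ Sig) + d @ P0 @ d - len(mu)
                    + np.linalg.slogdet(prior.cov)[1]
                    - np.linalg.slogdet(Sig)[1])
        assert fe.complexity == pytest.approx(kl, abs=1e-8)
        assert fe.complexity >= 0
        assert fe.F == pytest.approx(fe.accuracy - fe.complexity, abs=1e-10)

    def test_posterior_equal_to_prior_with_zero_residual_has_zero_complexity(self):
        p = 2
        X = np.zeros((5, p))
        names = ("a", "b")
        prior = GaussianBelief(names, np.zeros(p), np.eye(p) * 0.3)
        data = ERFDataset(subject="t", group="control", session="placebo",
                          condition="deviant", time_ms=np.arange(5.0),
                          erf=np.zeros((1, 5)), sources=("lA1",),
                          conditioned=True)
        fe = free_energy(GaussianBelief(names, prior.mean, prior.cov,
                                        hyper=np.array([0.0])),
                         data, LinearToyModel(X), prior,
                         InversionSettings(fix_noise=True))
        # no data information: posterior = prior, residuals zero
        assert fe.complexity == pytest.approx(0.0, abs=1e-10)

    def test_unused_parameter_penalised_by_its_prior_kl(self):
        """A parameter with no effect on predictions leaves F unchanged
        while it sits at its prior mean, and lowers F by exactly its
        Gaussian prior penalty when estimated away from it."""
        X, prior, data, lam, y = _toy_problem(2)
        settings = InversionSettings(fix_noise=True)
        s2 = np.exp(-lam)
        P0 = prior.precision()
        Sig = np.linalg.inv(X.T @ X / s2 + P0)
        mu = Sig @ (X.T @ y / s2 + P0 @ prior.mean)
        fe_small = free_energy(
            GaussianBelief(prior.names, mu, prior.cov, hyper=np.array([lam])),
            data, LinearToyModel(X), prior, settings)
        Xa = np.hstack([X, np.zeros((X.shape[0], 1))])
        names_a = prior.names + ("unused",)
        m_u, v_u = 0.3, 0.2
        prior_a = GaussianBelief(names_a, np.r_[prior.mean, m_u],
                                 np.diag(np.r_[np.diag(prior.cov), v_u]))
        toy_a = LinearToyModel(Xa)
        at_prior_mean = free_energy(
            GaussianBelief(names_a, np.r_[mu, m_u], prior_a.cov,
                           hyper=np.array([lam])),
            data, toy_a, prior_a, settings)
        assert at_prior_mean.F == pytest.approx(fe_small.F, abs=1e-8)
        displaced = free_energy(
            GaussianBelief(names_a, np.r_[mu, 0.0], prior_a.cov,
                           hyper=np.array([lam])),
            data, toy_a, prior_a, settings)
        assert displaced.F < fe_small.F
        assert fe_small.F - displaced.F == pytest.approx(
            0.5 * m_u**2 / v_u, abs=1e-8)


class TestInvertLinearOracle:
    def test_posterior_matches_conjugate_closed_form(self):
        X, prior, data, lam, y = _toy_problem(3)
        model = LinearToyModel(X)
        settings = InversionSettings(fix_noise=True, hyper_mean=lam)
        post = invert(data, model, prior, settings)
        s2 = np.exp(-lam)
        P0 = prior.precision()
        Sig = np.linalg.inv(X.T @ X / s2 + P0)
        mu = Sig @ (X.T @ y / s2 + P0 @ prior.mean)
        np.testing.assert_allclose(post.mean, mu, rtol=1e-6, atol=1e-8)
        np.testing.assert_allclose(post.cov, Sig, rtol=1e-5, atol=1e-8)

    def test_inversion_is_deterministic(self):
        X, prior, data, lam, y = _toy_problem(4)
        model = LinearToyModel(X)
        a = invert(data, model, prior, InversionSettings())
        b = invert(data, model, prior, InversionSettings())
        np.testing.assert_array_equal(a.mean, b.mean)
        np.testing.assert_array_equal(a.cov, b.cov)
        assert a.F == b.F


class TestInvertERFModel:
    def test_low_noise_recovery_within_two_posterior_sd(self, recovered_posterior,
                                                        single_source_prior):
        post = recovered_posterior["posterior"]
        theta = recovered_posterior["theta_true"]
        within = np.abs(post.mean - theta) <= 2 * post.sd()
        assert within.mean() >= 0.9
        assert post.meta["fit"]["median_r"] > 0.99

    def test_accepted_free_energy_trace_is_monotone(self, recovered_posterior):
        tr = recovered_posterior["posterior"].meta["F_trace"]
        assert len(tr) >= 2
        assert all(b >= a for a, b in zip(tr, tr[1:]))

    def test_prediction_depends_only_on_posterior_mean(self, recovered_posterior,
                                                       single_source_model):
        post = recovered_posterior["posterior"]
        ds1, _ = predict(post, single_source_model)
        jittered = post.copy()
        jittered.cov = post.cov * 2.0
        ds2, _ = predict(jittered, single_source_model)
        np.testing.assert_array_equal(ds1.erf, ds2.erf)

    def test_self_prediction_correlation(self, recovered_posterior,
                                         single_source_model):
        """Prediction at the generating parameters reproduces noiseless
        data essentially perfectly."""
        clean = recovered_posterior["clean"]
        theta = recovered_posterior["theta_true"]
        gen = GaussianBelief(recovered_posterior["posterior"].names, theta,
                             np.eye(theta.size))
        ds, _ = predict(gen, single_source_model)
        r = np.corrcoef(ds.erf[0], clean.erf[0])[0, 1]
        assert r >= 0.999

    def test_white_noise_data_fits_poorly(self, single_source_model,
                                          single_source_prior):
        rng = np.random.default_rng(0)
        t = single_source_model.time_ms
        rs = []
        for _ in range(3):
            noise = ERFDataset(subject="n", group="control", session="placebo",
                               condition="deviant", time_ms=t,
                               erf=rng.normal(size=(1, t.size)),
                               sources=("lA1",), conditioned=False)
            post = invert(noise, single_source_model, single_source_prior,
                          InversionSettings(max_iter=8))
            r = post.meta["fit"]["median_r"]
            rs.append(0.0 if r is None else r)
        assert np.median(np.abs(rs)) < 0.3
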