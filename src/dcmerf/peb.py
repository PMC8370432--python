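"""Parametric empirical Bayes over subjects' parameter posteriors.

The hierarchical model places a general linear model over subjects'
first-level parameters:

    theta_i = B' x_i + eps_i,      eps_i ~ N(0, Gamma)
    vec(B) ~ N(0, B0)

where ``x_i`` is subject *i*'s row of the between-subject design matrix,
``B`` the (columns x parameters) matrix of second-level effects and
``Gamma`` the between-subject covariance, parameterized by a scalar
log-precision ``gamma``: ``Gamma = exp(-gamma) * diag(first-level prior
variances)``.

Because the first level is Gaussian, each subject's data enter only through
the information form of their likelihood, reconstructed from posterior and
prior as ``Lambda_i = P_i - P0`` and ``h_i = P_i mu_i - P0 m0``.  All
integrals are then exact Gaussian algebra: the marginal likelihood of
``(B, gamma)`` is evaluated in closed form, ``gamma`` is optimised on it,
and effect posterior probabilities follow by Bayesian model reduction of
the ``B`` posterior with each effect pinned to zero.

Stacking levels is free: a fitted :class:`PEBModel` exposes its ``B``
posterior as a Gaussian belief, so a third-level "PEB of PEBs" that
compares groups is literally :func:`fit_peb` applied to second-level
models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .bmr import reduce, pin_prior
from .params import GaussianBelief

#: separator joining design-column and parameter names at higher levels
LEVEL_SEP = "|"


# ---------------------------------------------------------------------------
# design matrices

class DesignMatrix:
    """Between-subject design matrix with named columns.

    The first column must be a constant mean column of ones; covariate
    columns added through :meth:`add_covariate` are mean-centred (and by
    default scaled to unit SD); contrast/interaction helpers produce the
    +/-1 codings used for group and drug comparisons.
    """

    def __init__(self, frame: pd.DataFrame):
        if frame.shape[1] < 1:
            raise ValueError("design matrix needs at least the mean column")
        if frame.columns.duplicated().any():
            raise ValueError("design matrix column names must be unique")
        if not np.allclose(frame.iloc[:, 0].to_numpy(dtype=float), 1.0):
            raise ValueError("first design column must be all ones (mean)")
        self.frame = frame.astype(float)

    @classmethod
    def mean_only(cls, n: int, index=None) -> "DesignMatrix":
        return cls(pd.DataFrame({"mean": np.ones(n)}, index=index))

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def n(self) -> int:
        return len(self.frame)

    def add_contrast(self, name: str, codes) -> "DesignMatrix":
        codes = np.asarray(codes, dtype=float)
        if codes.shape != (self.n,):
            raise ValueError("contrast length mismatch")
        f = self.frame.copy()
        f[name] = codes
        return DesignMatrix(f)

    def add_covariate(self, name: str, values, scale: bool = True) -> "DesignMatrix":
        v = np.asarray(values, dtype=float)
        if v.shape != (self.n,):
            raise ValueError("covariate length mismatch")
        v = v - v.mean()
        if scale:
            sd = v.std(ddof=0)
            if sd > 0:
                v = v / sd
        f = self.frame.copy()
        f[name] = v
        return DesignMatrix(f)

    def add_interaction(self, a: str, b: str, name: str | None = None) -> "DesignMatrix":
        f = self.frame.copy()
        f[name or f"{a}x{b}"] = f[a] * f[b]
        return DesignMatrix(f)

    def drop(self, names) -> "DesignMatrix":
        return DesignMatrix(self.frame.drop(columns=list(names)))

    def check_rank(self) -> None:
        # all-zero columns are merely uninformative (their effects keep the
        # prior and Pp <= 0.5); only nonzero collinear columns are an error
        X = self.values
        nz = np.any(X != 0.0, axis=0)
        X = X[:, nz]
        cols = [c for c, keep in zip(self.columns, nz) if keep]
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # name the columns involved in the collinearity via the null space
            _, s, vt = np.linalg.svd(X)
            null = vt[rank:]
            bad = sorted({cols[j]
                          for row in null for j in np.where(np.abs(row) > 1e-8)[0]})
            raise ValueError(f"design matrix rank deficient; collinear columns {bad}")

    @classmethod
    def from_csv(cls, path) -> "DesignMatrix":
        return cls(pd.read_csv(path, index_col=0))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path)


# ---------------------------------------------------------------------------
# PEB model

@dataclass(frozen=True)
class PEBSettings:
    #: prior N(mean, var) over the between-subject log-precision gamma
    gamma_prior_mean: float = float(np.log(16.0))
    gamma_prior_var: float = 4.0
    gamma_bounds: tuple[float, float] = (-4.0, 16.0)
    #: second-level effect prior variance as a multiple of the first-level
    #: prior variance of the corresponding parameter
    beta_prior_scale: float = 1.0


@dataclass
class PEBModel:
    parameters: tuple[str, ...]
    columns: tuple[str, ...]
    beta_mean: np.ndarray            # (k, p)
    beta_cov: np.ndarray             # (kp, kp), row-major over (column, param)
    beta_prior_var: np.ndarray       # (kp,)
    gamma: float
    F: float
    Pp: np.ndarray                   # (k, p) effect posterior probabilities
    n_subjects: int
    settings: PEBSettings = field(default_factory=PEBSettings)

    @property
    def effect_names(self) -> tuple[str, ...]:
        return tuple(f"{c}{LEVEL_SEP}{p}" for c in self.columns
                     for p in self.parameters)

    def as_belief(self) -> GaussianBelief:
        """The vec(B) posterior as a Gaussian belief (for level stacking)."""
        return GaussianBelief(self.effect_names, self.beta_mean.reshape(-1),
                              self.beta_cov, F=self.F)

    def prior_belief(self) -> GaussianBelief:
        return GaussianBelief(self.effect_names,
                              np.zeros(len(self.effect_names)),
                              np.diag(self.beta_prior_var))

    def effect_table(self) -> pd.DataFrame:
        rows = []
        k, p = self.beta_mean.shape
        sd = np.sqrt(np.clip(np.diag(self.beta_cov), 0, None)).reshape(k, p)
        for c in range(k):
            for j in range(p):
                b = self.beta_mean[c, j]
                rows.append({
                    "effect": self.columns[c],
                    "parameter": self.parameters[j],
                    "beta": b,
                    "beta_sd": sd[c, j],
                    "Pp": self.Pp[c, j],
                    "sign": int(np.sign(b)),
                })
        return pd.DataFrame(rows)


def _likelihood_form(post: GaussianBelief, prior: GaussianBelief):
    """Information form (Lambda, h, ln c) of one subject's likelihood,
    reconstructed as posterior over prior."""
    P = np.linalg.inv(post.cov)
    P0 = np.linalg.inv(prior.cov)
    lam = (P - P0 + (P - P0).T) / 2.0
    w, V = np.linalg.eigh(lam)
    lam = (V * np.clip(w, 0.0, None)) @ V.T  # likelihood precision is PSD
    h = P @ post.mean - P0 @ prior.mean
    ln_c = 0.5 * (np.linalg.slogdet(P)[1] - np.linalg.slogdet(P0)[1]) - 0.5 * (
        post.mean @ P @ post.mean - prior.mean @ P0 @ prior.mean
    )
    return lam, h, float(ln_c)


def _log_evidence(forms, Xv, v0, b0_var, gamma: float):
    """Exact log marginal likelihood of the hierarchical Gaussian model at
    fixed between-subject log-precision (relative to the constant carried
    by the first-level fits)."""
    p = v0.size
    k = Xv.shape[1]
    g_var = np.exp(-gamma) * v0                  # diag of Gamma
    Pb = 1.0 / g_var
    Q = np.zeros((k * p, k * p))
    l = np.zeros(k * p)
    const = 0.0
    for (lam, h, ln_c), x in zip(forms, Xv):
        A = lam + np.diag(Pb)
        Ainv = np.linalg.inv(A)
        ln_ga = np.linalg.slogdet(np.eye(p) + g_var[:, None] * lam)[1]
        R = np.diag(Pb) - (Pb[:, None] * Ainv) * Pb[None, :]
        r = Pb * (Ainv @ h)
        const += ln_c - 0.5 * ln_ga + 0.5 * h @ Ainv @ h
        for c in range(k):
            l[c * p:(c + 1) * p] += x[c] * r
            for c2 in range(k):
                Q[c * p:(c + 1) * p, c2 * p:(c2 + 1) * p] += x[c] * x[c2] * R
    Ab = Q + np.diag(1.0 / b0_var)
    Ab = (Ab + Ab.T) / 2.0
    ln_ab = np.linalg.slogdet(Ab)[1]
    mu_b = np.linalg.solve(Ab, l)
    F = const - 0.5 * (np.sum(np.log(b0_var)) + ln_ab) + 0.5 * l @ mu_b
    return F, mu_b, Ab


def peb_log_evidence(posteriors, X: DesignMatrix, prior: GaussianBelief,
                     gamma: float,
                     settings: PEBSettings = PEBSettings()) -> float:
    """Log evidence of the between-subject model at fixed ``gamma``
    (exposed for oracle checks and sensitivity analyses)."""
    v0 = np.clip(np.diag(prior.cov), 1e-12, None)
    forms = [_likelihood_form(b, prior) for b in posteriors]
    b0_var = settings.beta_prior_scale * np.tile(v0, len(X.columns))
    return float(_log_evidence(forms, X.values, v0, b0_var, gamma)[0])


def fit_peb(posteriors, X: DesignMatrix, prior: GaussianBelief,
            settings: PEBSettings = PEBSettings()) -> PEBModel:
    """Empirical-Bayes fit of the between-subject GLM.

    ``posteriors`` are first-level Gaussian beliefs sharing parameter names
    (all obtained under ``prior``); rows of ``X`` align with them.  Returns
    the fitted :class:`PEBModel` with exact free energy, optimised
    between-subject log-precision and per-effect posterior probabilities.
    """
    if len(posteriors) != X.n:
        raise ValueError("number of posteriors does not match design rows")
    names = posteriors[0].names
    for b in posteriors:
        if b.names != names:
            raise ValueError("posteriors are over different parameter names")
    if prior.names != names:
        raise ValueError("prior parameter names do not match posteriors")
    X.check_rank()

    p = len(names)
    k = len(X.columns)
    Xv = X.values
    v0 = np.clip(np.diag(prior.cov), 1e-12, None)
    forms = [_likelihood_form(b, prior) for b in posteriors]
    b0_var = settings.beta_prior_scale * np.tile(v0, k)

    def objective(gamma: float):
        F, mu_b, Ab = _log_evidence(forms, Xv, v0, b0_var, gamma)
        F -= (0.5 * (gamma - settings.gamma_prior_mean) ** 2
              / settings.gamma_prior_var)
        return F, mu_b, Ab

    res = minimize_scalar(lambda g: -objective(g)[0],
                          bounds=settings.gamma_bounds,
                          method="bounded", options={"xatol": 1e-5})
    gamma = float(res.x)
    F, mu_b, Ab = objective(gamma)
    beta_cov = np.linalg.inv(Ab)
    beta_cov = (beta_cov + beta_cov.T) / 2.0

    model = PEBModel(
        parameters=names, columns=X.columns,
        beta_mean=mu_b.reshape(k, p), beta_cov=beta_cov,
        beta_prior_var=b0_var, gamma=gamma, F=float(F),
        Pp=np.zeros((k, p)), n_subjects=X.n, settings=settings,
    )
    model.Pp = _effect_posterior_probabilities(model)
    return model


def _effect_posterior_probabilities(model: PEBModel) -> np.ndarray:
    """Pp per (column, parameter): evidence comparison of the second-level
    model with vs without that effect, by pinning its beta to zero."""
    post = model.as_belief()
    prior = model.prior_belief()
    k, p = model.beta_mean.shape
    pp = np.zeros((k, p))
    for c in range(k):
        for j in range(p):
            name = model.effect_names[c * p + j]
            _, dF = reduce(post, prior, pin_prior(prior, [name]))
            # dF = F(without) - F(with); Pp = p(effect present)
            pp[c, j] = 1.0 / (1.0 + np.exp(np.clip(dF, -700, 700)))
    return pp


def peb_of_pebs(pebs, X2: DesignMatrix,
                settings: PEBSettings = PEBSettings()) -> PEBModel:
    """Third-level PEB treating second-level effect posteriors as data.

    All input models must share parameter/column structure; ``X2`` has one
    row per input model (e.g. one per diagnostic group), so its columns
    express group means, group differences and their interactions with the
    second-level effects (such as drug x group).
    """
    first = pebs[0]
    for m in pebs[1:]:
        if (m.parameters != first.parameters or m.columns != first.columns
                or m.beta_prior_var.shape != first.beta_prior_var.shape):
            raise ValueError("PEB models have mismatched structure")
    beliefs = [m.as_belief() for m in pebs]
    prior = first.prior_belief()
    return fit_peb(beliefs, X2, prior, settings)


def threshold_effects(peb: PEBModel, pp_threshold: float = 0.95) -> pd.DataFrame:
    """Table of effects whose posterior probability exceeds the threshold
    (columns: effect, parameter, beta, Pp, sign)."""
    t = peb.effect_table()
    return t[t["Pp"] > pp_threshold].reset_index(drop=True)
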