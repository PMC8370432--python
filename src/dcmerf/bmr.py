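"""Bayesian model reduction over Gaussian beliefs.

Given a Gaussian posterior obtained under a full Gaussian prior, the
posterior and evidence of any model that differs only in its prior follow
in closed form, without revisiting the data:

    P_r = P + P_r0 - P_0
    mu_r = P_r^-1 (P mu + P_r0 m_r0 - P_0 m_0)
    dF  = 1/2 [ ln|P| + ln|P_r0| - ln|P_0| - ln|P_r| ]
        + 1/2 [ mu_r' P_r mu_r - mu' P mu - m_r0' P_r0 m_r0 + m_0' P_0 m_0 ]

with P denoting precisions (subscript 0: priors, r: reduced model) and dF
the log evidence of the reduced model relative to the full one.  These
identities drive the greedy pruning of redundant parameters and the
posterior probabilities of second-level effects.
"""

from __future__ import annotations

import numpy as np

from .params import GaussianBelief

#: ridge added before inverting near-singular covariances
RIDGE = 1e-8
#: prior variance representing a parameter switched off (pinned to 0)
PINNED_VARIANCE = 1e-8


class ReductionError(ValueError):
    """Reduced-model precision not positive definite."""


def _safe_precision(belief: GaussianBelief) -> np.ndarray:
    """Exact precision where the covariance permits it; a small ridge is
    added only for numerically singular covariances."""
    try:
        P = belief.precision(ridge=0.0)
        if np.all(np.isfinite(P)):
            return P
    except np.linalg.LinAlgError:
        pass
    return belief.precision(ridge=RIDGE)


def _logdet_pd(m: np.ndarray, what: str):
    sign, ld = np.linalg.slogdet(m)
    if sign <= 0:
        raise ReductionError(f"{what} is not positive definite")
    return ld


def reduce(posterior: GaussianBelief, full_prior: GaussianBelief,
           reduced_prior: GaussianBelief) -> tuple[GaussianBelief, float]:
    """Closed-form reduced posterior and log-evidence change dF.

    All three beliefs must be over the same parameter names; the reduction
    never touches data.  Raises :class:`ReductionError` naming the
    offending parameters when the reduced precision loses positive
    definiteness.
    """
    if not (posterior.names == full_prior.names == reduced_prior.names):
        raise ValueError("beliefs are over different parameter names")
    P = _safe_precision(posterior)
    P0 = _safe_precision(full_prior)
    Pr0 = _safe_precision(reduced_prior)
    Pn = P + Pr0 - P0
    eigvals = np.linalg.eigvalsh((Pn + Pn.T) / 2)
    if eigvals[0] <= 0:
        vecs = np.linalg.eigh((Pn + Pn.T) / 2)[1][:, eigvals <= 0]
        guilty = [posterior.names[i]
                  for i in np.unique(np.argmax(np.abs(vecs), axis=0))]
        raise ReductionError(
            f"reduced precision not positive definite (parameters {guilty})"
        )
    mu, m0, mr0 = posterior.mean, full_prior.mean, reduced_prior.mean
    b = P @ mu + Pr0 @ mr0 - P0 @ m0
    mu_n = np.linalg.solve(Pn, b)
    dF = 0.5 * (
        _logdet_pd(P, "posterior precision")
        + _logdet_pd(Pr0, "reduced prior precision")
        - _logdet_pd(P0, "full prior precision")
        - _logdet_pd(Pn, "reduced posterior precision")
    ) + 0.5 * (
        mu_n @ Pn @ mu_n - mu @ P @ mu - mr0 @ Pr0 @ mr0 + m0 @ P0 @ m0
    )
    reduced = GaussianBelief(posterior.names, mu_n, np.linalg.inv(Pn))
    if posterior.F is not None:
        reduced.F = posterior.F + float(dF)
    return reduced, float(dF)


def pin_prior(prior: GaussianBelief, names,
              variance: float = PINNED_VARIANCE) -> GaussianBelief:
    """Reduced prior with the listed parameters pinned at 0 by a
    near-delta prior."""
    out = prior.copy()
    for n in names:
        i = out.index(n)
        out.mean[i] = 0.0
        out.cov[i, :] = 0.0
        out.cov[:, i] = 0.0
        out.cov[i, i] = variance
    return out


def greedy_prune(posterior: GaussianBelief, prior: GaussianBelief,
                 candidates, margin: float = 0.0):
    """Greedy search over reduced models that switch off redundant
    parameters.

    At each round every remaining candidate is scored by the dF of pinning
    it (on top of pins already accepted); the candidate with the largest dF
    is pinned if ``dF >= -margin`` (removal does not appreciably lower the
    evidence).  Ties break lexicographically by parameter name, so the
    search is deterministic.  Returns ``(reduced posterior, pruned names,
    total dF)``; an empty candidate list returns the inputs unchanged.
    """
    candidates = list(candidates)
    if not candidates:
        return posterior, [], 0.0
    pruned: list[str] = []
    total = 0.0
    current = posterior
    while True:
        remaining = [c for c in candidates if c not in pruned]
        if not remaining:
            break
        scores = []
        for c in remaining:
            rp = pin_prior(prior, pruned + [c])
            try:
                _, dF = reduce(posterior, prior, rp)
            except ReductionError:
                continue
            scores.append((dF - total, c))
        if not scores:
            break
        scores.sort(key=lambda t: (-t[0], t[1]))
        best_gain, best = scores[0]
        if best_gain < -margin:
            break
        pruned.append(best)
        total += best_gain
        current, _ = reduce(posterior, prior, pin_prior(prior, pruned))
    return current, pruned, float(total)


def compare_evidence(F_list, labels=None) -> dict:
    """Posterior model probabilities from free energies (softmax) and log
    Bayes factors relative to the best model."""
    F = np.asarray(F_list, dtype=float)
    if F.size < 2:
        raise ValueError("need at least two models to compare")
    if labels is None:
        labels = [f"model{i}" for i in range(F.size)]
    z = F - F.max()
    p = np.exp(z) / np.exp(z).sum()
    return {
        "labels": list(labels),
        "F": F.tolist(),
        "probability": p.tolist(),
        "log_bf_vs_best": (F - F.max()).tolist(),
    }
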