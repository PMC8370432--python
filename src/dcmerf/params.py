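"""Log-scaling parameters and Gaussian beliefs over them.

Every tunable quantity of the generative model is parameterized as a
dimensionless log-scaling deviation ``theta`` from its prior mean:
``actual = prior_mean * exp(theta)``, so ``theta = 0`` reproduces the
prior-mean model exactly and Gaussian priors/posteriors over ``theta``
respect positivity of the underlying physical quantity.

Parameter classes
-----------------
``intrinsic_gaba``
    The ten named GABAergic synapses of the microcircuit — six tonic
    self-connections (``tonic:<pop>``) and four phasic interneuron efferents
    (``phasic:<src>-><dst>``) — shared across sources.
``extrinsic``
    Per-edge gains of the forward and backward cortico-cortical connections.
``lateral``
    Per-edge gains of the interhemispheric lateral connections.
``input``
    Amplitude and latency of the exogenous Gaussian bump.
``observation``
    Log-gain of the ERF projection.
``rate_constant``
    Receptor rate constants (inverse synaptic time constants).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .microcircuit import MicrocircuitSpec
from .network import NetworkSpec

#: default prior variance per parameter class (log-scaling units)
DEFAULT_PRIOR_VARIANCES = {
    "intrinsic_gaba": 1.0 / 16.0,
    "extrinsic": 1.0 / 16.0,
    "lateral": 1.0 / 16.0,
    "input": 1.0 / 32.0,
    "observation": 1.0 / 16.0,
    "rate_constant": 1.0 / 32.0,
}

#: parameter classes free to vary under the default inversion configuration
DEFAULT_FREE_CLASSES = ("intrinsic_gaba", "extrinsic", "input")


def parameter_catalog(net: NetworkSpec) -> dict[str, str]:
    """Ordered mapping parameter name -> class for a network."""
    mc: MicrocircuitSpec = net.microcircuit
    cat: dict[str, str] = {}
    for name in mc.gaba_parameter_names():
        cat[name] = "intrinsic_gaba"
    for e in net.extrinsic:
        cat[e.name] = "lateral" if e.type == "lateral" else "extrinsic"
    cat["input:amp"] = "input"
    cat["input:latency"] = "input"
    cat["obs:gain"] = "observation"
    cat["kappa:ampa"] = "rate_constant"
    cat["kappa:nmda"] = "rate_constant"
    cat["kappa:gaba"] = "rate_constant"
    return cat


@dataclass
class ParameterSet:
    """A named vector of log-scaling deviations.

    ``values`` may be 1-D ``(p,)`` or batched ``(B, p)``; batching is used
    to evaluate many parameter points in one integrator run (e.g. finite
    difference Jacobians).
    """

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        self.names = tuple(self.names)
        self.values = np.atleast_1d(np.asarray(self.values, dtype=float))
        if self.values.shape[-1] != len(self.names):
            raise ValueError(
                f"values last axis {self.values.shape[-1]} != {len(self.names)} names"
            )
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate parameter names")

    @classmethod
    def zeros(cls, names) -> "ParameterSet":
        names = tuple(names)
        return cls(names, np.zeros(len(names)))

    @property
    def batch_shape(self) -> tuple:
        return self.values.shape[:-1]

    def get(self, name: str, default: float = 0.0) -> np.ndarray:
        """Value(s) of one parameter; ``default`` for parameters not in the
        set (frozen at their prior mean)."""
        try:
            i = self.names.index(name)
        except ValueError:
            return np.broadcast_to(default, self.batch_shape).astype(float)
        return self.values[..., i]

    def scale(self, name: str) -> np.ndarray:
        """Multiplier exp(theta) applied to the prior-mean quantity."""
        return np.exp(self.get(name))

    def updated(self, values: np.ndarray) -> "ParameterSet":
        return ParameterSet(self.names, values)

    def as_dict(self) -> dict[str, float]:
        if self.batch_shape:
            raise ValueError("as_dict requires an unbatched ParameterSet")
        return dict(zip(self.names, self.values))


@dataclass
class GaussianBelief:
    """Gaussian density over a named parameter vector.

    Used for priors and (approximate) posteriors alike.  ``hyper`` holds
    observation-noise log-precisions (one per source) where relevant, and
    ``F`` the variational free energy of the fit that produced the belief.
    """

    names: tuple[str, ...]
    mean: np.ndarray
    cov: np.ndarray
    hyper: np.ndarray | None = None
    F: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.names = tuple(self.names)
        self.mean = np.asarray(self.mean, dtype=float).reshape(-1)
        self.cov = np.asarray(self.cov, dtype=float)
        p = len(self.names)
        if self.mean.shape != (p,):
            raise ValueError("mean length does not match names")
        if self.cov.shape != (p, p):
            raise ValueError("cov shape does not match names")
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise ValueError("covariance not symmetric")
        if self.hyper is not None:
            self.hyper = np.asarray(self.hyper, dtype=float)

    @property
    def p(self) -> int:
        return len(self.names)

    def sd(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    def precision(self, ridge: float = 0.0) -> np.ndarray:
        c = self.cov
        if ridge:
            c = c + ridge * np.eye(self.p)
        return np.linalg.inv(c)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def marginal(self, name: str) -> tuple[float, float]:
        i = self.index(name)
        return float(self.mean[i]), float(np.sqrt(max(self.cov[i, i], 0.0)))

    def parameter_set(self) -> ParameterSet:
        return ParameterSet(self.names, self.mean.copy())

    def subset(self, names) -> "GaussianBelief":
        idx = [self.index(n) for n in names]
        return GaussianBelief(
            tuple(names), self.mean[idx], self.cov[np.ix_(idx, idx)],
            hyper=self.hyper, F=self.F,
        )

    def copy(self) -> "GaussianBelief":
        return GaussianBelief(
            self.names, self.mean.copy(), self.cov.copy(),
            hyper=None if self.hyper is None else self.hyper.copy(),
            F=self.F, meta=dict(self.meta),
        )

    # -- persistence ---------------------------------------------------------

    def to_hdf5(self, group: h5py.Group) -> None:
        group.create_dataset(
            "names", data=np.array(self.names, dtype=h5py.string_dtype())
        )
        group.create_dataset("mean", data=self.mean)
        group.create_dataset("cov", data=self.cov)
        if self.hyper is not None:
            group.create_dataset("hyper", data=self.hyper)
        if self.F is not None:
            group.attrs["F"] = float(self.F)
        for k, v in self.meta.items():
            if isinstance(v, (str, int, float, bool, np.integer, np.floating)):
                group.attrs[k] = v

    @classmethod
    def from_hdf5(cls, group: h5py.Group) -> "GaussianBelief":
        names = tuple(s.decode() if isinstance(s, bytes) else str(s)
                      for s in group["names"][()])
        hyper = group["hyper"][()] if "hyper" in group else None
        F = float(group.attrs["F"]) if "F" in group.attrs else None
        meta = {k: v for k, v in group.attrs.items() if k != "F"}
        return cls(names, group["mean"][()], group["cov"][()],
                   hyper=hyper, F=F, meta=meta)


def build_parameter_priors(
    net: NetworkSpec,
    free_classes=DEFAULT_FREE_CLASSES,
    variances: dict[str, float] | None = None,
) -> GaussianBelief:
    """Diagonal Gaussian prior (mean 0) over the free parameters of a network.

    ``free_classes`` selects parameter groups; ``variances`` overrides the
    per-class prior variances.  Unknown class names raise.
    """
    var = dict(DEFAULT_PRIOR_VARIANCES)
    if variances:
        for k in variances:
            if k not in var:
                raise ValueError(f"unknown parameter class {k!r}")
        var.update(variances)
    free_classes = tuple(free_classes)
    for k in free_classes:
        if k not in var:
            raise ValueError(f"unknown parameter class {k!r}")
    cat = parameter_catalog(net)
    names = [n for n, c in cat.items() if c in free_classes]
    v = np.array([var[cat[n]] for n in names])
    return GaussianBelief(tuple(names), np.zeros(len(names)), np.diag(v))
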