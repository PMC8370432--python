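"""Six-population conductance-based cortical microcircuit.

A single cortical source is modelled as a mean-field column of six neuronal
populations spanning the cortical laminae:

====  =========================================  ==========
key   population                                 layer
====  =========================================  ==========
ss    spiny stellate cells                       granular (L4)
sp    superficial pyramidal cells                supragranular
si    superficial inhibitory interneurons        supragranular
dp    deep cortico-cortical pyramidal cells      infragranular
di    deep inhibitory interneurons               infragranular
tp    thalamic-projection pyramidal cells        infragranular
====  =========================================  ==========

Each population carries a mean membrane potential ``V`` and three mean
channel conductances (AMPA, NMDA, GABA-A), expressed as dimensionless
multiples of the leak conductance.  Inhibition is organised into *tonic*
GABA-A self-connections (one per population, background gain control) and
*phasic* efferents from the two interneuron populations onto their laminar
targets (si->ss, si->sp, di->dp, di->tp).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

#: canonical population ordering used by every array in the package
POPULATIONS: tuple[str, ...] = ("ss", "sp", "si", "dp", "di", "tp")
EXCITATORY: tuple[str, ...] = ("ss", "sp", "dp", "tp")
INHIBITORY: tuple[str, ...] = ("si", "di")
#: phasic GABA-A synapses (source population, target population)
PHASIC_SYNAPSES: tuple[tuple[str, str], ...] = (
    ("si", "ss"),
    ("si", "sp"),
    ("di", "dp"),
    ("di", "tp"),
)

POP_INDEX = {p: i for i, p in enumerate(POPULATIONS)}
N_POP = len(POPULATIONS)
#: state variables per population: V, g_AMPA, g_NMDA, g_GABAA
N_STATES = 4


def _default_w_exc() -> np.ndarray:
    """Prior-mean excitatory intrinsic weights (target row, source column).

    A laminar feed chain: granular stellates drive the superficial layer,
    superficial pyramidals drive the deep layer, deep pyramidals drive the
    thalamic-projection cells, with interneurons sampling their home layer.
    Magnitudes are calibrated so that prior-mean dynamics produce a damped
    deflection peaking 100-250 ms after a granular-layer input at 60 ms.
    """
    w = np.zeros((N_POP, N_POP))
    idx = POP_INDEX

    def set_(dst, src, val):
        w[idx[dst], idx[src]] = val

    set_("sp", "ss", 1.2)    # granular -> superficial pyramidal
    set_("si", "ss", 1.2)    # granular -> superficial interneuron
    set_("dp", "sp", 2.4)    # superficial -> deep pyramidal
    set_("si", "sp", 1.2)    # superficial recurrent inhibition drive
    set_("tp", "dp", 1.8)    # deep pyramidal -> thalamic projection
    set_("di", "dp", 2.4)    # deep pyramidal -> deep interneuron
    set_("di", "tp", 1.2)    # thalamic projection collateral
    set_("ss", "tp", 0.15)   # intracolumnar return loop
    return w


def _default_w_gaba() -> np.ndarray:
    """Prior-mean GABA-A weights: tonic self-connections on every
    population plus the four phasic interneuron efferents."""
    w = np.zeros((N_POP, N_POP))
    for p in POPULATIONS:
        w[POP_INDEX[p], POP_INDEX[p]] = 3.0  # tonic self-inhibition
    for src, dst in PHASIC_SYNAPSES:
        w[POP_INDEX[dst], POP_INDEX[src]] = 4.5
    return w


@dataclass(frozen=True)
class MicrocircuitSpec:
    """Prior-mean specification of one cortical column.

    Weight matrices are indexed ``[target, source]`` and are non-negative;
    receptor identity (excitatory vs GABA-A) carries the sign of the
    postsynaptic current through the reversal potentials.
    """

    w_ampa: np.ndarray = field(default_factory=_default_w_exc)
    #: NMDA shares the AMPA wiring at reduced gain
    w_nmda: np.ndarray = field(default_factory=lambda: 0.5 * _default_w_exc())
    w_gaba: np.ndarray = field(default_factory=_default_w_gaba)
    #: receptor rate constants, ms^-1 (inverse synaptic time constants)
    kappa_ampa: float = 1.0 / 4.0
    kappa_nmda: float = 1.0 / 100.0
    kappa_gaba: float = 1.0 / 16.0
    #: reversal potentials, mV
    v_leak: float = -70.0
    v_exc: float = 60.0
    v_inh: float = -90.0
    #: membrane capacitance per population (ms, as multiples of g_leak)
    capacitance: np.ndarray = field(
        default_factory=lambda: np.full(N_POP, 16.0)
    )
    #: firing-rate sigmoid: threshold (mV) and slope (mV^-1); the threshold
    #: sits 15 mV above rest so evoked deflections of a few mV modulate
    #: population rates appreciably — with a far-threshold regime the
    #: inhibitory parameters would be invisible to the measured fields
    sigmoid_threshold: float = -55.0
    sigmoid_slope: float = 0.2

    def __post_init__(self):
        for name in ("w_ampa", "w_nmda", "w_gaba"):
            w = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, w)
            if w.shape != (N_POP, N_POP):
                raise ValueError(f"{name} must be {N_POP}x{N_POP}, got {w.shape}")
            if np.any(w < 0):
                raise ValueError(f"{name} has negative weights")
        object.__setattr__(
            self, "capacitance", np.asarray(self.capacitance, dtype=float)
        )
        self.validate()

    def validate(self) -> None:
        """Assert the laminar wiring rules.

        Excitatory (AMPA/NMDA) weights may originate only from excitatory
        populations; off-diagonal GABA-A weights only from interneurons.
        Every population must carry a tonic (self) GABA-A entry and the four
        named phasic synapses must be present.
        """
        inh = [POP_INDEX[p] for p in INHIBITORY]
        for name in ("w_ampa", "w_nmda"):
            w = getattr(self, name)
            if np.any(w[:, inh] != 0):
                raise ValueError(f"{name}: excitatory weights from interneurons")
        w = self.w_gaba
        exc = [POP_INDEX[p] for p in EXCITATORY]
        off = w.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off[:, exc] != 0):
            raise ValueError(
                "w_gaba: off-diagonal GABA-A weights must originate from si/di"
            )
        if np.any(np.diag(w) <= 0):
            missing = [p for p, v in zip(POPULATIONS, np.diag(w)) if v <= 0]
            raise ValueError(f"missing tonic GABA-A self-connection on {missing}")
        for src, dst in PHASIC_SYNAPSES:
            if w[POP_INDEX[dst], POP_INDEX[src]] <= 0:
                raise ValueError(f"missing phasic GABA-A synapse {src}->{dst}")

    # -- named synapse access ------------------------------------------------

    def tonic_parameter_names(self) -> list[str]:
        return [f"tonic:{p}" for p in POPULATIONS]

    def phasic_parameter_names(self) -> list[str]:
        return [f"phasic:{src}->{dst}" for src, dst in PHASIC_SYNAPSES]

    def gaba_parameter_names(self) -> list[str]:
        """All GABAergic synapses entered into the group analyses."""
        return self.tonic_parameter_names() + self.phasic_parameter_names()

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "w_ampa": self.w_ampa.tolist(),
            "w_nmda": self.w_nmda.tolist(),
            "w_gaba": self.w_gaba.tolist(),
            "kappa_ampa": self.kappa_ampa,
            "kappa_nmda": self.kappa_nmda,
            "kappa_gaba": self.kappa_gaba,
            "v_leak": self.v_leak,
            "v_exc": self.v_exc,
            "v_inh": self.v_inh,
            "capacitance": self.capacitance.tolist(),
            "sigmoid_threshold": self.sigmoid_threshold,
            "sigmoid_slope": self.sigmoid_slope,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MicrocircuitSpec":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "MicrocircuitSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def with_(self, **kwargs) -> "MicrocircuitSpec":
        return replace(self, **kwargs)


def sigmoid_rate(v, spec: MicrocircuitSpec):
    """Expected population firing rate in [0, 1] as a logistic function of
    mean depolarization.

    ``rate = 1 / (1 + exp(-slope * (V - threshold)))``; the derivative at
    threshold is slope/4.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("sigmoid_rate: non-finite membrane potential")
    x = spec.sigmoid_slope * (v - spec.sigmoid_threshold)
    # numerically stable logistic
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


def mg_block(v):
    """Voltage-dependent magnesium gate on the NMDA conductance,
    ``1 / (1 + 0.2 exp(-0.06 V))`` — monotone in V, ->1 with depolarization."""
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("mg_block: non-finite membrane potential")
    out = 1.0 / (1.0 + 0.2 * np.exp(-0.06 * v))
    return out if out.ndim else float(out)
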