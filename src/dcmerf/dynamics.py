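"""Equations of motion and numerical integration of the source network.

Per population the hidden states are the mean membrane potential ``V`` and
three mean channel conductances ``g_AMPA, g_NMDA, g_GABAA`` (dimensionless
multiples of the leak conductance):

    C dV/dt = g_L (V_L - V) + g_AMPA (V_E - V)
              + g_NMDA m(V) (V_E - V) + g_GABAA (V_I - V) + u(t)
    dg_k/dt = kappa_k (sigma_k - g_k)

where ``m(V)`` is the magnesium gate on the NMDA channel and ``sigma_k`` the
connectivity-weighted presynaptic drive for receptor ``k``.  Presynaptic
drive is the rectified deviation of the logistic firing rate from its
resting value, ``r(V) = max(sigmoid(V) - sigmoid(V_L), 0)``, which makes the
resting state (V = V_L, g = 0) an exact fixed point and keeps conductances
non-negative throughout integration.

Integration is a fixed-step explicit Runge-Kutta (RK4) scheme, dt = 1 ms by
default over the -100..400 ms epoch.  All routines accept batched parameter
sets, evaluating many parameter points in a single vectorized run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .microcircuit import (
    MicrocircuitSpec, POP_INDEX, POPULATIONS, N_POP, N_STATES,
    sigmoid_rate, mg_block,
)
from .network import NetworkSpec, TERMINATION, ORIGIN

#: receptor ordering of the conductance states
RECEPTORS = ("ampa", "nmda", "gaba")
#: fraction of extrinsic drive entering the NMDA channel (AMPA gets 1)
EXTRINSIC_NMDA_FRACTION = 0.25
#: |V - V_L| divergence bound, mV
DIVERGENCE_BOUND_MV = 150.0


class IntegrationError(RuntimeError):
    """Raised when a trajectory diverges; carries the offending batch mask."""

    def __init__(self, msg, diverged=None):
        super().__init__(msg)
        self.diverged = diverged


def default_time_grid(dt: float = 1.0, t_min: float = -100.0,
                      t_max: float = 400.0) -> np.ndarray:
    """Epoch time axis in ms (stimulus onset at t = 0)."""
    n = int(round((t_max - t_min) / dt)) + 1
    return t_min + dt * np.arange(n)


@dataclass
class CompiledSystem:
    """Network + parameters resolved into flat arrays for integration."""

    net: NetworkSpec
    weights: np.ndarray      # (B, 3, N, N) receptor-wise coupling, target x source
    kappa: np.ndarray        # (B, 3) rate constants ms^-1
    capacitance: np.ndarray  # (N,)
    input_mask: np.ndarray   # (N,) exogenous drive routing
    input_amp: np.ndarray    # (B,)
    input_peak: np.ndarray   # (B,)
    batched: bool
    linear: bool = False

    @property
    def n(self) -> int:
        return self.input_mask.size


def compile_system(net: NetworkSpec, params, linear: bool = False) -> CompiledSystem:
    """Resolve a ParameterSet against a network into coupling arrays.

    Parameter names not in ``params`` stay at their prior mean (theta = 0).
    Names in ``params`` that the network cannot resolve raise ``KeyError``.
    """
    from .params import ParameterSet, parameter_catalog

    if not isinstance(params, ParameterSet):
        params = ParameterSet.zeros(()) if params is None else params
    known = set(parameter_catalog(net))
    unknown = [n for n in params.names if n not in known]
    if unknown:
        raise KeyError(f"unresolvable parameter name(s): {unknown}")

    mc = net.microcircuit
    ns = net.n_sources
    n = ns * N_POP
    batch = params.batch_shape
    B = int(np.prod(batch)) if batch else 1
    vals = params.values.reshape(B, -1)
    params = params.updated(vals)

    # intrinsic weights with named GABAergic scalings, shared across sources
    w_gaba = np.broadcast_to(mc.w_gaba, (B, N_POP, N_POP)).copy()
    for p in POPULATIONS:
        i = POP_INDEX[p]
        w_gaba[:, i, i] = mc.w_gaba[i, i] * params.scale(f"tonic:{p}")
    from .microcircuit import PHASIC_SYNAPSES
    for src, dst in PHASIC_SYNAPSES:
        i, j = POP_INDEX[dst], POP_INDEX[src]
        w_gaba[:, i, j] = mc.w_gaba[i, j] * params.scale(f"phasic:{src}->{dst}")

    W = np.zeros((B, 3, n, n))
    for s in range(ns):
        sl = slice(s * N_POP, (s + 1) * N_POP)
        W[:, 0, sl, sl] = mc.w_ampa
        W[:, 1, sl, sl] = mc.w_nmda
        W[:, 2, sl, sl] = w_gaba

    # extrinsic edges enter the excitatory channels of their target laminae
    for e in net.extrinsic:
        g = e.gain * net.extrinsic_base * params.scale(e.name)  # (B,)
        src_pop = net.source_index(e.source) * N_POP + POP_INDEX[ORIGIN[e.type]]
        for pop, frac in TERMINATION[e.type].items():
            dst = net.source_index(e.target) * N_POP + POP_INDEX[pop]
            W[:, 0, dst, src_pop] += frac * g
            W[:, 1, dst, src_pop] += frac * g * EXTRINSIC_NMDA_FRACTION

    kappa = np.stack(
        [
            mc.kappa_ampa * params.scale("kappa:ampa"),
            mc.kappa_nmda * params.scale("kappa:nmda"),
            mc.kappa_gaba * params.scale("kappa:gaba"),
        ],
        axis=-1,
    )

    input_mask = np.zeros(n)
    for s in net.input_targets:
        input_mask[net.source_index(s) * N_POP + POP_INDEX["ss"]] = 1.0

    return CompiledSystem(
        net=net,
        weights=W,
        kappa=kappa,
        capacitance=np.tile(mc.capacitance, ns),
        input_mask=input_mask,
        input_amp=net.input_amplitude * params.scale("input:amp"),
        input_peak=net.input_peak_ms * params.scale("input:latency"),
        batched=bool(batch),
        linear=linear,
    )


def gaussian_input(sys: CompiledSystem, t: float) -> np.ndarray:
    """Exogenous Gaussian bump drive at time ``t`` (ms); shape (B,)."""
    w = sys.net.input_width_ms
    return sys.input_amp * np.exp(-0.5 * ((t - sys.input_peak) / w) ** 2)


def _rates(v: np.ndarray, mc: MicrocircuitSpec, linear: bool) -> np.ndarray:
    if linear:
        # identity-rate test mode: drive proportional to depolarization
        return 0.25 * mc.sigmoid_slope * (v - mc.v_leak)
    # clip defensively: intermediate Runge-Kutta stages of a diverging
    # trajectory may overflow before the step-level divergence check runs
    v = np.nan_to_num(v, nan=1e3, posinf=1e3, neginf=-1e3)
    v = np.clip(v, -1e3, 1e3)
    r0 = sigmoid_rate(np.array(mc.v_leak), mc)
    return np.clip(sigmoid_rate(v, mc) - r0, 0.0, None)


def derivatives(state: np.ndarray, t: float, sys: CompiledSystem,
                input_fn=None) -> np.ndarray:
    """Time derivative of the network state.

    ``state`` has shape (..., N, 4) with the last axis ordered
    (V, g_AMPA, g_NMDA, g_GABAA).  ``input_fn(sys, t)`` may replace the
    default Gaussian bump.
    """
    mc = sys.net.microcircuit
    v = state[..., 0]
    g = state[..., 1:]                                  # (..., N, 3)
    r = _rates(v, mc, sys.linear)                       # (..., N)
    drive = np.einsum("...knm,...m->...nk", sys.weights, r)  # (..., N, 3)

    u = (input_fn(sys, t) if input_fn is not None else gaussian_input(sys, t))
    u = np.asarray(u)[..., None] * sys.input_mask       # (..., N)

    if sys.linear:
        # linearized currents: driving forces frozen at rest
        syn = (
            g[..., 0] * (mc.v_exc - mc.v_leak)
            + g[..., 1] * mg_block(np.array(mc.v_leak)) * (mc.v_exc - mc.v_leak)
            + g[..., 2] * (mc.v_inh - mc.v_leak)
        )
    else:
        vc = np.clip(np.nan_to_num(v, nan=1e3, posinf=1e3, neginf=-1e3),
                     -1e3, 1e3)
        syn = (
            g[..., 0] * (mc.v_exc - v)
            + g[..., 1] * mg_block(vc) * (mc.v_exc - v)
            + g[..., 2] * (mc.v_inh - v)
        )
    dv = ((mc.v_leak - v) + syn + u) / sys.capacitance
    dg = sys.kappa[..., None, :] * (drive - g)
    return np.concatenate([dv[..., None], dg], axis=-1)


def resting_state(sys: CompiledSystem) -> np.ndarray:
    """The fixed point: V at leak reversal, all conductances zero."""
    shape = (sys.weights.shape[0], sys.n, N_STATES)
    state = np.zeros(shape)
    state[..., 0] = sys.net.microcircuit.v_leak
    return state


def integrate(
    net: NetworkSpec,
    params=None,
    input_fn=None,
    t_grid: np.ndarray | None = None,
    linear: bool = False,
    raise_on_divergence: bool = True,
):
    """Integrate the network over ``t_grid`` (ms), returning trajectories of
    shape ``(T, N, 4)`` — or ``(B, T, N, 4)`` for batched parameters — plus
    a per-batch success mask.

    Uses fixed-step RK4 at the grid spacing.  A trajectory whose potential
    leaves ``V_L +/- 150 mV`` is flagged as diverged (and raises unless
    ``raise_on_divergence=False``); diverged trajectories are frozen rather
    than propagated as NaN.
    """
    if t_grid is None:
        t_grid = default_time_grid()
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing with >= 2 points")

    sys = compile_system(net, params, linear=linear)
    state = resting_state(sys)
    B = state.shape[0]
    T = t_grid.size
    out = np.empty((B, T, sys.n, N_STATES))
    out[:, 0] = state
    ok = np.ones(B, dtype=bool)
    v_leak = net.microcircuit.v_leak

    for i in range(T - 1):
        t, dt = t_grid[i], t_grid[i + 1] - t_grid[i]
        k1 = derivatives(state, t, sys, input_fn)
        k2 = derivatives(state + 0.5 * dt * k1, t + 0.5 * dt, sys, input_fn)
        k3 = derivatives(state + 0.5 * dt * k2, t + 0.5 * dt, sys, input_fn)
        k4 = derivatives(state + dt * k3, t + dt, sys, input_fn)
        new = state + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        bad = ~np.all(
            np.isfinite(new[..., 0])
            & (np.abs(new[..., 0] - v_leak) <= DIVERGENCE_BOUND_MV),
            axis=-1,
        )
        if np.any(bad & ok):
            ok &= ~bad
            if raise_on_divergence:
                raise IntegrationError(
                    f"trajectory diverged at t={t_grid[i + 1]:.1f} ms "
                    f"(batch indices {np.where(~ok)[0].tolist()})",
                    diverged=~ok,
                )
        new = np.where(ok[:, None, None], new, state)  # freeze diverged items
        state = new
        out[:, i + 1] = state

    if not sys.batched:
        return out[0], bool(ok[0])
    return out, ok


def depolarization(trajectories: np.ndarray, net: NetworkSpec) -> np.ndarray:
    """Membrane-potential deviation from rest, shape (..., T, N)."""
    return trajectories[..., 0] - net.microcircuit.v_leak


def save_trajectories(path, t_grid: np.ndarray, trajectories: np.ndarray,
                      net: NetworkSpec) -> None:
    """Write state trajectories to HDF5 (datasets: time, state, labels)."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("time", data=np.asarray(t_grid))
        fh.create_dataset("state", data=np.asarray(trajectories))
        fh.create_dataset(
            "labels",
            data=np.array(net.population_labels(), dtype=h5py.string_dtype()),
        )
        fh["state"].attrs["state_vars"] = "V,g_ampa,g_nmda,g_gaba"
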