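"""From neuronal trajectories to conditioned event-related fields.

The measured ERF of a source is a gain-scaled weighted sum of population
depolarizations, dominated by the pyramidal populations whose apical
dendrites generate the open-field currents MEG sees.  Simulated and
"recorded" ERFs pass through the same conditioning: a zero-phase low-pass
at 48 Hz (DC retained) and a Tukey window that is exactly 1 between 50 and
350 ms post-stimulus, tapering to zero at the epoch edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .dynamics import depolarization
from .erf import ERFDataset
from .microcircuit import POPULATIONS, N_POP
from .network import NetworkSpec

#: default contribution of each population to the measured field
DEFAULT_CONTRIBUTIONS = {"ss": 0.2, "sp": 1.0, "si": 0.0, "dp": 0.6, "di": 0.0, "tp": 0.3}


@dataclass(frozen=True)
class ObservationSpec:
    """Fixed population contribution weights J plus noise hyperpriors.

    The overall scale is absorbed by the free ``obs:gain`` log-parameter, so
    J is a shape, not a calibration.  Observation noise is additive Gaussian
    per source with log-precision hyperparameters (prior N(mean, var)).
    """

    contributions: dict = field(default_factory=lambda: dict(DEFAULT_CONTRIBUTIONS))
    noise_logprec_mean: float = 4.0
    noise_logprec_var: float = 1.0

    def weights(self) -> np.ndarray:
        w = np.array([self.contributions.get(p, 0.0) for p in POPULATIONS])
        if not np.any(w[[POPULATIONS.index("sp"), POPULATIONS.index("dp"),
                         POPULATIONS.index("tp")]]):
            raise ValueError("at least one pyramidal population must contribute")
        return w


def project_erf(trajectories: np.ndarray, obs: ObservationSpec,
                params, net: NetworkSpec) -> np.ndarray:
    """Project trajectories ``(..., T, N, 4)`` to source ERFs ``(..., S, T)``.

    Linear in the trajectories for fixed parameters; zero depolarization
    maps to a zero ERF.
    """
    dep = depolarization(trajectories, net)          # (..., T, N)
    ns = net.n_sources
    if dep.shape[-1] != ns * N_POP:
        raise ValueError(
            f"trajectory population axis {dep.shape[-1]} != {ns * N_POP}"
        )
    dep = dep.reshape(dep.shape[:-1] + (ns, N_POP))  # (..., T, S, P)
    j = obs.weights()
    gain = np.exp(params.get("obs:gain")) if params is not None else 1.0
    erf = np.einsum("...tsp,p->...st", dep, j)
    return np.asarray(gain)[..., None, None] * erf


def tukey_window(time_ms: np.ndarray, flat=(50.0, 350.0)) -> np.ndarray:
    """Cosine-tapered window equal to exactly 1.0 on ``flat`` (ms), rolling
    off to zero at the epoch edges."""
    t = np.asarray(time_ms, dtype=float)
    lo, hi = float(flat[0]), float(flat[1])
    if lo < t[0] or hi > t[-1] or lo >= hi:
        raise ValueError(
            f"window flat region [{lo}, {hi}] ms not inside epoch "
            f"[{t[0]}, {t[-1]}] ms"
        )
    w = np.ones_like(t)
    rise = t < lo
    if t[0] < lo:
        w[rise] = 0.5 * (1.0 - np.cos(np.pi * (t[rise] - t[0]) / (lo - t[0])))
    fall = t > hi
    if t[-1] > hi:
        w[fall] = 0.5 * (1.0 + np.cos(np.pi * (t[fall] - hi) / (t[-1] - hi)))
    return w


def lowpass(x: np.ndarray, fs_hz: float, cutoff_hz: float = 48.0,
            order: int = 6) -> np.ndarray:
    """Zero-phase Butterworth low-pass along the last axis (DC retained)."""
    if fs_hz < 2.0 * cutoff_hz:
        raise ValueError("sampling rate below twice the low-pass cutoff")
    b, a = _signal.butter(order, cutoff_hz / (fs_hz / 2.0), btype="low")
    return _signal.filtfilt(b, a, x, axis=-1)


def condition_erf(ds: ERFDataset, lowpass_hz: float = 48.0,
                  window=(50.0, 350.0)) -> ERFDataset:
    """Band-limit (zero-phase low-pass at ``lowpass_hz``) and window an ERF.

    Already-conditioned datasets pass through unchanged, so repeated
    application never double-tapers the epoch edges.
    """
    if ds.conditioned:
        return ds.copy()
    w = tukey_window(ds.time_ms, flat=window)
    filtered = lowpass(ds.erf, ds.fs_hz, cutoff_hz=lowpass_hz)
    return ds.with_erf(filtered * w, conditioned=True)


def condition_array(erf: np.ndarray, time_ms: np.ndarray,
                    lowpass_hz: float = 48.0, window=(50.0, 350.0)) -> np.ndarray:
    """Array-level conditioning used on model predictions, identical to the
    treatment of the data."""
    fs = 1000.0 / float(time_ms[1] - time_ms[0])
    return lowpass(erf, fs, cutoff_hz=lowpass_hz) * tukey_window(time_ms, window)


def pearson(x: np.ndarray, y: np.ndarray) -> float | None:
    """Pearson r for two 1-D signals; ``None`` when either has zero
    variance (rather than propagating NaN)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xd = x - x.mean()
    yd = y - y.mean()
    sx = np.sqrt(xd @ xd)
    sy = np.sqrt(yd @ yd)
    if sx == 0.0 or sy == 0.0:
        return None
    return float(np.clip((xd @ yd) / (sx * sy), -1.0, 1.0))


def fit_statistics(observed: ERFDataset, predicted: ERFDataset) -> dict:
    """Per-source and pooled Pearson correlation between observed and
    predicted ERFs; the pooled summary reports median and interquartile
    range over defined correlations."""
    if observed.erf.shape != predicted.erf.shape or not np.allclose(
        observed.time_ms, predicted.time_ms
    ):
        raise ValueError("observed and predicted ERFs are not aligned")
    per_source = {
        src: pearson(observed.erf[i], predicted.erf[i])
        for i, src in enumerate(observed.sources)
    }
    return {"per_source": per_source, **summarize_correlations(per_source.values())}


def summarize_correlations(rs) -> dict:
    """Median and IQR of a collection of correlations, ignoring missing."""
    vals = np.array([r for r in rs if r is not None], dtype=float)
    if vals.size == 0:
        return {"median_r": None, "iqr_r": None, "n": 0}
    q25, med, q75 = np.percentile(vals, [25, 50, 75])
    return {"median_r": float(med), "iqr_r": float(q75 - q25), "n": int(vals.size)}
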