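"""Synthetic cohorts with the statistical structure the analysis assumes.

Emulates a placebo-controlled crossover pharmaco-MEG study of two
frontotemporal-degeneration groups and matched controls: 20 controls, 15
PSP and 17 bvFTD patients, each measured in two drug sessions (placebo,
tiagabine) and two conditions (standard, deviant), with an MRS GABA
covariate that is lower in patients than controls.  Group, drug,
interaction and GABA-slope effects are injected at named synaptic
parameters as a between-subject general linear model over the true
log-scaling parameters; ERFs are then simulated through the full
generative model with additive Gaussian observation noise.

True parameters are stored in a :class:`TruthStore` separate from the
datasets, so inversion and group analyses can only ever see the data and
covariates.

Two fidelities are supported: ``"erf"`` generates full ERF datasets (for
inversion studies), ``"posterior"`` generates first-level Gaussian
posterior beliefs directly around the true parameters — the standard
device for studying the hierarchical (PEB) machinery at realistic cohort
sizes without paying for thousands of model inversions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import h5py
import numpy as np
import pandas as pd
import yaml

from .erf import ERFDataset, GROUPS, SESSIONS, CONDITIONS
from .inversion import ERFModel
from .network import NetworkSpec
from .observation import ObservationSpec
from .params import GaussianBelief, ParameterSet, build_parameter_priors

#: default group sizes of the emulated study
DEFAULT_GROUP_SIZES = {"control": 20, "PSP": 15, "bvFTD": 17}
#: default GABA means (arbitrary units): patients below controls
DEFAULT_GABA_MEANS = {"control": 2.0, "PSP": 1.55, "bvFTD": 1.45}
DEFAULT_GABA_SD = 0.25
#: baseline trial counts entering the averaging-noise model
DEFAULT_TRIALS = {"deviant": 160, "standard": 120}

EFFECT_KINDS = ("group-contrast", "group-diff", "drug", "interaction", "gaba-slope")


@dataclass(frozen=True)
class Effect:
    """One injected effect: ``size`` is expressed in units of the prior SD
    of ``parameter``.

    kinds
    -----
    ``group-contrast``  controls - patients (+1 controls, -1 patients)
    ``group-diff``      PSP - bvFTD (+1 PSP, -1 bvFTD, 0 controls)
    ``drug``            tiagabine - placebo (+1 TGB, -1 PLA)
    ``interaction``     drug x (PSP - bvFTD)
    ``gaba-slope``      per-SD slope on the standardized GABA covariate
    """

    parameter: str
    kind: str
    size: float

    def __post_init__(self):
        if self.kind not in EFFECT_KINDS:
            raise ValueError(f"unknown effect kind {self.kind!r}")


def default_effects() -> tuple[Effect, ...]:
    """The default injected-effect map mirrors the loci the group analyses
    are designed to detect: a patient deficit of the left frontal-to-
    temporal backward gain, a drug effect on deep-interneuron tonic
    inhibition, opposing drug effects in the two patient groups at the
    stellate phasic synapse, and GABA-concentration slopes on the deep
    phasic synapses."""
    return (
        Effect("ext:B:lIFG->lSTG", "group-contrast", 0.5),
        Effect("tonic:di", "drug", 0.5),
        Effect("phasic:si->ss", "interaction", 0.5),
        # GABA-concentration slopes centre on the deep-layer synapses:
        # positive on deep-interneuron background inhibition and both deep
        # phasic efferents, negative on deep-pyramidal background inhibition
        Effect("tonic:di", "gaba-slope", 0.5),
        Effect("phasic:di->dp", "gaba-slope", 0.5),
        Effect("phasic:di->tp", "gaba-slope", 0.5),
        Effect("tonic:dp", "gaba-slope", -0.5),
    )


@dataclass(frozen=True)
class CohortSpec:
    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    sessions: tuple[str, ...] = SESSIONS
    conditions: tuple[str, ...] = CONDITIONS
    effects: tuple[Effect, ...] = field(default_factory=default_effects)
    gaba_means: dict = field(default_factory=lambda: dict(DEFAULT_GABA_MEANS))
    gaba_sd: float = DEFAULT_GABA_SD
    #: between-subject SD of the true parameters (log-scaling units)
    subject_sd: float = 0.1
    #: additional per-session parameter jitter (crossover session noise)
    session_sd: float = 0.02
    #: condition offset added to deviant trials on the forward gains
    deviant_offset: float = 0.1
    #: amplitude SNR of the trial-averaged ERF at the baseline trial count
    snr: float = 8.0
    #: SNR -> infinity switch (noiseless data)
    noiseless: bool = False
    trials: dict = field(default_factory=lambda: dict(DEFAULT_TRIALS))
    #: posterior-fidelity only: SD of the simulated first-level posterior
    posterior_sd: float = 0.05
    fidelity: str = "erf"  # "erf" | "posterior"
    seed: int = 0

    def __post_init__(self):
        for g, n in self.group_sizes.items():
            if g not in GROUPS or n < 1:
                raise ValueError(f"bad group size entry {g}={n}")
        if not self.noiseless and self.snr <= 0:
            raise ValueError("SNR must be positive")
        if self.fidelity not in ("erf", "posterior"):
            raise ValueError("fidelity must be 'erf' or 'posterior'")
        object.__setattr__(self, "effects", tuple(
            e if isinstance(e, Effect) else Effect(**e) for e in self.effects
        ))
        object.__setattr__(self, "sessions", tuple(self.sessions))
        object.__setattr__(self, "conditions", tuple(self.conditions))

    def to_yaml(self, path) -> None:
        def plain(x):
            if isinstance(x, dict):
                return {k: plain(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [plain(v) for v in x]
            return x

        with open(path, "w") as fh:
            yaml.safe_dump(plain(asdict(self)), fh)

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class TruthStore:
    """Ground-truth parameters, kept apart from the analysable data."""

    names: tuple[str, ...]
    #: theta[(subject, session, condition)] -> (p,) true parameters
    theta: dict
    noiseless: dict  # key -> noiseless ERF array (erf fidelity only)

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("names",
                              data=np.array(self.names, dtype=h5py.string_dtype()))
            g = fh.create_group("theta")
            for key, v in self.theta.items():
                g.create_dataset("/".join(key), data=v)
            gn = fh.create_group("noiseless")
            for key, v in self.noiseless.items():
                gn.create_dataset("/".join(key), data=v)


@dataclass
class SyntheticCohort:
    spec: CohortSpec
    subjects: pd.DataFrame            # subject, group, gaba, trial counts
    datasets: list                    # ERFDataset (erf fidelity)
    beliefs: dict                     # (subject, session) -> GaussianBelief
    truth: TruthStore
    net: NetworkSpec
    prior: GaussianBelief

    def dataset(self, subject, session, condition) -> ERFDataset:
        for ds in self.datasets:
            if (ds.subject, ds.session, ds.condition) == (subject, session, condition):
                return ds
        raise KeyError((subject, session, condition))


def _effect_code(effect: Effect, group: str, session: str, gaba_z: float) -> float:
    drug = +1.0 if session == "tiagabine" else -1.0
    if effect.kind == "group-contrast":
        return +1.0 if group == "control" else -1.0
    if effect.kind == "group-diff":
        return {"PSP": +1.0, "bvFTD": -1.0}.get(group, 0.0)
    if effect.kind == "drug":
        return drug
    if effect.kind == "interaction":
        return drug * {"PSP": +1.0, "bvFTD": -1.0}.get(group, 0.0)
    if effect.kind == "gaba-slope":
        return gaba_z
    raise AssertionError(effect.kind)


def generate_cohort(spec: CohortSpec, net: NetworkSpec | None = None,
                    obs: ObservationSpec | None = None,
                    prior: GaussianBelief | None = None) -> SyntheticCohort:
    """Draw a full synthetic cohort from a specification.

    Deterministic in ``spec`` (including ``spec.seed``): regenerating with
    the same spec is bit-identical.
    """
    net = net or NetworkSpec()
    obs = obs or ObservationSpec()
    prior = prior or build_parameter_priors(net)
    names = prior.names
    sd = prior.sd()
    for e in spec.effects:
        if e.parameter not in names:
            raise ValueError(f"effect references unknown parameter {e.parameter!r}")

    rng = np.random.default_rng(spec.seed)
    rows = []
    for group in GROUPS:
        n = spec.group_sizes.get(group, 0)
        for i in range(n):
            sid = f"{group}{i + 1:02d}"
            gaba = rng.normal(spec.gaba_means[group], spec.gaba_sd)
            trials = {c: int(rng.normal(spec.trials.get(c, 150), 20))
                      for c in spec.conditions}
            rows.append({"subject": sid, "group": group, "gaba": gaba, **{
                f"n_trials_{c}": max(t, 30) for c, t in trials.items()}})
    subjects = pd.DataFrame(rows)
    g_sd = subjects["gaba"].std(ddof=0)
    gaba_z = ((subjects["gaba"] - subjects["gaba"].mean())
              / (g_sd if g_sd > 0 else 1.0)).to_numpy()

    model = ERFModel(net, obs)
    theta_store: dict = {}
    noiseless_store: dict = {}
    datasets: list[ERFDataset] = []
    beliefs: dict = {}
    fwd_idx = [i for i, nm in enumerate(names) if nm.startswith("ext:F:")]

    for si, row in subjects.iterrows():
        base = rng.normal(0.0, spec.subject_sd, prior.p)
        for session in spec.sessions:
            th_sess = base + rng.normal(0.0, spec.session_sd, prior.p)
            for e in spec.effects:
                j = list(names).index(e.parameter)
                code = _effect_code(e, row["group"], session, gaba_z[si])
                # size is the per-unit-code deviation in prior-SD units
                th_sess[j] += e.size * sd[j] * code
            if spec.fidelity == "posterior":
                key = (row["subject"], session)
                th = th_sess.copy()
                theta_store[(row["subject"], session, "deviant")] = th
                cov = np.diag(np.full(prior.p, spec.posterior_sd**2))
                mean = th + rng.normal(0.0, spec.posterior_sd, prior.p)
                beliefs[key] = GaussianBelief(names, mean, cov)
                continue
            for condition in spec.conditions:
                th = th_sess.copy()
                if condition == "deviant":
                    th[fwd_idx] += spec.deviant_offset
                key = (row["subject"], session, condition)
                theta_store[key] = th
                clean, ok = model.predict(ParameterSet(names, th))
                if not ok:
                    raise RuntimeError(f"simulation diverged for {key}")
                noiseless_store[key] = clean
                n_tr = int(row[f"n_trials_{condition}"])
                if spec.noiseless:
                    noisy = clean
                else:
                    sigma = _noise_sd(clean, spec, n_tr, condition)
                    noisy = clean + rng.normal(0.0, sigma, clean.shape)
                datasets.append(ERFDataset(
                    subject=row["subject"], group=row["group"], session=session,
                    condition=condition, time_ms=model.time_ms, erf=noisy,
                    sources=net.sources, gaba=float(row["gaba"]),
                    n_trials=n_tr, conditioned=False,
                ))

    truth = TruthStore(names=names, theta=theta_store, noiseless=noiseless_store)
    return SyntheticCohort(spec=spec, subjects=subjects, datasets=datasets,
                           beliefs=beliefs, truth=truth, net=net, prior=prior)


def _noise_sd(clean: np.ndarray, spec: CohortSpec, n_trials: int,
              condition: str) -> float:
    """Additive noise SD: the nominal SNR applies at the baseline trial
    count; noise variance of a trial average scales as 1/n_trials."""
    rms = np.sqrt(np.mean(clean**2))
    base = spec.trials.get(condition, 150)
    return (rms / spec.snr) * np.sqrt(base / max(n_trials, 1))


def snr_report(cohort: SyntheticCohort) -> pd.DataFrame:
    """Realized amplitude SNR per dataset against the stored noiseless
    reference."""
    rows = []
    for ds in cohort.datasets:
        key = (ds.subject, ds.session, ds.condition)
        clean = cohort.truth.noiseless[key]
        noise = ds.erf - clean
        rms_n = np.sqrt(np.mean(noise**2))
        rows.append({
            "subject": ds.subject, "session": ds.session,
            "condition": ds.condition, "n_trials": ds.n_trials,
            "snr": np.inf if rms_n == 0 else
                   float(np.sqrt(np.mean(clean**2)) / rms_n),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# roving oddball sequence

def generate_roving_sequence(n_tones: int, seed: int = 0) -> pd.DataFrame:
    """Roving-oddball tone sequence.

    Tones on a 50 Hz grid in [400, 800] Hz; after 3-10 repetitions the
    frequency steps up or down by 50 Hz.  The first tone of each train
    (after the very first train) is labelled ``deviant`` and the sixth
    ``standard``; all others ``other``.  Returns a frame with columns
    (frequency_hz, train, position, label).
    """
    if n_tones < 1:
        raise ValueError("n_tones must be >= 1")
    rng = np.random.default_rng(seed)
    freqs = np.arange(400, 801, 50)
    f = int(rng.choice(freqs))
    rows = []
    train = 0
    emitted = 0
    while emitted < n_tones:
        length = int(rng.integers(3, 11))
        for pos in range(1, length + 1):
            if emitted >= n_tones:
                break
            label = "other"
            if pos == 1 and train > 0:
                label = "deviant"
            elif pos == 6:
                label = "standard"
            rows.append({"frequency_hz": f, "train": train,
                         "position": pos, "label": label})
            emitted += 1
        train += 1
        if f <= 400:
            f += 50
        elif f >= 800:
            f -= 50
        else:
            f += int(rng.choice([-50, 50]))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# persistence

def save_cohort(cohort: SyntheticCohort, data_path, spec_path=None,
                truth_path=None, provenance_path=None) -> None:
    """Cohort on disk: HDF5 data, YAML spec, separate HDF5 truth store and
    JSON provenance."""
    from .erf import save_erfs

    if cohort.spec.fidelity == "erf":
        save_erfs(data_path, cohort.datasets)
    else:
        with h5py.File(data_path, "w") as fh:
            for (subj, sess), belief in cohort.beliefs.items():
                belief.to_hdf5(fh.create_group(f"{subj}/{sess}"))
    if spec_path:
        cohort.spec.to_yaml(spec_path)
    if truth_path:
        cohort.truth.to_hdf5(truth_path)
    if provenance_path:
        with open(provenance_path, "w") as fh:
            json.dump({"seed": cohort.spec.seed,
                       "fidelity": cohort.spec.fidelity,
                       "n_subjects": len(cohort.subjects)}, fh, indent=2)
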