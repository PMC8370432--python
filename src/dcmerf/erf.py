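"""Event-related field containers and on-disk formats.

An :class:`ERFDataset` holds one subject x session x condition source-level
ERF: a ``(n_sources, T)`` array over a uniform time axis in ms, with the
cohort metadata (group, drug session, MRS GABA covariate, trial count) the
group analyses consume.  Collections are stored in a single HDF5 file with
one group per subject/session/condition, or exported to flat CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

GROUPS = ("control", "PSP", "bvFTD")
SESSIONS = ("placebo", "tiagabine")
CONDITIONS = ("standard", "deviant")


@dataclass
class ERFDataset:
    subject: str
    group: str
    session: str
    condition: str
    time_ms: np.ndarray
    erf: np.ndarray                      # (n_sources, T), arbitrary field units
    sources: tuple[str, ...]
    gaba: float | None = None            # MRS GABA covariate, arbitrary units
    n_trials: int | None = None
    conditioned: bool = False            # band-limit + window already applied
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.erf = np.asarray(self.erf, dtype=float)
        self.sources = tuple(self.sources)
        if self.erf.shape != (len(self.sources), self.time_ms.size):
            raise ValueError(
                f"erf shape {self.erf.shape} inconsistent with "
                f"{len(self.sources)} sources x {self.time_ms.size} samples"
            )
        dt = np.diff(self.time_ms)
        if self.time_ms.size > 1 and not np.allclose(dt, dt[0], rtol=1e-9):
            raise ValueError("time axis must be uniform")
        if not np.all(np.isfinite(self.erf)):
            raise ValueError("non-finite ERF values")

    @property
    def fs_hz(self) -> float:
        """Sampling rate in Hz."""
        return 1000.0 / float(self.time_ms[1] - self.time_ms[0])

    def key(self) -> str:
        return f"{self.subject}/{self.session}/{self.condition}"

    def with_erf(self, erf: np.ndarray, conditioned: bool | None = None) -> "ERFDataset":
        out = replace(self, erf=np.asarray(erf, dtype=float))
        if conditioned is not None:
            out.conditioned = conditioned
        return out

    def copy(self) -> "ERFDataset":
        return replace(self, erf=self.erf.copy(), time_ms=self.time_ms.copy())

    # -- persistence ---------------------------------------------------------

    def to_hdf5(self, grp: h5py.Group) -> None:
        grp.create_dataset("time_ms", data=self.time_ms)
        grp.create_dataset("erf", data=self.erf)
        grp.create_dataset(
            "sources", data=np.array(self.sources, dtype=h5py.string_dtype())
        )
        grp.attrs["subject"] = self.subject
        grp.attrs["group"] = self.group
        grp.attrs["session"] = self.session
        grp.attrs["condition"] = self.condition
        grp.attrs["conditioned"] = self.conditioned
        if self.gaba is not None:
            grp.attrs["gaba"] = float(self.gaba)
        if self.n_trials is not None:
            grp.attrs["n_trials"] = int(self.n_trials)

    @classmethod
    def from_hdf5(cls, grp: h5py.Group) -> "ERFDataset":
        sources = tuple(
            s.decode() if isinstance(s, bytes) else str(s) for s in grp["sources"][()]
        )
        a = grp.attrs
        return cls(
            subject=str(a["subject"]),
            group=str(a["group"]),
            session=str(a["session"]),
            condition=str(a["condition"]),
            time_ms=grp["time_ms"][()],
            erf=grp["erf"][()],
            sources=sources,
            gaba=float(a["gaba"]) if "gaba" in a else None,
            n_trials=int(a["n_trials"]) if "n_trials" in a else None,
            conditioned=bool(a.get("conditioned", False)),
        )


def save_erfs(path, datasets: list[ERFDataset]) -> None:
    with h5py.File(path, "w") as fh:
        for ds in datasets:
            ds.to_hdf5(fh.create_group(ds.key()))


def load_erfs(path) -> list[ERFDataset]:
    out = []
    with h5py.File(path, "r") as fh:
        for subj in sorted(fh):
            for sess in sorted(fh[subj]):
                for cond in sorted(fh[subj][sess]):
                    out.append(ERFDataset.from_hdf5(fh[subj][sess][cond]))
    return out


def erfs_to_frame(datasets: list[ERFDataset]) -> pd.DataFrame:
    """Flat long-format export (subject, session, condition, source,
    time_ms, value) for interoperability."""
    rows = []
    for ds in datasets:
        for i, src in enumerate(ds.sources):
            rows.append(
                pd.DataFrame(
                    {
                        "subject": ds.subject,
                        "group": ds.group,
                        "session": ds.session,
                        "condition": ds.condition,
                        "source": src,
                        "time_ms": ds.time_ms,
                        "value": ds.erf[i],
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)
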