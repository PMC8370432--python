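"""Six-source auditory hierarchy: bilateral A1, STG and IFG.

The network is the fully connected mismatch-negativity hierarchy: forward
connections ascend A1 -> STG -> IFG in each hemisphere, backward connections
descend the same edges in reverse, and lateral connections couple homologous
regions across hemispheres.  Exogenous (auditory and expectancy) drive enters
the granular stellate population of bilateral A1 and bilateral IFG as a
Gaussian bump peaking 60 ms after stimulus onset with 8 ms half-width.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .microcircuit import MicrocircuitSpec, POP_INDEX, N_POP

SOURCES: tuple[str, ...] = ("lA1", "rA1", "lSTG", "rSTG", "lIFG", "rIFG")
CONDITIONS: tuple[str, ...] = ("standard", "deviant")

#: laminar termination of extrinsic connections: {type: {target pop: weight}}
TERMINATION = {
    "forward": {"ss": 1.0, "si": 0.5},
    "backward": {"sp": 0.5, "si": 0.5, "dp": 0.5, "di": 0.25},
    "lateral": {"ss": 0.5, "dp": 0.5},
}
#: population of origin for each extrinsic connection type
ORIGIN = {"forward": "sp", "backward": "dp", "lateral": "dp"}
_TYPE_CODE = {"forward": "F", "backward": "B", "lateral": "L"}


@dataclass(frozen=True)
class ExtrinsicConnection:
    source: str
    target: str
    type: str  # forward | backward | lateral
    gain: float = 1.0  # prior-mean gain multiplier

    @property
    def name(self) -> str:
        return f"ext:{_TYPE_CODE[self.type]}:{self.source}->{self.target}"


def _default_edges() -> tuple[ExtrinsicConnection, ...]:
    fwd = [("lA1", "lSTG"), ("lSTG", "lIFG"), ("rA1", "rSTG"), ("rSTG", "rIFG")]
    lat = [("lA1", "rA1"), ("lSTG", "rSTG"), ("lIFG", "rIFG")]
    edges = [ExtrinsicConnection(a, b, "forward") for a, b in fwd]
    edges += [ExtrinsicConnection(b, a, "backward") for a, b in fwd]
    for a, b in lat:
        edges.append(ExtrinsicConnection(a, b, "lateral"))
        edges.append(ExtrinsicConnection(b, a, "lateral"))
    return tuple(edges)


@dataclass(frozen=True)
class NetworkSpec:
    """Sources, extrinsic wiring and exogenous-input routing."""

    microcircuit: MicrocircuitSpec = field(default_factory=MicrocircuitSpec)
    sources: tuple[str, ...] = SOURCES
    extrinsic: tuple[ExtrinsicConnection, ...] = field(default_factory=_default_edges)
    #: sources receiving the exogenous Gaussian bump (into population ss)
    input_targets: tuple[str, ...] = ("lA1", "rA1", "lIFG", "rIFG")
    #: base extrinsic coupling applied on top of per-edge gain and termination
    extrinsic_base: float = 1.5
    #: exogenous input: peak time (ms), half-width (ms), amplitude
    input_peak_ms: float = 60.0
    input_width_ms: float = 8.0
    input_amplitude: float = 8.0

    def __post_init__(self):
        object.__setattr__(self, "sources", tuple(self.sources))
        object.__setattr__(self, "extrinsic", tuple(
            e if isinstance(e, ExtrinsicConnection) else ExtrinsicConnection(**e)
            for e in self.extrinsic
        ))
        object.__setattr__(self, "input_targets", tuple(self.input_targets))
        known = set(self.sources)
        for e in self.extrinsic:
            if e.source not in known or e.target not in known:
                raise ValueError(f"extrinsic edge {e.name} references unknown source")
            if e.type not in TERMINATION:
                raise ValueError(f"unknown extrinsic connection type {e.type!r}")
        for s in self.input_targets:
            if s not in known:
                raise ValueError(f"input target {s!r} not among sources")

    @property
    def n_sources(self) -> int:
        return len(self.sources)

    @property
    def n_populations(self) -> int:
        return self.n_sources * N_POP

    def source_index(self, name: str) -> int:
        return self.sources.index(name)

    def population_labels(self) -> list[str]:
        return [f"{s}:{p}" for s in self.sources for p in POP_INDEX]

    def extrinsic_parameter_names(self) -> list[str]:
        return [e.name for e in self.extrinsic]

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "microcircuit": self.microcircuit.to_dict(),
            "sources": list(self.sources),
            "extrinsic": [
                {"source": e.source, "target": e.target, "type": e.type, "gain": e.gain}
                for e in self.extrinsic
            ],
            "input_targets": list(self.input_targets),
            "extrinsic_base": self.extrinsic_base,
            "input_peak_ms": self.input_peak_ms,
            "input_width_ms": self.input_width_ms,
            "input_amplitude": self.input_amplitude,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        d = dict(d)
        d["microcircuit"] = MicrocircuitSpec.from_dict(d["microcircuit"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "NetworkSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def subnetwork(net: NetworkSpec, sources: list[str]) -> NetworkSpec:
    """Restrict a network to a subset of sources (edges within the subset
    are kept); handy for fast small-scale tests."""
    keep = set(sources)
    edges = tuple(e for e in net.extrinsic if e.source in keep and e.target in keep)
    return NetworkSpec(
        microcircuit=net.microcircuit,
        sources=tuple(s for s in net.sources if s in keep),
        extrinsic=edges,
        input_targets=tuple(s for s in net.input_targets if s in keep),
        extrinsic_base=net.extrinsic_base,
        input_peak_ms=net.input_peak_ms,
        input_width_ms=net.input_width_ms,
        input_amplitude=net.input_amplitude,
    )
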