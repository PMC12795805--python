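"""Domain types for conductance-based LIF network models.

Units follow the conventions of conductance-based point-neuron simulators:
millivolts (mV), picofarads (pF), nanosiemens (nS), milliseconds (ms) and
spikes per second (s^-1) for Poisson rates.  Synaptic currents come out in
picoamperes (pA = nS * mV).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml


class ParameterError(ValueError):
    """Raised when a model parameter violates its physical constraints."""


@dataclass(frozen=True)
class ReceptorKind:
    """A synaptic receptor channel: alpha-conductance time constant + reversal.

    A receptor whose reversal potential sits above the spike threshold of the
    postsynaptic neuron is excitatory; below, inhibitory.  Only the time
    constant, reversal potential and (per-projection) weight distinguish
    AMPA, NMDA and GABA here.
    """

    name: str  # one of "AMPA", "NMDA", "GABA"
    tau_syn: float  # ms
    E_rev: float  # mV

    def __post_init__(self) -> None:
        if self.tau_syn <= 0:
            raise ParameterError(f"tau_syn must be positive, got {self.tau_syn}")


@dataclass(frozen=True)
class NeuronParams:
    """Leaky integrate-and-fire membrane constants for one population."""

    V_reset: float  # mV
    V_th: float  # mV
    V_rest: float  # mV (leak reversal, E_L)
    C_m: float  # pF
    g_L: float  # nS
    E_ex: float  # mV, excitatory reversal (for bookkeeping/recording split)
    E_in: float  # mV, inhibitory reversal
    t_ref: float  # ms

    def __post_init__(self) -> None:
        if not self.V_reset < self.V_th:
            raise ParameterError("require V_reset < V_th")
        if self.t_ref <= 0 or self.C_m <= 0 or self.g_L <= 0:
            raise ParameterError("t_ref, C_m and g_L must be positive")
        if not (self.E_in < self.V_th < self.E_ex):
            raise ParameterError("require E_in < V_th < E_ex")

    @property
    def tau_m(self) -> float:
        """Membrane time constant C_m / g_L in ms."""
        return self.C_m / self.g_L


@dataclass(frozen=True)
class Population:
    name: str
    n: int
    params: NeuronParams

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ParameterError(f"population {self.name}: n must be positive")


@dataclass(frozen=True)
class ProjectionSpec:
    """One synaptic pathway between two populations.

    ``weight`` is the peak conductance magnitude g_max (nS); the sign of the
    postsynaptic effect is carried by the receptor's reversal potential.
    ``delay`` is either a scalar (ms) or a ``(low, high)`` pair from which
    per-connection delays are drawn uniformly.
    """

    source: str
    target: str
    in_degree: int
    weight: float  # nS, magnitude
    receptor: ReceptorKind
    delay: float | tuple[float, float]

    def __post_init__(self) -> None:
        if self.in_degree < 0:
            raise ParameterError("in_degree must be non-negative")
        if self.weight <= 0:
            raise ParameterError("weight magnitude must be positive")
        lo, hi = self.delay_range
        if lo <= 0 or hi < lo:
            raise ParameterError(f"bad delay specification {self.delay!r}")

    @property
    def delay_range(self) -> tuple[float, float]:
        if isinstance(self.delay, (tuple, list)):
            lo, hi = self.delay
            return float(lo), float(hi)
        return float(self.delay), float(self.delay)


@dataclass(frozen=True)
class PoissonDrive:
    """Background Poisson input, independent across target neurons."""

    target: str
    rate: float  # spikes/s per neuron (aggregate over the drive's afferents)
    weight: float  # nS
    receptor: ReceptorKind
    label: str = "bg"

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ParameterError("drive rate must be non-negative")
        if self.weight <= 0:
            raise ParameterError("drive weight must be positive")


@dataclass
class NetworkConfig:
    """A complete, simulable network instance: one point of a sweep grid."""

    name: str
    populations: list[Population]
    projections: list[ProjectionSpec]
    drives: list[PoissonDrive]
    coords: dict = field(default_factory=dict)  # grid coordinates / metadata
    I_ext: dict = field(default_factory=dict)  # pA per population name

    # -- structural queries ------------------------------------------------
    def population(self, name: str) -> Population:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def n_total(self) -> int:
        return sum(p.n for p in self.populations)

    def offsets(self) -> dict[str, int]:
        """Global neuron-index offset of each population."""
        out, acc = {}, 0
        for p in self.populations:
            out[p.name] = acc
            acc += p.n
        return out

    def validate(self) -> None:
        names = {p.name for p in self.populations}
        for proj in self.projections:
            if proj.source not in names or proj.target not in names:
                raise ParameterError(f"projection {proj.source}->{proj.target}: unknown population")
            n_src = self.population(proj.source).n
            avail = n_src - (1 if proj.source == proj.target else 0)
            if proj.in_degree > avail:
                raise ParameterError(
                    f"projection {proj.source}->{proj.target}: in_degree {proj.in_degree} "
                    f"exceeds available sources {avail}"
                )
        for d in self.drives:
            if d.target not in names:
                raise ParameterError(f"drive onto unknown population {d.target}")

    def projection_table(self):
        """Projections as a pandas DataFrame (one row per pathway)."""
        import pandas as pd

        rows = []
        for pr in self.projections:
            lo, hi = pr.delay_range
            rows.append(
                dict(
                    source=pr.source,
                    target=pr.target,
                    receptor=pr.receptor.name,
                    in_degree=pr.in_degree,
                    weight=pr.weight,
                    tau_syn=pr.receptor.tau_syn,
                    E_rev=pr.receptor.E_rev,
                    delay_lo=lo,
                    delay_hi=hi,
                )
            )
        return pd.DataFrame(rows)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "coords": dict(self.coords),
            "I_ext": dict(self.I_ext),
            "populations": [
                {"name": p.name, "n": p.n, "params": asdict(p.params)} for p in self.populations
            ],
            "projections": [
                {
                    "source": pr.source,
                    "target": pr.target,
                    "in_degree": pr.in_degree,
                    "weight": pr.weight,
                    "delay": list(pr.delay) if isinstance(pr.delay, (tuple, list)) else pr.delay,
                    "receptor": asdict(pr.receptor),
                }
                for pr in self.projections
            ],
            "drives": [
                {
                    "target": d.target,
                    "rate": d.rate,
                    "weight": d.weight,
                    "label": d.label,
                    "receptor": asdict(d.receptor),
                }
                for d in self.drives
            ],
        }

    def to_yaml(self, path=None) -> Optional[str]:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        def _rec(r):
            return ReceptorKind(**r)

        pops = [Population(p["name"], int(p["n"]), NeuronParams(**p["params"])) for p in d["populations"]]
        projs = [
            ProjectionSpec(
                source=pr["source"],
                target=pr["target"],
                in_degree=int(pr["in_degree"]),
                weight=float(pr["weight"]),
                delay=tuple(pr["delay"]) if isinstance(pr["delay"], (list, tuple)) else float(pr["delay"]),
                receptor=_rec(pr["receptor"]),
            )
            for pr in d["projections"]
        ]
        drives = [
            PoissonDrive(
                target=dr["target"],
                rate=float(dr["rate"]),
                weight=float(dr["weight"]),
                receptor=_rec(dr["receptor"]),
                label=dr.get("label", "bg"),
            )
            for dr in d["drives"]
        ]
        cfg = cls(
            name=d["name"],
            populations=pops,
            projections=projs,
            drives=drives,
            coords=dict(d.get("coords", {})),
            I_ext=dict(d.get("I_ext", {})),
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, src) -> "NetworkConfig":
        if hasattr(src, "read"):
            d = yaml.safe_load(src.read())
        else:
            try:
                with open(src) as fh:
                    d = yaml.safe_load(fh.read())
            except (OSError, FileNotFoundError):
                d = yaml.safe_load(src)
        return cls.from_dict(d)
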