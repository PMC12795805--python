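"""LFP proxy: summed synaptic currents of a small set of recorded neurons.

Point neurons carry no dipole, so the population signal is proxied by the
sum over recorded excitatory neurons of their synaptic currents
I_c = G_c (V_m - E_c) for the excitatory and inhibitory channels, sampled
at 1 kHz.  The models here are homogeneous, so ten neurons already carry
the population's spectral signature (checked by test against a larger
recorded set).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulator import SimResult


@dataclass
class LfpTrace:
    samples: np.ndarray  # pA, arbitrary-unit current-like signal
    fs: float  # Hz, fixed 1 kHz in the standard pipeline
    n_contributing_neurons: int
    t0_ms: float = 0.0

    @property
    def duration_ms(self) -> float:
        return len(self.samples) / self.fs * 1000.0

    def write_csv(self, path) -> None:
        t = self.t0_ms + np.arange(len(self.samples)) / self.fs * 1000.0
        np.savetxt(
            path,
            np.column_stack([t, self.samples]),
            delimiter=",",
            header="time_ms,lfp",
            comments="",
        )


def read_trace_csv(path) -> LfpTrace:
    """Read a two-column (time_ms, value) CSV/whitespace trace at 1 kHz."""
    delim = "," if str(path).endswith(".csv") else None
    arr = np.loadtxt(path, delimiter=delim, skiprows=_sniff_header(path), ndmin=2)
    t = arr[:, 0]
    if len(t) > 1:
        dt = np.median(np.diff(t))
        fs = 1000.0 / dt
    else:
        fs = 1000.0
    return LfpTrace(samples=arr[:, 1], fs=fs, n_contributing_neurons=0, t0_ms=float(t[0]))


def _sniff_header(path) -> int:
    with open(path) as fh:
        first = fh.readline()
    try:
        float(first.replace(",", " ").split()[0])
        return 0
    except (ValueError, IndexError):
        return 1


def make_lfp(sim: SimResult, neuron_ids=None, mode: str = "signed") -> LfpTrace:
    """Build the LFP proxy from recorded conductances and membrane traces.

    ``neuron_ids`` selects a subset of the recorded neurons (global indices);
    default: all recorded neurons.  ``mode`` is "signed" (sum of signed
    currents; excitatory current is inward/negative) or "rectified"
    (sum of |I_ex| + |I_in|).
    """
    if neuron_ids is None:
        cols = np.arange(len(sim.record_ids))
    else:
        wanted = np.asarray(neuron_ids)
        pos = {int(g): i for i, g in enumerate(sim.record_ids)}
        missing = [int(w) for w in wanted if int(w) not in pos]
        if missing:
            raise ValueError(f"neurons {missing} were not recorded")
        cols = np.array([pos[int(w)] for w in wanted])
    if cols.size == 0:
        raise ValueError("no recorded neurons selected")

    # recorded neurons come from one population; take its reversal potentials
    offs = sim.config.offsets()
    gid = int(sim.record_ids[cols[0]])
    pop = next(
        p for p in sim.config.populations if offs[p.name] <= gid < offs[p.name] + p.n
    )
    E_ex, E_in = pop.params.E_ex, pop.params.E_in

    V = sim.V_rec[:, cols]
    I_ex = sim.Gex_rec[:, cols] * (V - E_ex)
    I_in = sim.Gin_rec[:, cols] * (V - E_in)
    if mode == "rectified":
        lfp = np.sum(np.abs(I_ex) + np.abs(I_in), axis=1)
    elif mode == "signed":
        lfp = np.sum(I_ex + I_in, axis=1)
    else:
        raise ValueError(f"unknown LFP mode {mode!r}")
    return LfpTrace(samples=lfp, fs=1000.0, n_contributing_neurons=cols.size,
                    t0_ms=float(sim.t_rec[0]))


def mean_conductances(sim: SimResult, t_start_ms: float = 0.0) -> tuple[float, float]:
    """Time- and neuron-averaged excitatory and inhibitory conductance (nS)."""
    m = sim.t_rec >= t_start_ms
    return float(sim.Gex_rec[m].mean()), float(sim.Gin_rec[m].mean())
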