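"""Fixed-step conductance-based LIF network simulator.

Alpha-function synapses (exact per-step exponential update), Poisson
background drives independent across neurons, fixed in-degree random
wiring with per-projection (or per-connection) transmission delays
honoured through a ring buffer, and 1 kHz recording of membrane potential
and excitatory/inhibitory conductances for a chosen subset of neurons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _engine
from .params import NetworkConfig, ParameterError
from .seeds import SeedBundle


class WiringError(ValueError):
    pass


class NumericError(RuntimeError):
    """Integration left the physically admissible voltage range."""

    def __init__(self, neuron: int, time_ms: float):
        self.neuron = neuron
        self.time_ms = time_ms
        super().__init__(f"unstable integration: neuron {neuron} at t={time_ms:.1f} ms")


def alpha_conductance_kernel(t, tau_syn: float, g_max: float):
    """Alpha conductance transient g_max * (t/tau) * exp(-t/tau).

    Zero for t < 0; peaks at t = tau_syn with value g_max/e.  ``t`` may be
    scalar or array (ms).
    """
    if tau_syn <= 0:
        raise ParameterError(f"tau_syn must be positive, got {tau_syn}")
    t = np.asarray(t, dtype=float)
    out = np.where(t >= 0, g_max * (t / tau_syn) * np.exp(-np.clip(t, 0, None) / tau_syn), 0.0)
    return out if out.ndim else float(out)


def conductance_trace(
    spike_times_ms, tau_syn: float, g_max: float, duration_ms: float, step_ms: float = 0.1
) -> np.ndarray:
    """Exact discrete conductance for input spikes through one alpha synapse.

    Spikes are snapped to the step grid; the returned trace samples g at
    every step, using the same two-state propagator as the network engine,
    so superposition over spikes is exact.
    """
    if tau_syn <= 0:
        raise ParameterError(f"tau_syn must be positive, got {tau_syn}")
    n_steps = int(round(duration_ms / step_ms))
    steps = np.sort(np.round(np.asarray(spike_times_ms, dtype=float) / step_ms)).astype(np.int64)
    amps = np.full(steps.size, g_max / tau_syn)
    return _engine.alpha_train(steps, amps, n_steps, step_ms, tau_syn)


def wire_fixed_indegree(
    n_source: int,
    n_target: int,
    in_degree: int,
    rng: np.random.Generator,
    self_connections_excluded_offset: int | None = None,
) -> np.ndarray:
    """Sample a fixed in-degree adjacency.

    Every target neuron receives exactly ``in_degree`` distinct presynaptic
    partners, drawn uniformly without replacement; the out-degree across
    sources is then binomial-like with mean in_degree * n_target / n_source.
    If ``self_connections_excluded_offset`` is given, source and target index
    the same population and target ``j`` never draws source
    ``j - offset``... i.e. itself.

    Returns an ``(n_target, in_degree)`` int32 array of source indices.
    """
    avail = n_source - (1 if self_connections_excluded_offset is not None else 0)
    if in_degree > avail:
        raise WiringError(f"in_degree {in_degree} exceeds available sources {avail}")
    out = np.empty((n_target, in_degree), dtype=np.int32)
    if in_degree == 0:
        return out
    for j in range(n_target):
        if self_connections_excluded_offset is not None:
            # draw from n_source-1 and skip own index
            pick = rng.choice(n_source - 1, size=in_degree, replace=False)
            self_idx = j - self_connections_excluded_offset
            if 0 <= self_idx < n_source:
                pick = np.where(pick >= self_idx, pick + 1, pick)
            out[j] = pick
        else:
            out[j] = rng.choice(n_source, size=in_degree, replace=False)
    return out


@dataclass
class SimResult:
    """Raster plus 1 kHz recorded traces for a subset of neurons."""

    config: NetworkConfig
    step: float  # ms
    duration: float  # ms
    spike_times: np.ndarray  # ms, in time order per the integration loop
    spike_ids: np.ndarray  # global neuron indices
    t_rec: np.ndarray  # ms, 1 kHz sample times
    record_ids: np.ndarray  # global indices of recorded neurons
    V_rec: np.ndarray  # (n_samples, n_rec) mV
    Gex_rec: np.ndarray  # (n_samples, n_rec) nS
    Gin_rec: np.ndarray  # (n_samples, n_rec) nS
    seeds: SeedBundle

    def spikes_of(self, population: str) -> tuple[np.ndarray, np.ndarray]:
        off = self.config.offsets()[population]
        n = self.config.population(population).n
        m = (self.spike_ids >= off) & (self.spike_ids < off + n)
        return self.spike_times[m], self.spike_ids[m]

    def rate_of(self, population: str, t_start: float = 0.0) -> float:
        """Population-mean firing rate (spikes/s) from ``t_start`` on."""
        t, _ = self.spikes_of(population)
        n = self.config.population(population).n
        window_s = (self.duration - t_start) / 1000.0
        return float(np.sum(t > t_start)) / (n * window_s)

    def min_isi(self) -> float:
        """Smallest inter-spike interval over all neurons (ms); inf if none."""
        best = np.inf
        order = np.lexsort((self.spike_times, self.spike_ids))
        ids = self.spike_ids[order]
        ts = self.spike_times[order]
        same = ids[1:] == ids[:-1]
        if np.any(same):
            best = float(np.min(np.diff(ts)[same]))
        return best

    def plot_raster(self, ax=None, t_start: float = 0.0):
        """Spike raster, populations stacked and labeled."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        offs = self.config.offsets()
        for p in self.config.populations:
            t, ids = self.spikes_of(p.name)
            m = t >= t_start
            ax.plot(t[m], ids[m], ".", ms=1, label=p.name)
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("neuron")
        ax.legend(frameon=False, markerscale=8)
        return ax

    def write_raster(self, path, fmt: str = "txt") -> None:
        cols = np.column_stack([self.spike_times, self.spike_ids])
        if fmt == "csv":
            np.savetxt(path, cols, fmt="%.4f,%d", header="time_ms,neuron_id", comments="")
        else:
            np.savetxt(path, cols, fmt="%.4f %d")

    def write_conductances(self, path) -> None:
        """1 kHz conductance traces as CSV: time plus G_ex, G_in per
        recorded neuron (columns gex_<id>, gin_<id>)."""
        header = ["time_ms"]
        cols = [self.t_rec]
        for k, gid in enumerate(self.record_ids):
            header += [f"gex_{gid}", f"gin_{gid}"]
            cols += [self.Gex_rec[:, k], self.Gin_rec[:, k]]
        np.savetxt(path, np.column_stack(cols), delimiter=",",
                   header=",".join(header), comments="")


def read_raster(path) -> tuple[np.ndarray, np.ndarray]:
    arr = np.loadtxt(path, delimiter="," if str(path).endswith(".csv") else None, skiprows=0, ndmin=2)
    if arr.size == 0:
        return np.empty(0), np.empty(0, dtype=int)
    return arr[:, 0], arr[:, 1].astype(int)


def _build_channels(config: NetworkConfig):
    """Assign per-population receptor channels from projections + drives.

    Channels are keyed by (tau_syn, E_rev) within each target population; at
    most three (AMPA/NMDA/GABA) occur in the models considered here.
    """
    chan_key_by_pop: dict[str, list] = {p.name: [] for p in config.populations}

    def chan_index(pop: str, rec) -> int:
        key = (rec.tau_syn, rec.E_rev)
        keys = chan_key_by_pop[pop]
        if key not in keys:
            keys.append(key)
        return keys.index(key)

    proj_chan = [chan_index(pr.target, pr.receptor) for pr in config.projections]
    drive_chan = [chan_index(d.target, d.receptor) for d in config.drives]
    n_chan = max(1, max((len(v) for v in chan_key_by_pop.values()), default=1))
    return chan_key_by_pop, proj_chan, drive_chan, n_chan


def simulate(
    config: NetworkConfig,
    duration: float,
    seeds: SeedBundle,
    step: float = 0.1,
    record: "int | np.ndarray" = 10,
    record_population: str | None = None,
    method: str = "exp",
    fs_record: float = 1000.0,
) -> SimResult:
    """Integrate the network and return raster + recorded traces.

    ``record`` is either a neuron count (the first ``record`` neurons of
    ``record_population``, default the first population) or an explicit array
    of global neuron indices.  Traces are sampled at ``fs_record`` (1 kHz).
    """
    config.validate()
    if step <= 0:
        raise ParameterError("step must be positive")
    n_steps = int(round(duration / step))
    if abs(n_steps * step - duration) > 1e-9:
        raise ParameterError("step must divide duration")
    for pr in config.projections:
        if pr.delay_range[0] < step - 1e-12:
            raise ParameterError("projection delays must be >= the simulation step")

    pops = config.populations
    offs = config.offsets()
    N = config.n_total
    chan_keys, proj_chan, drive_chan_idx, C = _build_channels(config)

    # per-neuron parameter arrays
    V_th = np.empty(N)
    V_reset = np.empty(N)
    V_rest = np.empty(N)
    g_L = np.empty(N)
    C_m = np.empty(N)
    I_ext = np.zeros(N)
    t_ref_steps = np.empty(N, dtype=np.int64)
    tau = np.ones((N, C))
    E_rev = np.zeros((N, C))
    exc_mask = np.zeros((N, C), dtype=np.bool_)
    for p in pops:
        sl = slice(offs[p.name], offs[p.name] + p.n)
        prm = p.params
        V_th[sl] = prm.V_th
        V_reset[sl] = prm.V_reset
        V_rest[sl] = prm.V_rest
        g_L[sl] = prm.g_L
        C_m[sl] = prm.C_m
        I_ext[sl] = float(config.I_ext.get(p.name, 0.0))
        t_ref_steps[sl] = int(round(prm.t_ref / step))
        for c, (tau_c, e_c) in enumerate(chan_keys[p.name]):
            tau[sl, c] = tau_c
            E_rev[sl, c] = e_c
            exc_mask[sl, c] = e_c > prm.V_th
    decay = np.exp(-step / tau)
    decay_half = np.exp(-0.5 * step / tau)

    # wiring -> flat edge arrays grouped by source
    wrng = seeds.wiring_rng()
    src_list, tgt_list, chan_list, amp_list, del_list = [], [], [], [], []
    for pr, ch in zip(config.projections, proj_chan):
        n_src = config.population(pr.source).n
        n_tgt = config.population(pr.target).n
        self_off = offs[pr.source] - offs[pr.target] if pr.source == pr.target else None
        adj = wire_fixed_indegree(
            n_src, n_tgt, pr.in_degree, wrng, self_connections_excluded_offset=0 if self_off is not None else None
        )
        n_edges = adj.size
        if n_edges == 0:
            continue
        src = adj.ravel() + offs[pr.source]
        tgt = np.repeat(np.arange(n_tgt, dtype=np.int64) + offs[pr.target], pr.in_degree)
        lo, hi = pr.delay_range
        if hi > lo:
            d_ms = wrng.uniform(lo, hi, size=n_edges)
        else:
            d_ms = np.full(n_edges, lo)
        src_list.append(src)
        tgt_list.append(tgt)
        chan_list.append(np.full(n_edges, ch, dtype=np.int64))
        amp_list.append(np.full(n_edges, pr.weight / pr.receptor.tau_syn))
        del_list.append(np.maximum(np.round(d_ms / step).astype(np.int64), 1))
    if src_list:
        src = np.concatenate(src_list)
        order = np.argsort(src, kind="stable")
        src = src[order]
        edge_tgt = np.concatenate(tgt_list)[order]
        edge_chan = np.concatenate(chan_list)[order]
        edge_amp = np.concatenate(amp_list)[order]
        edge_delay = np.concatenate(del_list)[order]
        edge_ptr = np.searchsorted(src, np.arange(N + 1))
        max_delay = int(edge_delay.max())
    else:
        edge_tgt = np.empty(0, dtype=np.int64)
        edge_chan = np.empty(0, dtype=np.int64)
        edge_amp = np.empty(0)
        edge_delay = np.empty(0, dtype=np.int64)
        edge_ptr = np.zeros(N + 1, dtype=np.int64)
        max_delay = 1
    ring = np.zeros((max_delay + 1, N, C))

    # Poisson drive count matrices (independent across neurons)
    n_drives = len(config.drives)
    drive_col0 = np.zeros(max(n_drives, 1), dtype=np.int64)
    drive_n = np.zeros(max(n_drives, 1), dtype=np.int64)
    drive_tgt0 = np.zeros(max(n_drives, 1), dtype=np.int64)
    drive_chan = np.zeros(max(n_drives, 1), dtype=np.int64)
    drive_amp = np.zeros(max(n_drives, 1))
    blocks = []
    col = 0
    for d_i, d in enumerate(config.drives):
        n_tgt = config.population(d.target).n
        lam = d.rate * step / 1000.0
        counts = seeds.drive_rng(d_i).poisson(lam, size=(n_steps, n_tgt)).astype(np.int16)
        blocks.append(counts)
        drive_col0[d_i] = col
        drive_n[d_i] = n_tgt
        drive_tgt0[d_i] = offs[d.target]
        drive_chan[d_i] = drive_chan_idx[d_i]
        drive_amp[d_i] = d.weight / d.receptor.tau_syn
        col += n_tgt
    drive_counts = np.concatenate(blocks, axis=1) if blocks else np.zeros((n_steps, 1), dtype=np.int16)
    if not blocks:
        drive_col0 = drive_col0[:0]
        drive_n = drive_n[:0]
        drive_tgt0 = drive_tgt0[:0]
        drive_chan = drive_chan[:0]
        drive_amp = drive_amp[:0]

    # initial conditions: V uniform in [V_reset, V_th), conductances zero
    irng = seeds.init_rng()
    V = V_reset + (V_th - V_reset) * irng.uniform(0.0, 1.0, size=N)
    refr = np.zeros(N, dtype=np.int64)
    z = np.zeros((N, C))
    g = np.zeros((N, C))

    # recording setup
    if np.isscalar(record):
        pop = record_population or pops[0].name
        n_req = int(record)
        if n_req > config.population(pop).n:
            raise ParameterError(f"cannot record {n_req} neurons from population {pop}")
        rec_ids = np.arange(n_req, dtype=np.int64) + offs[pop]
    else:
        rec_ids = np.asarray(record, dtype=np.int64)
    rec_every = int(round(1000.0 / (fs_record * step)))
    n_samples = (n_steps + rec_every - 1) // rec_every
    V_out = np.zeros((n_samples, rec_ids.size))
    Gex_out = np.zeros((n_samples, rec_ids.size))
    Gin_out = np.zeros((n_samples, rec_ids.size))

    cap = int(np.sum([p.n * (duration / p.params.t_ref + 2) for p in pops]))
    spike_t = np.zeros(cap)
    spike_id = np.zeros(cap, dtype=np.int64)

    V_lo = min(E_rev.min(), V_rest.min()) - 5.0
    V_hi = max(E_rev.max(), V_th.max()) + 5.0

    n_sp, samp, status, bad_i, bad_n = _engine.run_network(
        n_steps,
        step,
        V,
        refr,
        z,
        g,
        decay,
        decay_half,
        tau,
        E_rev,
        exc_mask,
        V_th,
        V_reset,
        V_rest,
        g_L,
        C_m,
        I_ext,
        t_ref_steps,
        edge_ptr.astype(np.int64),
        edge_tgt,
        edge_chan,
        edge_amp,
        edge_delay,
        ring,
        drive_counts,
        drive_col0,
        drive_n,
        drive_tgt0,
        drive_chan,
        drive_amp,
        rec_ids,
        rec_every,
        V_out,
        Gex_out,
        Gin_out,
        spike_t,
        spike_id,
        V_lo,
        V_hi,
        {"exp": 0, "euler": 1, "rk4": 2}[method],
    )
    if status == _engine.STATUS_UNSTABLE:
        raise NumericError(int(bad_i), float(bad_n * step))

    t_rec = np.arange(samp) * (rec_every * step)
    return SimResult(
        config=config,
        step=step,
        duration=duration,
        spike_times=spike_t[:n_sp].copy(),
        spike_ids=spike_id[:n_sp].copy(),
        t_rec=t_rec,
        record_ids=rec_ids,
        V_rec=V_out[:samp],
        Gex_rec=Gex_out[:samp],
        Gin_rec=Gin_out[:samp],
        seeds=seeds,
    )
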