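"""Builders for the two network motifs and their sweep grids.

* STN-GPe: excitatory subthalamic nucleus and inhibitory globus pallidus
  externa, no E-E recurrence.  Swept over four parameters (background rates
  to STN and GPe, STN->GPe and GPe->STN weights); an extra 600 spikes/s
  inhibitory Poisson drive onto GPe mimics striatal inhibition.
* Neocortex: mutually connected E (pyramidal) and I (interneuron)
  populations.  E synapses split their 800 afferents between NMDA (zeta)
  and AMPA (800 - zeta) receptors; g scales inhibitory weights relative to
  the printed g = 4 baseline; eta scales the background drive in units of
  the rate that holds an isolated neuron at threshold in the mean.

Sizes default to the desk-scale "mini" preset (populations / 10, printed
in-degrees preserved); the full-size preset is one argument away.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

from .params import (
    NetworkConfig,
    NeuronParams,
    ParameterError,
    PoissonDrive,
    Population,
    ProjectionSpec,
    ReceptorKind,
)

# ---------------------------------------------------------------------------
# STN-GPe motif
# ---------------------------------------------------------------------------

# LIF membrane constants for both STN and GPe; the resting potential is not
# part of the published set and is fixed at -70 mV (= V_reset).
STN_GPE_NEURON = NeuronParams(
    V_reset=-70.0,
    V_th=-54.0,
    V_rest=-70.0,
    C_m=200.0,
    g_L=10.0,
    E_ex=0.0,
    E_in=-80.0,
    t_ref=5.0,
)

AMPA_STN_GPE = ReceptorKind("AMPA", tau_syn=5.0, E_rev=0.0)
GABA_STN_GPE = ReceptorKind("GABA", tau_syn=10.0, E_rev=-80.0)

# (in_degree, weight nS, delay ms) per pathway; GPe pathways are inhibitory
STN_GPE_CONNECTIVITY = {
    "STN->GPe": (20, 1.5, 5.0),
    "GPe->STN": (40, 1.3, 5.0),
    "GPe->GPe": (40, 0.725, 2.0),
}

STN_GPE_SIZES = {"full": (1000, 2000), "mini": (100, 200)}
STN_GPE_BG_WEIGHT = 1.5  # nS; background excitatory weight (calibration knob)
GPE_PERTURBATION_WEIGHT = 0.725  # nS; reuses the GPe->GPe inhibitory weight
GPE_PERTURBATION_RATE = 600.0  # spikes/s


def build_stn_gpe(
    stn_bg: float = 1900.0,
    gpe_bg: float = 1200.0,
    stn_gpe_wt: float = 1.5,
    gpe_stn_wt: float = -1.3,
    sizes: tuple[int, int] | str = "mini",
    perturbation_rate: float = 0.0,
    bg_weight: float = STN_GPE_BG_WEIGHT,
    coords: dict | None = None,
) -> NetworkConfig:
    """Assemble one STN-GPe configuration.

    ``gpe_stn_wt`` carries the printed negative sign (inhibitory); its
    magnitude becomes the GABA peak conductance.  ``perturbation_rate`` > 0
    adds the extra inhibitory Poisson drive onto GPe only.
    """
    if isinstance(sizes, str):
        sizes = STN_GPE_SIZES[sizes]
    n_stn, n_gpe = sizes
    if gpe_stn_wt >= 0:
        raise ParameterError("GPe->STN weight must be negative (inhibitory pathway)")
    if stn_gpe_wt <= 0:
        raise ParameterError("STN->GPe weight must be positive (excitatory pathway)")

    k_sg, _, d_sg = STN_GPE_CONNECTIVITY["STN->GPe"]
    k_gs, _, d_gs = STN_GPE_CONNECTIVITY["GPe->STN"]
    k_gg, w_gg, d_gg = STN_GPE_CONNECTIVITY["GPe->GPe"]

    pops = [
        Population("STN", n_stn, STN_GPE_NEURON),
        Population("GPe", n_gpe, STN_GPE_NEURON),
    ]
    projections = [
        ProjectionSpec("STN", "GPe", k_sg, stn_gpe_wt, AMPA_STN_GPE, d_sg),
        ProjectionSpec("GPe", "STN", k_gs, abs(gpe_stn_wt), GABA_STN_GPE, d_gs),
        ProjectionSpec("GPe", "GPe", min(k_gg, n_gpe - 1), w_gg, GABA_STN_GPE, d_gg),
    ]
    drives = [
        PoissonDrive("STN", stn_bg, bg_weight, AMPA_STN_GPE, label="bg_STN"),
        PoissonDrive("GPe", gpe_bg, bg_weight, AMPA_STN_GPE, label="bg_GPe"),
    ]
    if perturbation_rate > 0:
        drives.append(
            PoissonDrive("GPe", perturbation_rate, GPE_PERTURBATION_WEIGHT, GABA_STN_GPE, label="perturb")
        )
    c = dict(coords or {})
    c.setdefault("stn_bg", stn_bg)
    c.setdefault("gpe_bg", gpe_bg)
    c.setdefault("stn_gpe_wt", stn_gpe_wt)
    c.setdefault("gpe_stn_wt", gpe_stn_wt)
    c["perturbation_rate"] = perturbation_rate
    cfg = NetworkConfig("stn-gpe", pops, projections, drives, coords=c)
    cfg.validate()
    return cfg


@dataclass(frozen=True)
class StnGpeGrid:
    """Cartesian sweep over the four STN-GPe state variables.

    Default value lists are the published five-point sets (5^4 = 625
    configurations); the mini preset keeps the first, middle and last value
    of each list (3^4 = 81).
    """

    stn_bg: tuple = (1700.0, 1800.0, 1900.0, 2000.0, 2100.0)
    gpe_bg: tuple = (800.0, 900.0, 1200.0, 1300.0, 1400.0)
    stn_gpe_wt: tuple = (0.8, 1.2, 1.5, 1.6, 1.8)
    gpe_stn_wt: tuple = (-1.7, -1.5, -1.3, -1.2, -1.1)
    perturbation_rate: float = 0.0

    @classmethod
    def mini(cls, perturbation_rate: float = 0.0) -> "StnGpeGrid":
        full = cls()
        sub = lambda v: (v[0], v[2], v[4])
        return cls(
            stn_bg=sub(full.stn_bg),
            gpe_bg=sub(full.gpe_bg),
            stn_gpe_wt=sub(full.stn_gpe_wt),
            gpe_stn_wt=sub(full.gpe_stn_wt),
            perturbation_rate=perturbation_rate,
        )

    @property
    def size(self) -> int:
        return len(self.stn_bg) * len(self.gpe_bg) * len(self.stn_gpe_wt) * len(self.gpe_stn_wt)


# ---------------------------------------------------------------------------
# Neocortical motif
# ---------------------------------------------------------------------------

# E_ex is kept at the printed -10 mV (above threshold, hence still
# excitatory); pass e_ex=0.0 to build_cortex for the conventional value.
def cortex_neuron(e_ex: float = -10.0) -> NeuronParams:
    return NeuronParams(
        V_reset=-65.0,
        V_th=-54.0,
        V_rest=-70.0,
        C_m=60.0,
        g_L=12.0,
        E_ex=e_ex,
        E_in=-84.0,
        t_ref=2.0,
    )


TAU_AMPA = 3.0
TAU_NMDA = 30.0
TAU_GABA_CTX = 5.0

# printed weights (nS) at the g = 4 baseline and delays (ms)
CORTEX_WEIGHTS = {
    "E->I_NMDA": 0.16,
    "E->I_AMPA": 0.14,
    "E->E_NMDA": 0.15,
    "E->E_AMPA": 0.13,
    "I->E": 0.547,
    "I->I": 0.3,
}
CORTEX_DELAYS = {"E->E": 2.0, "E->I": 2.0, "I->E": 2.0, "I->I": (1.0, 5.0)}
CORTEX_IN_DEGREE_E = 800  # excitatory afferents per neuron (NMDA + AMPA)
CORTEX_IN_DEGREE_I = 200  # inhibitory afferents per neuron
G_BASELINE = 4.0
CORTEX_SIZES = {"full": (8000, 2000), "mini": (800, 200)}
# Background weight is a calibration knob (the value is not part of the
# published set): 1.5 nS puts the g=4, zeta=400 base state at the target
# pyramidal rate of ~0.68 spikes/s within the eta search range.
CORTEX_BG_WEIGHT = 1.5


def cortex_threshold_rate(
    e_ex: float = -10.0, bg_weight: float = CORTEX_BG_WEIGHT, zeta: int = 0
) -> float:
    """Aggregate Poisson rate (spikes/s) whose Campbell-mean conductance
    holds an isolated neuron at threshold: the eta = 1 reference.

    The background is glutamatergic and sees the postsynaptic receptor
    composition, so a fraction zeta/800 of its events drive the NMDA
    channel; the mean conductance per unit rate uses the mixed time
    constant accordingly.
    """
    p = cortex_neuron(e_ex)
    g_thr = p.g_L * (p.V_th - p.V_rest) / (e_ex - p.V_th)
    fz = zeta / CORTEX_IN_DEGREE_E
    tau_mix = fz * TAU_NMDA + (1.0 - fz) * TAU_AMPA
    return g_thr / (bg_weight * tau_mix / 1000.0)


def build_cortex(
    g: float = 4.0,
    zeta: int = 400,
    eta: float = 2.0,
    sizes: tuple[int, int] | str = "mini",
    e_ex: float = -10.0,
    bg_weight: float = CORTEX_BG_WEIGHT,
    bg_rate: float | None = None,
    coords: dict | None = None,
) -> NetworkConfig:
    """Assemble one neocortical configuration.

    ``zeta`` of the 800 excitatory afferents per neuron are NMDA, the rest
    AMPA; ``g`` rescales the printed inhibitory weights by g/4; background
    rate is ``eta`` times the threshold rate unless ``bg_rate`` overrides it.

    Receptor composition is a postsynaptic property, so the external
    glutamatergic background splits across the NMDA and AMPA channels in
    the same zeta : (800 - zeta) proportion as the recurrent synapses.
    """
    if isinstance(sizes, str):
        sizes = CORTEX_SIZES[sizes]
    n_e, n_i = sizes
    if not 0 <= zeta <= CORTEX_IN_DEGREE_E:
        raise ParameterError(f"zeta must lie in [0, {CORTEX_IN_DEGREE_E}]")
    if zeta % 50 != 0:
        warnings.warn(f"zeta={zeta} is not a multiple of 50; building anyway", stacklevel=2)
    if g <= 0:
        raise ParameterError("g must be positive")

    neuron = cortex_neuron(e_ex)
    ampa = ReceptorKind("AMPA", TAU_AMPA, e_ex)
    nmda = ReceptorKind("NMDA", TAU_NMDA, e_ex)
    gaba = ReceptorKind("GABA", TAU_GABA_CTX, -84.0)
    scale_i = g / G_BASELINE

    def cap(k: int, n_src: int, recurrent: bool) -> int:
        return min(k, n_src - 1) if recurrent else min(k, n_src)

    k_ampa = CORTEX_IN_DEGREE_E - zeta
    projections = []
    if zeta > 0:
        projections += [
            ProjectionSpec("E", "E", cap(zeta, n_e, True), CORTEX_WEIGHTS["E->E_NMDA"], nmda, CORTEX_DELAYS["E->E"]),
            ProjectionSpec("E", "I", cap(zeta, n_e, False), CORTEX_WEIGHTS["E->I_NMDA"], nmda, CORTEX_DELAYS["E->I"]),
        ]
    if k_ampa > 0:
        projections += [
            ProjectionSpec("E", "E", cap(k_ampa, n_e, True), CORTEX_WEIGHTS["E->E_AMPA"], ampa, CORTEX_DELAYS["E->E"]),
            ProjectionSpec("E", "I", cap(k_ampa, n_e, False), CORTEX_WEIGHTS["E->I_AMPA"], ampa, CORTEX_DELAYS["E->I"]),
        ]
    projections += [
        ProjectionSpec("I", "E", cap(CORTEX_IN_DEGREE_I, n_i, False), CORTEX_WEIGHTS["I->E"] * scale_i, gaba, CORTEX_DELAYS["I->E"]),
        ProjectionSpec("I", "I", cap(CORTEX_IN_DEGREE_I, n_i, True), CORTEX_WEIGHTS["I->I"] * scale_i, gaba, CORTEX_DELAYS["I->I"]),
    ]

    nu_thr = cortex_threshold_rate(e_ex, bg_weight, zeta)
    rate = bg_rate if bg_rate is not None else eta * nu_thr
    fz = zeta / CORTEX_IN_DEGREE_E
    drives = []
    for tgt in ("E", "I"):
        if fz > 0:
            drives.append(PoissonDrive(tgt, rate * fz, bg_weight, nmda, label=f"bg_{tgt}_nmda"))
        if fz < 1:
            drives.append(PoissonDrive(tgt, rate * (1.0 - fz), bg_weight, ampa, label=f"bg_{tgt}_ampa"))
    pops = [Population("E", n_e, neuron), Population("I", n_i, neuron)]
    c = dict(coords or {})
    c.setdefault("g", g)
    c.setdefault("zeta", zeta)
    c.setdefault("eta", eta if bg_rate is None else rate / nu_thr)
    c["bg_rate"] = rate
    cfg = NetworkConfig("cortex", pops, projections, drives, coords=c)
    cfg.validate()
    return cfg


@dataclass(frozen=True)
class CortexGrid:
    """Cartesian sweep over (g, eta, zeta).

    The eta range spans from just below the calibrated base-state drive to
    a strongly driven, oscillation-prone regime; eta units are multiples of
    the single-neuron threshold rate.
    """

    g: tuple = (4.0, 8.0, 12.0)
    eta: tuple = (0.8, 1.0, 1.2, 1.4, 1.6, 1.8, 2.0, 2.2, 2.4)
    zeta: tuple = tuple(range(0, 501, 50))

    @classmethod
    def mini(cls) -> "CortexGrid":
        return cls(g=(4.0, 8.0, 12.0), eta=(0.8, 1.6, 2.4), zeta=(0, 400, 500))

    @property
    def size(self) -> int:
        return len(self.g) * len(self.eta) * len(self.zeta)


# ---------------------------------------------------------------------------
# Grid enumeration
# ---------------------------------------------------------------------------


def enumerate_grid(grid, sizes="mini") -> list[NetworkConfig]:
    """Expand a grid into an ordered list of configurations.

    Ordering is lexicographic in the parameter order the grids declare
    (STN-GPe: stn_bg, gpe_bg, stn_gpe_wt, gpe_stn_wt; cortex: g, eta, zeta);
    each config carries its grid coordinates and index.
    """
    configs: list[NetworkConfig] = []
    if isinstance(grid, StnGpeGrid):
        lists = [grid.stn_bg, grid.gpe_bg, grid.stn_gpe_wt, grid.gpe_stn_wt]
        if any(len(v) == 0 for v in lists):
            raise ParameterError("grid value lists must be non-empty")
        for i, (a, b, w1, w2) in enumerate(itertools.product(*lists)):
            cfg = build_stn_gpe(
                stn_bg=a, gpe_bg=b, stn_gpe_wt=w1, gpe_stn_wt=w2,
                sizes=sizes, perturbation_rate=grid.perturbation_rate,
            )
            cfg.coords["grid_index"] = i
            configs.append(cfg)
    elif isinstance(grid, CortexGrid):
        lists = [grid.g, grid.eta, grid.zeta]
        if any(len(v) == 0 for v in lists):
            raise ParameterError("grid value lists must be non-empty")
        for i, (g, eta, zeta) in enumerate(itertools.product(*lists)):
            cfg = build_cortex(g=g, zeta=int(zeta), eta=eta, sizes=sizes)
            cfg.coords["grid_index"] = i
            configs.append(cfg)
    else:
        raise TypeError(f"unknown grid type {type(grid)!r}")
    return configs
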