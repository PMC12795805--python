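"""Multi-trial sweeps, regime classification, perturbations, EI-ratio.

Protocol per configuration: simulate 1700 ms trials (wiring frozen across
trials, fresh input/initial-condition streams per trial), analyze the last
1000 ms, and average the oscillation index, aperiodic exponent, fit R^2 and
mean E/I conductances over valid trials.  Trials whose spectral fit fails
to converge or lands below R^2 = 0.5 are excluded from the averages with a
count kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lfp import mean_conductances
from .networks import (
    CortexGrid,
    GPE_PERTURBATION_RATE,
    StnGpeGrid,
    build_cortex,
    enumerate_grid,
)
from .params import NetworkConfig
from .seeds import SeedBundle
from .simulator import NumericError, simulate
from .spectral import analyze_trial

TRIAL_DURATION_MS = 1700.0
DISCARD_MS = 700.0
N_TRIALS_DEFAULT = 25
N_RECORDED = 10
MIN_FIT_R2 = 0.5

OI_LOW_MAX = 0.4
OI_HIGH_MIN = 0.6
GAMMA_HIGH_MIN = 3.0


@dataclass
class StateSummary:
    """Trial-averaged state of one configuration under one condition."""

    coords: dict
    condition: str
    oi_avg: float
    gamma_avg: float
    mean_r2: float
    mean_gex: float  # nS
    mean_gin: float  # nS
    ei_ratio: float
    n_valid_trials: int
    n_trials: int
    oi_sd: float = math.nan
    gamma_sd: float = math.nan
    flagged: bool = False

    def to_row(self) -> dict:
        row = {f"p_{k}": v for k, v in self.coords.items()}
        row.update(
            condition=self.condition,
            oi_avg=self.oi_avg,
            gamma_avg=self.gamma_avg,
            mean_r2=self.mean_r2,
            mean_gex=self.mean_gex,
            mean_gin=self.mean_gin,
            ei_ratio=self.ei_ratio,
            n_valid_trials=self.n_valid_trials,
            n_trials=self.n_trials,
            oi_sd=self.oi_sd,
            gamma_sd=self.gamma_sd,
            flagged=self.flagged,
        )
        return row


def run_configuration(
    config: NetworkConfig,
    n_trials: int = N_TRIALS_DEFAULT,
    seeds: SeedBundle | int = 0,
    condition: str = "baseline",
    duration_ms: float = TRIAL_DURATION_MS,
    discard_ms: float = DISCARD_MS,
    record: int = N_RECORDED,
    **analyze_kwargs,
) -> StateSummary:
    """Simulate ``n_trials`` trials of one configuration and average."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if isinstance(seeds, int):
        seeds = SeedBundle(seeds, config_key=int(config.coords.get("grid_index", 0)))
    ois, gammas, r2s, gexs, gins = [], [], [], [], []
    for trial in range(n_trials):
        sb = seeds.for_trial(trial)
        try:
            sim = simulate(config, duration_ms, sb, record=record)
            res = analyze_trial(sim, discard_ms=discard_ms, **analyze_kwargs)
        except (NumericError, ValueError, RuntimeError):
            continue
        if not res.converged or res.fit_r2 < MIN_FIT_R2:
            continue
        gex, gin = mean_conductances(sim, t_start_ms=discard_ms)
        ois.append(res.oi)
        gammas.append(res.gamma)
        r2s.append(res.fit_r2)
        gexs.append(gex)
        gins.append(gin)
    n_valid = len(ois)
    if n_valid == 0:
        return StateSummary(
            coords=dict(config.coords), condition=condition,
            oi_avg=math.nan, gamma_avg=math.nan, mean_r2=math.nan,
            mean_gex=math.nan, mean_gin=math.nan, ei_ratio=math.nan,
            n_valid_trials=0, n_trials=n_trials, flagged=True,
        )
    mean_gex = float(np.mean(gexs))
    mean_gin = float(np.mean(gins))
    ei = mean_gex / mean_gin if mean_gin > 0 else math.inf
    return StateSummary(
        coords=dict(config.coords),
        condition=condition,
        oi_avg=float(np.mean(ois)),
        gamma_avg=float(np.mean(gammas)),
        mean_r2=float(np.mean(r2s)),
        mean_gex=mean_gex,
        mean_gin=mean_gin,
        ei_ratio=ei,
        n_valid_trials=n_valid,
        n_trials=n_trials,
        oi_sd=float(np.std(ois, ddof=1)) if n_valid > 1 else math.nan,
        gamma_sd=float(np.std(gammas, ddof=1)) if n_valid > 1 else math.nan,
        flagged=not math.isfinite(ei),
    )


def classify_state(s: StateSummary) -> tuple[str, str]:
    """(oscillation regime, exponent regime) from the empirical thresholds.

    Oscillation: low for OI_avg <= 0.4, high for OI_avg > 0.6, intermediate
    in the gap (excluded from regime-conditioned analyses).  Exponent: high
    for gamma_avg >= 3, else low.
    """
    if s.oi_avg <= OI_LOW_MAX:
        osc = "low"
    elif s.oi_avg > OI_HIGH_MIN:
        osc = "high"
    else:
        osc = "intermediate"
    exp_ = "high" if s.gamma_avg >= GAMMA_HIGH_MIN else "low"
    return osc, exp_


@dataclass
class TransitionRecord:
    """Displacement of one configuration's (OI_avg, gamma_avg) state."""

    baseline: StateSummary
    perturbed: StateSummary
    d_oi: float
    d_gamma: float
    angle_deg: float  # [0, 360); NaN when both deltas vanish
    quadrant: str  # e.g. "+OI/+gamma"
    angle_deg_normalized: float = math.nan  # after min-max axis normalization


def transition_angle(base: StateSummary, pert: StateSummary) -> TransitionRecord:
    """Direction of the state change, OI on the abscissa, gamma ordinate.

    A joint increase maps to (0, 90) degrees; rising OI with falling gamma
    to (270, 360).
    """
    if base.coords.get("grid_index") != pert.coords.get("grid_index"):
        raise ValueError("transition requires matching grid coordinates")
    d_oi = pert.oi_avg - base.oi_avg
    d_g = pert.gamma_avg - base.gamma_avg
    if d_oi == 0 and d_g == 0:
        angle = math.nan
    else:
        angle = math.degrees(math.atan2(d_g, d_oi)) % 360.0
    quadrant = f"{'+' if d_oi >= 0 else '-'}OI/{'+' if d_g >= 0 else '-'}gamma"
    return TransitionRecord(base, pert, float(d_oi), float(d_g), angle, quadrant)


def angle_histogram(records: list[TransitionRecord], n_bins: int = 16) -> dict:
    """Radar-plot data: counts of transition directions in 22.5-degree bins."""
    angles = np.array([r.angle_deg for r in records if math.isfinite(r.angle_deg)])
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    counts, _ = np.histogram(angles, bins=edges)
    return {
        "bin_edges_deg": edges.tolist(),
        "counts": counts.tolist(),
        "n_records": int(len(angles)),
        "n_undefined": int(sum(1 for r in records if not math.isfinite(r.angle_deg))),
    }


def normalize_param(x, cohort) -> float:
    """Min-max normalization of ``x`` against its sweep cohort."""
    cohort = np.asarray(cohort, dtype=float)
    lo, hi = cohort.min(), cohort.max()
    if hi <= lo:
        raise ValueError("cohort has no spread; cannot normalize")
    return float((x - lo) / (hi - lo))


def _normalized_angles(records: list[TransitionRecord]) -> None:
    """Recompute angles after min-max normalizing each axis over the cohort.

    Axis scaling changes angles; both the raw and normalized variants are
    reported.
    """
    ois = [r.baseline.oi_avg for r in records] + [r.perturbed.oi_avg for r in records]
    gs = [r.baseline.gamma_avg for r in records] + [r.perturbed.gamma_avg for r in records]
    ois = np.asarray(ois)
    gs = np.asarray(gs)
    span_oi = ois.max() - ois.min() if len(ois) else 0.0
    span_g = gs.max() - gs.min() if len(gs) else 0.0
    for r in records:
        if span_oi <= 0 or span_g <= 0:
            r.angle_deg_normalized = math.nan
            continue
        d_oi = (r.perturbed.oi_avg - r.baseline.oi_avg) / span_oi
        d_g = (r.perturbed.gamma_avg - r.baseline.gamma_avg) / span_g
        if d_oi == 0 and d_g == 0:
            r.angle_deg_normalized = math.nan
        else:
            r.angle_deg_normalized = math.degrees(math.atan2(d_g, d_oi)) % 360.0


@dataclass
class PerturbationResult:
    baseline: list[StateSummary]
    perturbed: list[StateSummary]
    records: list[TransitionRecord]
    histogram: dict
    condition: str


def run_sweep(
    grid,
    n_trials: int = 3,
    master_seed: int = 0,
    sizes: str = "mini",
    condition: str = "baseline",
    configs: list[NetworkConfig] | None = None,
    progress=None,
    **run_kwargs,
) -> list[StateSummary]:
    """Summarize every configuration of a grid under one condition."""
    if configs is None:
        configs = enumerate_grid(grid, sizes=sizes)
    out = []
    for cfg in configs:
        sb = SeedBundle(master_seed, config_key=int(cfg.coords.get("grid_index", 0)))
        out.append(run_configuration(cfg, n_trials=n_trials, seeds=sb, condition=condition, **run_kwargs))
        if progress is not None:
            progress(len(out), len(configs))
    return out


def perturbation_experiment(
    grid,
    baseline: list[StateSummary],
    n_trials: int = 3,
    master_seed: int = 0,
    sizes: str = "mini",
    perturbation=None,
    **run_kwargs,
) -> PerturbationResult:
    """Recompute summaries under the motif's perturbation and pair them.

    STN-GPe grids: add the 600 spikes/s inhibitory drive onto GPe (or
    ``perturbation`` spikes/s).  Cortex grids: raise g from the baseline to
    ``perturbation`` (a single g value, e.g. 8 or 12) at matched (eta, zeta).
    """
    if isinstance(grid, StnGpeGrid):
        rate = GPE_PERTURBATION_RATE if perturbation is None else float(perturbation)
        pert_grid = StnGpeGrid(
            stn_bg=grid.stn_bg, gpe_bg=grid.gpe_bg, stn_gpe_wt=grid.stn_gpe_wt,
            gpe_stn_wt=grid.gpe_stn_wt, perturbation_rate=rate,
        )
        condition = f"inhib_{rate:g}Hz"
        perturbed = run_sweep(
            pert_grid, n_trials=n_trials, master_seed=master_seed, sizes=sizes,
            condition=condition, **run_kwargs,
        )
    elif isinstance(grid, CortexGrid):
        # baselines are the g = 4 configurations; the perturbation raises g
        # at matched (eta, zeta) on the same wiring/input streams
        from .networks import G_BASELINE

        g_new = 8.0 if perturbation is None else float(perturbation)
        condition = f"g_{g_new:g}"
        baseline = [b for b in baseline if float(b.coords.get("g", G_BASELINE)) == G_BASELINE]
        configs = []
        for b in baseline:
            new = build_cortex(
                g=g_new, zeta=int(b.coords["zeta"]), eta=float(b.coords["eta"]), sizes=sizes
            )
            new.coords["grid_index"] = int(b.coords["grid_index"])
            configs.append(new)
        perturbed = run_sweep(
            grid, n_trials=n_trials, master_seed=master_seed, sizes=sizes,
            condition=condition, configs=configs, **run_kwargs,
        )
    else:
        raise TypeError(f"unknown grid type {type(grid)!r}")

    records = []
    for b, p in zip(baseline, perturbed):
        if b.flagged or p.flagged or not (math.isfinite(b.oi_avg) and math.isfinite(p.oi_avg)):
            continue
        records.append(transition_angle(b, p))
    _normalized_angles(records)
    return PerturbationResult(
        baseline=baseline,
        perturbed=perturbed,
        records=records,
        histogram=angle_histogram(records),
        condition=condition,
    )


def summaries_to_frame(summaries: list[StateSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.to_row() for s in summaries])


def records_to_frame(records: list[TransitionRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {f"p_{k}": v for k, v in r.baseline.coords.items()}
        row.update(
            oi_base=r.baseline.oi_avg, gamma_base=r.baseline.gamma_avg,
            oi_pert=r.perturbed.oi_avg, gamma_pert=r.perturbed.gamma_avg,
            d_oi=r.d_oi, d_gamma=r.d_gamma, angle_deg=r.angle_deg,
            angle_deg_normalized=r.angle_deg_normalized, quadrant=r.quadrant,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def ei_ratio_analysis(summaries: list[StateSummary]) -> dict:
    """Scatter table of (EI_ratio, gamma_avg) with per-condition rank stats.

    Summaries with a non-finite ratio (zero inhibitory conductance) are
    flagged and excluded.  Reports Spearman's rho with a Fisher-z 95% CI per
    condition; no sign is asserted.
    """
    rows = []
    for s in summaries:
        if s.flagged or not math.isfinite(s.ei_ratio) or not math.isfinite(s.gamma_avg):
            continue
        rows.append({"condition": s.condition, "ei_ratio": s.ei_ratio, "gamma_avg": s.gamma_avg})
    table = pd.DataFrame(rows)
    correlations = {}
    for cond, grp in table.groupby("condition") if len(table) else []:
        if len(grp) < 3:
            continue
        rho, p = stats.spearmanr(grp["ei_ratio"], grp["gamma_avg"])
        n = len(grp)
        if abs(rho) < 1 and n > 3:
            zr = np.arctanh(rho)
            se = 1.0 / math.sqrt(n - 3)
            ci = (float(np.tanh(zr - 1.96 * se)), float(np.tanh(zr + 1.96 * se)))
        else:
            ci = (math.nan, math.nan)
        correlations[cond] = {"rho": float(rho), "p": float(p), "n": n, "ci95": ci}
    return {"table": table, "correlations": correlations,
            "n_excluded": len(summaries) - len(table)}


def plot_state_space(records: list[TransitionRecord], ax=None):
    """Baseline states as dots and perturbation displacements as arrows in
    the (OI_avg, gamma_avg) plane."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for r in records:
        ax.plot(r.baseline.oi_avg, r.baseline.gamma_avg, "k.", ms=4)
        if math.isfinite(r.angle_deg):
            ax.annotate(
                "", xy=(r.perturbed.oi_avg, r.perturbed.gamma_avg),
                xytext=(r.baseline.oi_avg, r.baseline.gamma_avg),
                arrowprops=dict(arrowstyle="->", color="r", lw=0.8),
            )
    ax.set_xlabel("oscillation index (OI$_{avg}$)")
    ax.set_ylabel(r"aperiodic exponent ($\gamma_{avg}$)")
    return ax
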