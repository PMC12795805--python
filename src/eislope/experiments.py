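"""End-to-end experiment runners: grid -> summaries -> perturbation ->
EI-ratio, with CSV/JSON outputs and a manifest.

Two named experiments mirror the study protocols:

* ``stn-gpe-sweep``: the four-parameter grid at baseline plus the 600
  spikes/s inhibitory GPe drive.
* ``cortex-sweep``: the (g, eta, zeta) grid at baseline g = 4 plus the
  g -> 8 and g -> 12 transition conditions.

Presets: ``mini`` (3 values per STN-GPe axis, populations / 10, 3 trials)
for desk-scale runs, ``full`` (5^4 = 625 configurations, full populations,
25 trials) for the complete protocol.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .manifest import RunManifest, config_hash, package_versions
from .networks import CortexGrid, StnGpeGrid, enumerate_grid
from .sweeps import (
    ei_ratio_analysis,
    perturbation_experiment,
    records_to_frame,
    run_sweep,
    summaries_to_frame,
)

PRESETS = {
    "mini": {"sizes": "mini", "n_trials": 3},
    "full": {"sizes": "full", "n_trials": 25},
}


def _grid_for(name: str, preset: str):
    if name == "stn-gpe-sweep":
        return StnGpeGrid.mini() if preset == "mini" else StnGpeGrid()
    if name == "cortex-sweep":
        return CortexGrid.mini() if preset == "mini" else CortexGrid()
    raise ValueError(f"unknown experiment {name!r}")


def run_experiment(
    name: str,
    preset: str = "mini",
    out_dir="results",
    master_seed: int = 0,
    n_trials: int | None = None,
    perturbations=None,
    progress=None,
    grid=None,
) -> RunManifest:
    """Execute a named experiment and write its CSV/JSON bundle + manifest.

    ``grid`` overrides the preset's sweep grid (the preset still sets
    population sizes and the default trial count).
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    sizes = PRESETS[preset]["sizes"]
    n_trials = n_trials if n_trials is not None else PRESETS[preset]["n_trials"]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if grid is None:
        grid = _grid_for(name, preset)
    configs = enumerate_grid(grid, sizes=sizes)

    manifest = RunManifest(
        experiment=name,
        master_seed=master_seed,
        preset=preset,
        n_trials=n_trials,
        n_configs=len(configs),
        versions=package_versions(),
        seeds={"scheme": "SeedSequence(master, spawn_key=(stream, grid_index, trial, drive))"},
    )
    manifest.config_hashes = [config_hash(c) for c in configs[: min(len(configs), 8)]]

    baseline_csv = out / f"{name}_{preset}_baseline.csv"
    baseline, reused = _resume_or_run(
        baseline_csv, grid, configs, n_trials, master_seed, sizes, "baseline", progress
    )
    if not reused:
        summaries_to_frame(baseline).to_csv(baseline_csv, index=False)
    manifest.outputs["baseline"] = str(baseline_csv)

    if perturbations is None:
        perturbations = [None] if name == "stn-gpe-sweep" else [8.0, 12.0]
    all_summaries = list(baseline)
    for pert in perturbations:
        res = perturbation_experiment(
            grid, baseline, n_trials=n_trials, master_seed=master_seed,
            sizes=sizes, perturbation=pert,
        )
        tag = res.condition
        pert_csv = out / f"{name}_{preset}_{tag}.csv"
        summaries_to_frame(res.perturbed).to_csv(pert_csv, index=False)
        rec_csv = out / f"{name}_{preset}_{tag}_transitions.csv"
        records_to_frame(res.records).to_csv(rec_csv, index=False)
        hist_json = out / f"{name}_{preset}_{tag}_angle_histogram.json"
        with open(hist_json, "w") as fh:
            json.dump(res.histogram, fh, indent=2)
        manifest.outputs[tag] = str(pert_csv)
        manifest.outputs[f"{tag}_transitions"] = str(rec_csv)
        manifest.outputs[f"{tag}_histogram"] = str(hist_json)
        all_summaries += res.perturbed

    ei = ei_ratio_analysis(all_summaries)
    ei_csv = out / f"{name}_{preset}_ei_ratio.csv"
    ei["table"].to_csv(ei_csv, index=False)
    ei_json = out / f"{name}_{preset}_ei_ratio_stats.json"
    with open(ei_json, "w") as fh:
        json.dump({"correlations": ei["correlations"], "n_excluded": ei["n_excluded"]}, fh, indent=2)
    manifest.outputs["ei_ratio"] = str(ei_csv)
    manifest.outputs["ei_ratio_stats"] = str(ei_json)

    manifest.finish()
    manifest.write(out / f"{name}_{preset}_manifest.json")
    return manifest


def _resume_or_run(csv_path, grid, configs, n_trials, master_seed, sizes, condition, progress):
    """Reuse a previously written baseline CSV when it matches the grid.

    A partial or mismatched file is ignored and the sweep recomputed, so an
    interrupted run resumes at worst from the start of the stage.
    """
    if Path(csv_path).exists():
        try:
            prev = pd.read_csv(csv_path)
            if len(prev) == len(configs) and (prev["n_trials"] == n_trials).all():
                from .sweeps import StateSummary

                out = []
                for _, row in prev.iterrows():
                    coords = {k[2:]: row[k] for k in prev.columns if k.startswith("p_")}
                    if "grid_index" in coords:
                        coords["grid_index"] = int(coords["grid_index"])
                    out.append(
                        StateSummary(
                            coords=coords, condition=row["condition"],
                            oi_avg=row["oi_avg"], gamma_avg=row["gamma_avg"],
                            mean_r2=row["mean_r2"], mean_gex=row["mean_gex"],
                            mean_gin=row["mean_gin"], ei_ratio=row["ei_ratio"],
                            n_valid_trials=int(row["n_valid_trials"]),
                            n_trials=int(row["n_trials"]),
                            oi_sd=row["oi_sd"], gamma_sd=row["gamma_sd"],
                            flagged=bool(row["flagged"]),
                        )
                    )
                return out, True
        except Exception:
            pass
    return run_sweep(
        grid, n_trials=n_trials, master_seed=master_seed, sizes=sizes,
        condition=condition, configs=configs, progress=progress,
    ), False
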