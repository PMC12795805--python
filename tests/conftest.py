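"""Shared fixtures.

The two mini-sweep fixtures are session-scoped because several acceptance
checks (fit quality, transition heterogeneity, NMDA slope, EI-ratio) read
different aspects of the same computation.
"""

import pytest
from hypothesis import settings as _hyp_settings

from eislope import (
    CortexGrid,
    SeedBundle,
    StnGpeGrid,
    build_stn_gpe,
    perturbation_experiment,
    run_sweep,
    simulate,
)

MASTER_SEED = 1

_hyp_settings.register_profile("det", derandomize=True, deadline=None)
_hyp_settings.load_profile("det")


@pytest.fixture(scope="session")
def master_seed():
    return MASTER_SEED


@pytest.fixture(scope="session")
def stn_gpe_mini_experiment():
    """Mini STN-GPe protocol: 81 configurations x 3 trials, populations /10,
    baseline plus the 600 spikes/s inhibitory GPe drive."""
    grid = StnGpeGrid.mini()
    baseline = run_sweep(grid, n_trials=3, master_seed=MASTER_SEED, sizes="mini")
    pert = perturbation_experiment(grid, baseline, n_trials=3, master_seed=MASTER_SEED, sizes="mini")
    return {"grid": grid, "baseline": baseline, "perturbation": pert}


@pytest.fixture(scope="session")
def cortex_mini_experiment():
    """Mini neocortical protocol: 27 (g, eta, zeta) configurations x 3
    trials, populations /10, plus the g -> 8 and g -> 12 transitions."""
    grid = CortexGrid.mini()
    baseline = run_sweep(grid, n_trials=3, master_seed=MASTER_SEED, sizes="mini")
    perts = {
        g_new: perturbation_experiment(
            grid, baseline, n_trials=3, master_seed=MASTER_SEED, sizes="mini", perturbation=g_new
        )
        for g_new in (8.0, 12.0)
    }
    return {"grid": grid, "baseline": baseline, "perturbations": perts}


@pytest.fixture(scope="module")
def stn_gpe_trial():
    """One 1700 ms trial of the default mini STN-GPe configuration."""
    cfg = build_stn_gpe(sizes="mini")
    return simulate(cfg, 1700.0, SeedBundle(MASTER_SEED))
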