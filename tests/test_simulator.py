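"""Simulator unit and property tests against analytic oracles."""

import numpy as np
import pytest

from eislope import (
    NetworkConfig,
    NeuronParams,
    ParameterError,
    PoissonDrive,
    Population,
    ReceptorKind,
    SeedBundle,
    alpha_conductance_kernel,
    build_stn_gpe,
    simulate,
    wire_fixed_indegree,
)
from eislope.simulator import NumericError, WiringError, conductance_trace

STN_PARAMS = NeuronParams(
    V_reset=-70.0, V_th=-54.0, V_rest=-70.0, C_m=200.0, g_L=10.0,
    E_ex=0.0, E_in=-80.0, t_ref=5.0,
)
AMPA = ReceptorKind("AMPA", 5.0, 0.0)
GABA = ReceptorKind("GABA", 10.0, -80.0)


def single_pop_config(n=1, drives=(), I_ext=0.0, params=STN_PARAMS):
    return NetworkConfig(
        "single", [Population("P", n, params)], [], list(drives),
        I_ext={"P": I_ext},
    )


class TestAlphaKernel:
    def test_starts_at_zero_and_is_causal(self):
        assert alpha_conductance_kernel(0.0, 5.0, 2.0) == 0.0
        assert alpha_conductance_kernel(-3.0, 5.0, 2.0) == 0.0

    def test_peaks_at_tau_with_gmax_over_e(self):
        tau, gmax = 5.0, 2.0
        assert alpha_conductance_kernel(tau, tau, gmax) == pytest.approx(gmax * np.exp(-1))
        t = np.linspace(0, 50, 5001)
        k = alpha_conductance_kernel(t, tau, gmax)
        assert t[np.argmax(k)] == pytest.approx(tau, abs=0.02)

    def test_rejects_nonpositive_tau(self):
        with pytest.raises(ParameterError):
            alpha_conductance_kernel(1.0, 0.0, 1.0)

    def test_discrete_trace_superposes_exactly(self):
        # two spikes delta apart: engine trace equals the closed-form sum
        tau, gmax, h = 5.0, 2.0, 0.1
        t_spk = [0.0, 3.7]
        g = conductance_trace(t_spk, tau, gmax, duration_ms=200.0, step_ms=h)
        t = np.arange(len(g)) * h
        expected = sum(alpha_conductance_kernel(t - s, tau, gmax) for s in t_spk)
        assert np.max(np.abs(g - expected)) <= 1e-9 * gmax


class TestWiring:
    def test_exact_in_degree_distinct_sources(self):
        rng = np.random.default_rng(0)
        adj = wire_fixed_indegree(2000, 1000, 40, rng)
        assert adj.shape == (1000, 40)
        assert all(len(set(row)) == 40 for row in adj)

    def test_zero_in_degree_empty(self):
        adj = wire_fixed_indegree(100, 10, 0, np.random.default_rng(0))
        assert adj.size == 0

    def test_in_degree_exceeding_sources_raises(self):
        with pytest.raises(WiringError):
            wire_fixed_indegree(10, 5, 11, np.random.default_rng(0))

    def test_self_connections_excluded(self):
        rng = np.random.default_rng(1)
        adj = wire_fixed_indegree(50, 50, 49, rng, self_connections_excluded_offset=0)
        for j in range(50):
            assert j not in adj[j]

    def test_out_degree_mean_matches_binomial_expectation(self):
        n_s, n_t, k = 2000, 1000, 40
        adj = wire_fixed_indegree(n_s, n_t, k, np.random.default_rng(2))
        out_deg = np.bincount(adj.ravel(), minlength=n_s)
        expect = k * n_t / n_s
        sd = np.sqrt(n_t * (k / n_s) * (1 - k / n_s))
        assert abs(out_deg.mean() - expect) <= 3 * sd / np.sqrt(n_s)


class TestSingleNeuronDynamics:
    def test_silent_relaxation_with_membrane_time_constant(self):
        # no drive: V decays to V_rest with tau_m = C_m/g_L = 20 ms
        cfg = single_pop_config(n=5)
        sim = simulate(cfg, 200.0, SeedBundle(3), record=5)
        assert len(sim.spike_times) == 0
        v = sim.V_rec[:, 0] - STN_PARAMS.V_rest
        m = v > 0.2
        slope = np.polyfit(sim.t_rec[m], np.log(v[m]), 1)[0]
        assert -1.0 / slope == pytest.approx(STN_PARAMS.tau_m, rel=0.02)

    def test_firing_rate_matches_closed_form_lif_solution(self):
        I = 250.0  # pA; V_infty = -45 mV, suprathreshold
        p = STN_PARAMS
        drive = I / p.g_L
        isi = p.t_ref + p.tau_m * np.log(
            (drive + p.V_rest - p.V_reset) / (drive + p.V_rest - p.V_th)
        )
        cfg = single_pop_config(I_ext=I)
        sim = simulate(cfg, 10_000.0, SeedBundle(4), record=1)
        rate = len(sim.spike_times) / 10.0
        assert rate == pytest.approx(1000.0 / isi, rel=0.01)

    def test_step_halving_shifts_spike_times_less_than_point2_ms(self):
        cfg = single_pop_config(I_ext=250.0)
        t1 = simulate(cfg, 200.0, SeedBundle(5), record=1, step=0.1).spike_times
        t2 = simulate(cfg, 200.0, SeedBundle(5), record=1, step=0.05).spike_times
        assert len(t1) == len(t2)
        assert np.max(np.abs(t1 - t2)) < 0.2

    @pytest.mark.parametrize("other,tol", [("rk4", 0.1), ("euler", 1.0)])
    def test_integration_schemes_agree(self, other, tol):
        # rk4 matches the exponential update closely; forward Euler drifts
        # first-order in the step but stays within one step per spike
        cfg = single_pop_config(I_ext=250.0)
        te = simulate(cfg, 200.0, SeedBundle(5), record=1, method="exp").spike_times
        to = simulate(cfg, 200.0, SeedBundle(5), record=1, method=other).spike_times
        assert len(te) == len(to)
        assert np.max(np.abs(te - to)) < tol

    def test_rate_monotone_in_excitatory_drive(self):
        rates_in = [500.0, 1000.0, 2000.0, 4000.0, 8000.0]
        means = []
        for r in rates_in:
            cfg = single_pop_config(drives=[PoissonDrive("P", r, 1.5, AMPA)])
            out = [
                len(simulate(cfg, 2000.0, SeedBundle(10 + s), record=1).spike_times) / 2.0
                for s in range(5)
            ]
            means.append(np.mean(out))
        assert all(b >= a - 1e-9 for a, b in zip(means, means[1:]))

    def test_campbell_mean_conductance(self):
        # time-averaged G -> rate * g_max * tau (integral of the alpha kernel)
        rate, gmax, tau = 800.0, 1.0, 5.0
        cfg = single_pop_config(drives=[PoissonDrive("P", rate, gmax, AMPA)])
        sim = simulate(cfg, 10_000.0, SeedBundle(6), record=1)
        mean_g = sim.Gex_rec[sim.t_rec > 200.0].mean()
        assert mean_g == pytest.approx(rate * gmax * tau / 1000.0, rel=0.05)

    def test_unstable_integration_raises_numeric_error(self):
        cfg = single_pop_config(I_ext=-50_000.0)
        with pytest.raises(NumericError):
            simulate(cfg, 100.0, SeedBundle(7), record=1)


class TestNetworkContracts:
    def test_identical_seed_bundle_gives_bit_identical_raster(self):
        cfg = build_stn_gpe(sizes="mini")
        a = simulate(cfg, 400.0, SeedBundle(8))
        b = simulate(cfg, 400.0, SeedBundle(8))
        assert np.array_equal(a.spike_times, b.spike_times)
        assert np.array_equal(a.spike_ids, b.spike_ids)
        assert np.array_equal(a.V_rec, b.V_rec)

    def test_different_trial_streams_change_activity(self):
        cfg = build_stn_gpe(sizes="mini")
        a = simulate(cfg, 400.0, SeedBundle(8, trial=0))
        b = simulate(cfg, 400.0, SeedBundle(8, trial=1))
        assert not np.array_equal(a.spike_times, b.spike_times)

    def test_refractoriness_and_conductance_positivity(self, stn_gpe_trial):
        assert stn_gpe_trial.min_isi() >= STN_PARAMS.t_ref
        assert np.all(stn_gpe_trial.Gex_rec >= 0)
        assert np.all(stn_gpe_trial.Gin_rec >= 0)

    def test_raster_round_trip(self, stn_gpe_trial, tmp_path):
        from eislope.simulator import read_raster

        path = tmp_path / "raster.txt"
        stn_gpe_trial.write_raster(path)
        t, i = read_raster(path)
        assert np.allclose(t, stn_gpe_trial.spike_times, atol=1e-4)
        assert np.array_equal(i, stn_gpe_trial.spike_ids)

    def test_conductance_csv_round_trip(self, stn_gpe_trial, tmp_path):
        path = tmp_path / "g.csv"
        stn_gpe_trial.write_conductances(path)
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        assert arr.shape == (len(stn_gpe_trial.t_rec), 1 + 2 * len(stn_gpe_trial.record_ids))
        assert np.allclose(arr[:, 1], stn_gpe_trial.Gex_rec[:, 0], atol=1e-5)
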