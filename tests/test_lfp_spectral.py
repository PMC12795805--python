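"""LFP proxy and spectral statistics against hand-computed oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eislope import (
    LfpTrace,
    NetworkConfig,
    NeuronParams,
    Population,
    SeedBundle,
    SurrogatePeak,
    SurrogateSpec,
    analyze_trial,
    build_stn_gpe,
    fit_aperiodic,
    generate_powerlaw_signal,
    make_lfp,
    oscillation_index,
    simulate,
    welch_psd,
)
from eislope.params import PoissonDrive, ReceptorKind
from eislope.simulator import SimResult
from eislope.spectral import SpectralModel


def _fake_sim(V, Gex, Gin, n_rec=1):
    """Minimal SimResult with constant recorded traces."""
    params = NeuronParams(V_reset=-70, V_th=-54, V_rest=-70, C_m=200, g_L=10,
                          E_ex=0.0, E_in=-80.0, t_ref=5.0)
    cfg = NetworkConfig("fake", [Population("P", max(n_rec, 1), params)], [], [])
    n = 1000
    ones = np.ones((n, n_rec))
    return SimResult(
        config=cfg, step=0.1, duration=1000.0,
        spike_times=np.empty(0), spike_ids=np.empty(0, dtype=int),
        t_rec=np.arange(n, dtype=float), record_ids=np.arange(n_rec),
        V_rec=V * ones, Gex_rec=Gex * ones, Gin_rec=Gin * ones,
        seeds=SeedBundle(0),
    )


class TestMakeLfp:
    def test_zero_conductances_give_zero_lfp(self):
        lfp = make_lfp(_fake_sim(V=-60.0, Gex=0.0, Gin=0.0))
        assert np.all(lfp.samples == 0)

    def test_constant_case_matches_hand_computation(self):
        # one neuron, V=-60 mV, G_ex=1 nS, G_in=0: I = G_ex (V - E_ex) = -60 pA
        lfp = make_lfp(_fake_sim(V=-60.0, Gex=1.0, Gin=0.0))
        assert np.allclose(lfp.samples, -60.0)
        rect = make_lfp(_fake_sim(V=-60.0, Gex=1.0, Gin=0.0), mode="rectified")
        assert np.allclose(rect.samples, 60.0)

    def test_unrecorded_neurons_rejected(self):
        with pytest.raises(ValueError):
            make_lfp(_fake_sim(-60.0, 1.0, 0.0), neuron_ids=[5])

    def test_ten_neurons_carry_population_spectrum(self):
        # homogeneity: the exponent from 10 recorded neurons agrees with the
        # whole mini STN population on trial-averaged spectra.  The residual
        # gap (~0.3 here) is a scale effect: correlated inhibitory currents
        # gain relative weight as more neurons are summed.
        cfg = build_stn_gpe(sizes="mini")
        n_stn = cfg.population("STN").n
        acc = {10: [], n_stn: []}
        for trial in range(5):
            sim = simulate(cfg, 1700.0, SeedBundle(1, trial=trial), record=n_stn)
            for n_sum in acc:
                trace = make_lfp(sim, neuron_ids=np.arange(n_sum))
                trace.samples = trace.samples[700:]
                f, p = welch_psd(trace)
                acc[n_sum].append(p)
        g_ten = fit_aperiodic(f, np.mean(acc[10], axis=0)).exponent
        g_all = fit_aperiodic(f, np.mean(acc[n_stn], axis=0)).exponent
        assert abs(g_all - g_ten) < 0.5


class TestWelch:
    def test_sine_peak_lands_in_nearest_bin(self):
        rng = np.random.default_rng(0)
        t = np.arange(10_000) / 1000.0
        x = np.sin(2 * np.pi * 20.0 * t) + 1e-3 * rng.standard_normal(len(t))
        f, p = welch_psd(x)
        assert abs(f[np.argmax(p)] - 20.0) <= 1000.0 / 256 / 2
        assert f[1] - f[0] == pytest.approx(1000.0 / 256)

    def test_white_noise_flat_within_3db(self):
        x = np.random.default_rng(1).standard_normal(20_000)
        f, p = welch_psd(x)
        band = p[(f >= 5) & (f <= 150)]
        assert 10 * np.log10(band.max() / band.min()) < 6.0  # +-3 dB about the mean

    def test_total_power_matches_variance(self):
        x = np.random.default_rng(2).standard_normal(50_000)
        f, p = welch_psd(x)
        assert np.sum(p) * (f[1] - f[0]) == pytest.approx(np.var(x), rel=0.05)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            welch_psd(np.zeros(100))


class TestOscillationIndex:
    def test_uniform_spectrum_gives_zero(self):
        f = np.arange(64) * 3.90625
        assert oscillation_index(f, np.ones(64)) == pytest.approx(0.0, abs=1e-12)

    def test_single_bin_gives_one(self):
        f = np.arange(64) * 3.90625
        p = np.zeros(64)
        p[20] = 5.0
        assert oscillation_index(f, p) == pytest.approx(1.0)

    def test_half_half_distribution_gives_half(self):
        # P = [0.5, 0.5, 0, 0] over N=4 bins: H_s = 0.5, OI = 0.5
        f = np.array([10.0, 20.0, 30.0, 40.0])
        p = np.array([0.5, 0.5, 0.0, 0.0])
        assert oscillation_index(f, p, band=(5, 45)) == pytest.approx(0.5)

    def test_zero_power_and_negative_power_rejected(self):
        f = np.arange(64) * 3.90625
        with pytest.raises(ValueError):
            oscillation_index(f, np.zeros(64))
        with pytest.raises(ValueError):
            oscillation_index(f, -np.ones(64))

    def test_band_needs_two_bins(self):
        with pytest.raises(ValueError):
            oscillation_index(np.array([10.0, 200.0]), np.ones(2), band=(5, 15))

    @given(st.lists(st.floats(min_value=0.0, max_value=1e6), min_size=4, max_size=128))
    @settings(max_examples=200, deadline=None)
    def test_bounded_in_unit_interval_for_any_spectrum(self, psd):
        psd = np.asarray(psd)
        f = np.linspace(5, 150, len(psd))
        if psd.sum() <= 0:
            with pytest.raises(ValueError):
                oscillation_index(f, psd)
        else:
            oi = oscillation_index(f, psd)
            assert -1e-9 <= oi <= 1.0 + 1e-9

    @given(
        st.lists(st.floats(min_value=1e-3, max_value=1e3), min_size=4, max_size=64),
        st.floats(min_value=1e-3, max_value=1e3),
    )
    @settings(max_examples=200, deadline=None)
    def test_adding_power_to_dominant_bin_never_decreases_oi(self, psd, extra):
        psd = np.asarray(psd)
        f = np.linspace(5, 150, len(psd))
        before = oscillation_index(f, psd)
        boosted = psd.copy()
        boosted[np.argmax(psd)] += extra
        after = oscillation_index(f, boosted)
        assert after >= before - 1e-9


class TestAperiodicFit:
    def test_exact_power_law_recovered(self):
        f = np.arange(256 // 2 + 1) * (1000.0 / 256)
        psd = np.zeros_like(f)
        psd[1:] = 10.0 / f[1:] ** 2
        fit = fit_aperiodic(f, psd)
        assert fit.exponent == pytest.approx(2.0, abs=0.01)
        assert len(fit.peaks) == 0
        assert fit.r_squared > 0.999

    def test_white_noise_exponent_near_zero(self):
        x = np.random.default_rng(3).standard_normal(30_000)
        f, p = welch_psd(x)
        fit = fit_aperiodic(f, p)
        assert abs(fit.exponent) < 0.1

    def test_exponent_recovered_despite_in_band_peak(self):
        spec = SurrogateSpec(gamma=3.0, peaks=(SurrogatePeak(80.0, 1.0, 4.0),),
                             duration_ms=10_000, seed=7)
        f, p = welch_psd(generate_powerlaw_signal(spec))
        fit = fit_aperiodic(f, p)
        assert fit.exponent == pytest.approx(3.0, abs=0.2)
        assert any(60 < pk.center < 100 for pk in fit.peaks)

    def test_summary_reports_estimates(self):
        f = np.arange(129) * (1000.0 / 256)
        psd = np.zeros_like(f)
        psd[1:] = 1.0 / f[1:] ** 3
        fit = SpectralModel(f, psd).fit()
        text = fit.summary()
        assert "exponent" in text and "R^2" in text

    def test_too_few_bins_rejected(self):
        f = np.array([50.0, 60.0, 70.0, 80.0])
        with pytest.raises(ValueError):
            SpectralModel(f, np.ones(4))


class TestAnalyzeTrial:
    def test_silent_network_raises_on_zero_power(self):
        params = NeuronParams(V_reset=-70, V_th=-54, V_rest=-70, C_m=200, g_L=10,
                              E_ex=0.0, E_in=-80.0, t_ref=5.0)
        cfg = NetworkConfig("silent", [Population("P", 10, params)], [], [])
        sim = simulate(cfg, 1700.0, SeedBundle(0))
        with pytest.raises(ValueError):
            analyze_trial(sim)

    def test_same_trial_analyzed_twice_is_identical(self, stn_gpe_trial):
        a = analyze_trial(stn_gpe_trial)
        b = analyze_trial(stn_gpe_trial)
        assert a.oi == b.oi and a.gamma == b.gamma and a.fit_r2 == b.fit_r2
        assert np.array_equal(a.psd, b.psd)

    def test_campbell_limit_unconnected_population_slope_near_four(self):
        # Poisson-driven, unconnected neurons: the LFP inherits the squared
        # alpha-kernel transfer, whose high-frequency log-log slope is 4
        params = NeuronParams(V_reset=-70, V_th=-54, V_rest=-70, C_m=200, g_L=10,
                              E_ex=0.0, E_in=-80.0, t_ref=5.0)
        ampa = ReceptorKind("AMPA", 5.0, 0.0)
        gaba = ReceptorKind("GABA", 10.0, -80.0)
        cfg = NetworkConfig(
            "shot", [Population("P", 5, params)], [],
            [PoissonDrive("P", 400.0, 1.0, ampa), PoissonDrive("P", 400.0, 1.0, gaba)],
        )
        sim = simulate(cfg, 10_000.0, SeedBundle(11), record=5)
        res = analyze_trial(sim, discard_ms=200.0, fit_band=(100.0, 150.0))
        assert 3.2 <= res.gamma <= 4.5
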