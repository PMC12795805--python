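"""Ground-truth surrogate signals for the spectral pipeline.

Two generators:

* :func:`generate_powerlaw_signal` — inverse-FFT spectral synthesis of a
  1 kHz signal whose PSD is exactly 1/f^gamma times optional Gaussian
  bumps in log-power (oscillatory peaks), with uniformly random phases.
  The target exponent is bit-defined, which makes these traces the
  round-trip oracle for the aperiodic-exponent estimator.
* :func:`generate_shot_noise` — a Poisson spike train convolved with the
  alpha conductance kernel, the textbook Campbell-theorem process: its mean
  is rate * g_max * tau and its PSD follows |K(f)|^2 with a high-frequency
  log-log slope of 4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._engine import alpha_train
from .lfp import LfpTrace
from .params import ParameterError


@dataclass(frozen=True)
class SurrogatePeak:
    center_hz: float
    height: float  # log10(power) units
    width_hz: float  # Gaussian SD


@dataclass(frozen=True)
class SurrogateSpec:
    gamma: float
    peaks: tuple = field(default_factory=tuple)  # of SurrogatePeak
    duration_ms: float = 10_000.0
    fs: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ParameterError("target exponent must be non-negative")
        if self.duration_ms < 1024:
            raise ParameterError("surrogate duration must be at least 1024 ms")
        for pk in self.peaks:
            if pk.center_hz >= self.fs / 2:
                raise ParameterError("peak center must lie below Nyquist")


def generate_powerlaw_signal(spec: SurrogateSpec) -> LfpTrace:
    """Synthesize a signal with PSD proportional to 1/f^gamma plus peaks."""
    n = int(round(spec.duration_ms * spec.fs / 1000.0))
    freqs = np.fft.rfftfreq(n, d=1.0 / spec.fs)
    log_power = np.zeros_like(freqs)
    pos = freqs > 0
    log_power[pos] = -spec.gamma * np.log10(freqs[pos])
    for pk in spec.peaks:
        log_power += pk.height * np.exp(-((freqs - pk.center_hz) ** 2) / (2.0 * pk.width_hz**2))
    amplitude = np.sqrt(10.0**log_power)
    amplitude[0] = 0.0  # zero mean
    rng = np.random.default_rng(spec.seed)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(freqs))
    spectrum = amplitude * np.exp(1j * phases)
    # keep the Nyquist bin real for even n
    if n % 2 == 0:
        spectrum[-1] = amplitude[-1]
    x = np.fft.irfft(spectrum, n=n)
    x = x / np.std(x)
    return LfpTrace(samples=x, fs=spec.fs, n_contributing_neurons=0)


def generate_shot_noise(
    rate: float,
    tau_syn: float,
    g_max: float,
    duration_ms: float,
    seed: int = 0,
    step_ms: float = 0.1,
    fs_out: float = 1000.0,
) -> np.ndarray:
    """Poisson spike train through an alpha synapse, sampled at ``fs_out``.

    ``rate`` in spikes/s; returns the conductance trace in nS.  Uses the
    engine's exact two-state update, so superposition over spikes is exact.
    """
    if rate < 0:
        raise ParameterError("rate must be non-negative")
    n_steps = int(round(duration_ms / step_ms))
    rng = np.random.default_rng(seed)
    counts = rng.poisson(rate * step_ms / 1000.0, size=n_steps)
    idx = np.repeat(np.arange(n_steps), counts)
    amps = np.full(idx.size, g_max / tau_syn)
    g = alpha_train(idx.astype(np.int64), amps, n_steps, step_ms, tau_syn)
    every = int(round(1000.0 / (fs_out * step_ms)))
    return g[::every]
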