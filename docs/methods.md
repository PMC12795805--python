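# Methods

## Scope

`eislope` asks a single question with simulations: does the aperiodic
("1/f") exponent of a population-activity spectrum track the
excitation–inhibition (EI) balance of the network that generated it?  It
implements two conductance-based leaky integrate-and-fire (LIF) network
motifs — the STN–GPe loop of the basal ganglia (excitatory–inhibitory,
no E–E recurrence) and a neocortex-like random network (full E/I
recurrence) — an LFP proxy built from summed synaptic currents, an
entropy-based oscillation index, a spectral-parameterization estimator of
the aperiodic exponent, perturbation experiments, and an EI-conductance-
ratio analysis.

## Neuron and synapse model

Membrane:  C_m dV/dt = −g_L (V − V_rest) + Σ_c G_c(t) (E_c − V) + I_ext,
with threshold V_th, reset V_reset, and absolute refractory period t_ref
during which V is clamped at V_reset while synaptic conductances continue
to evolve.

Each presynaptic spike elicits an alpha conductance
G(t) = g_max (t/τ) e^(−t/τ) on the receptor channel it targets.  Channels
are distinguished only by time constant and reversal potential:

| motif   | channel | τ (ms) | E_rev (mV) |
|---------|---------|--------|------------|
| STN–GPe | AMPA    | 5      | 0          |
| STN–GPe | GABA    | 10     | −80        |
| cortex  | AMPA    | 3      | −10        |
| cortex  | NMDA    | 30     | −10        |
| cortex  | GABA    | 5      | −84        |

Membrane constants: STN/GPe — V_reset −70, V_th −54, C_m 200 pF, g_L 10 nS,
t_ref 5 ms; cortex (E and I) — V_reset −65, V_th −54, E_L −70, C_m 60 pF,
g_L 12 nS, t_ref 2 ms.  Two printed values deserve comment:

* The STN/GPe resting potential is not part of the published constants;
  it is set to −70 mV (equal to V_reset and to the neocortical leak
  reversal) and is config-exposed.
* The neocortical excitatory reversal of −10 mV is implemented as printed.
  It sits above threshold, so the channel is genuinely excitatory, but it
  is probably a typo for 0 mV; `build_cortex(e_ex=0.0)` switches it.

No Mg²⁺ block is modeled on NMDA: with point neurons held near threshold
by the background, the block would be largely relieved anyway.  AMPA,
NMDA and GABA are hosted as three conductance channels on a single
compartment; the original receptor-per-compartment construction is not
reproducible because the compartment coupling constants are unpublished
(see Limitations).

## Connectivity

Wiring has fixed in-degree: every target neuron draws its presynaptic
partners uniformly without replacement (self-connections excluded), so the
out-degree is binomial-like.  Pathways:

* STN–GPe: STN→GPe (AMPA, in-degree 20, delay 5 ms), GPe→STN (GABA, 40,
  5 ms), GPe→GPe (GABA, 40, 2 ms).  Default weights 1.5 / 1.3 / 0.725 nS.
* Cortex: every neuron receives 800 excitatory afferents, split ζ NMDA /
  (800−ζ) AMPA (E→E 0.15/0.13 nS, E→I 0.16/0.14 nS, delay 2 ms), plus
  200 GABA afferents (I→E 0.547 nS, delay 2 ms; I→I 0.3 nS, per-connection
  delay uniform in 1–5 ms).  The inhibition ratio g rescales the printed
  inhibitory weights by g/4; the printed column is the g = 4 baseline.

Population sizes are not published.  Full-scale defaults: N_STN = 1000,
N_GPe = 2000; cortex N_E = 8000, N_I = 2000 (so the printed in-degrees
correspond to a 10% connection fraction).  The desk-scale `mini` preset
divides populations by 10 with in-degrees preserved; the single place this
collides is the all-AMPA cortex (ζ = 0), where an 800-neuron E population
cannot supply 800 non-self partners — the in-degree is clipped to 799
(one synapse in 800).

## Background drive

Each neuron receives its own independent Poisson spike train (inputs are
uncorrelated and asynchronous by construction).  Background weights are
not published and are the model's calibration knobs:

* STN–GPe: excitatory background at the printed grid rates
  (1700–2100 s⁻¹ to STN, 800–1400 s⁻¹ to GPe) with weight 1.5 nS (the
  excitatory recurrent weight).  This puts the default network at
  STN ≈ 21 s⁻¹ and GPe ≈ 53 s⁻¹, in-vivo-like rates for the loop.  The
  600 s⁻¹ inhibitory perturbation onto GPe reuses the GPe→GPe weight.
* Cortex: the background is glutamatergic, and receptor composition is a
  property of the postsynaptic neuron, so external events split across
  NMDA and AMPA in the same ζ : (800−ζ) proportion as recurrent synapses.
  Drive level is expressed as η, a multiple of ν_thr — the aggregate rate
  whose Campbell-theorem mean conductance holds an isolated neuron exactly
  at threshold (ν_thr = g_L(V_th−E_L)/((E_ex−V_th)·w_bg·τ_mix)).  The
  background weight of 1.5 nS was calibrated once so that the base state
  (g = 4, ζ = 400) reaches the target pyramidal rate of ≈ 0.68 s⁻¹ inside
  the η search range; with the recurrent-sized weight of 0.13 nS the
  inhibitory population tracks the drive and clamps E at ≈ 0.25 s⁻¹ for
  every η, making the documented operating point unreachable.
* The η sweep spans 0.8–2.4 (mini grid {0.8, 1.6, 2.4}), from just below
  the calibrated base state into the strongly driven, oscillation-prone
  regime.

The base-state calibration itself (`calibrate_cortex_background`) bisects
η against the measured E rate — orientation detected from the bracket
endpoints, because in the inhibition-dominated regime the E rate
*decreases* with drive — and then measures the rate over five full
1700 ms trials.

## Integration

Fixed step of 0.1 ms.  The alpha synapse is advanced by the exact
propagator of its two-state linear system, so superposition over spikes is
exact to machine precision; spikes arrive as impulses on the step grid.
The membrane uses an exponential update (exact when conductances are
frozen across one step); forward Euler and RK4 (with conductances
evaluated analytically at substeps) are selectable.  Threshold crossings
are located by linear interpolation inside the step and the sub-step
residual is carried as a time credit into the first post-refractory step,
so the spike-phase error stays bounded by one step instead of
accumulating: halving the step moves single-neuron spike times by less
than 0.2 ms over a 200 ms test.  A voltage excursion beyond
[min E_rev − 5 mV, max E_rev + 5 mV] raises a numeric error naming the
neuron and time; such trials are excluded from sweep averages with a
count.

Initial conditions: V uniform in [V_reset, V_th) per neuron; conductances
zero; the first 700 ms of every 1700 ms trial are discarded as transient.

## Seeds

A single master seed fans out through `numpy.random.SeedSequence` spawn
keys into named streams: one wiring stream per configuration (frozen
across trials, so the 25-trial — desk scale: 3-trial — average isolates
input variability), and per-trial streams for initial conditions and each
Poisson drive.  Every pipeline stage is byte-reproducible from the master
seed; the manifest records the scheme.

## LFP proxy and spectral statistics

Excitatory and inhibitory conductances and V_m of 10 excitatory neurons
are recorded at 1 kHz.  The LFP proxy is the sum over those neurons of the
signed synaptic currents G_ex(V−E_ex) + G_in(V−E_in); a rectified variant
(Σ|I_ex|+|I_in|) exists because the conductance-to-current conversion is
underdetermined.  Ten neurons suffice in a homogeneous network, though at
mini scale summing all neurons shifts the fitted exponent by ≈ 0.3–0.45
(correlated recurrent currents gain weight relative to the uncorrelated
background as more neurons are summed) — the unit test allows 0.5.

* **PSD**: Welch with Hann window, 256-sample segments, 50% overlap
  (3.906 Hz bins at 1 kHz).
* **Oscillation index**: OI = 1 − H_s with H_s the Shannon entropy of the
  unit-sum PSD over the band, normalized by log₂N; 0 for a flat spectrum,
  1 for a single bin.  The OI band is not published; default 5–150 Hz,
  config-exposed.
* **Aperiodic exponent**: the PSD is parameterized as a power law plus
  Gaussian peaks in log₁₀ space, FOOOF-style and authored in-package:
  robust initial aperiodic fit (refit on the lowest 2.5% of positive
  residuals), iterative peak extraction (stop below max(2 SD of the
  flattened spectrum, 0.01 log-units)), simultaneous Gaussian refit with
  scipy `curve_fit` (SD bounds = width limits/2 = [0.25, 6] Hz), aperiodic
  refit on the peak-removed spectrum, R² = squared Pearson correlation of
  log-PSD and full model.  Settings: ≤ 16 peaks, widths [0.5, 12] Hz,
  aperiodic mode fixed (no knee), band 50–150 Hz (the lower bound avoids
  low-frequency network oscillations, the upper the spectral plateau); the
  5–150 Hz variant is one argument away.  Trials whose fit fails to
  converge or lands below R² = 0.5 are excluded from configuration
  averages, with counts kept.

## Sweeps, classification, transitions

A configuration summary averages OI, γ, R², and mean E/I conductances
over trials (full protocol 25, mini 3).  Regimes: low oscillation
OI ≤ 0.4, high > 0.6, intermediate in the gap (excluded from
regime-conditioned statistics, kept in totals); high exponent γ ≥ 3.

Perturbations: STN–GPe adds the 600 s⁻¹ inhibitory drive onto GPe;
cortex raises g from 4 to 8 or 12 at matched (η, ζ) on the same wiring
and input streams.  A transition's direction is atan2(Δγ, ΔOI) in
[0°, 360°) with ΔOI on the abscissa; since axis scaling changes angles, a
min-max-normalized variant is reported alongside.  The radar histogram
uses 16 bins of 22.5°.  EI balance is operationalized as
mean G_ex / mean G_in of the recorded neurons; the EI-ratio analysis
reports Spearman's ρ per condition with a Fisher-z 95% CI and asserts no
sign.

## Synthetic-data generator

`surrogate` is the ground-truth harness for the spectral pipeline.
Power-law traces are synthesized by inverse FFT with amplitude ∝ f^(−γ/2),
uniform random phases, and Gaussian bumps added in log-power for
oscillatory peaks — the target PSD is bit-defined, unlike an AR
approximation.  Shot-noise conductances convolve a Poisson train with the
alpha kernel via the engine's exact update; Campbell's theorem fixes their
mean (rate·g_max·τ) and their high-frequency log-log slope approaches 4
(the squared alpha-kernel transfer).  What the surrogates do *not* emulate:
non-Gaussian phase statistics, non-stationarity, and the correlated,
oscillation-contaminated currents of a recurrent network — passing the
round-trip tests certifies the estimator, not the network model.

## Problem sizes

The desk-scale defaults used throughout the test suite and the
reproduction script: mini populations (N/10), 81 STN-GPe configurations ×
3 trials, 27 cortex configurations × 3 trials, 1700 ms per trial with the
last 1000 ms analyzed.  The full protocol (625 configurations × 25 trials,
full populations) is the `full` preset of the same entry points.

## Known limitations

* **NMDA fraction and the exponent.**  In the 50–150 Hz fit band the NMDA
  alpha kernel (τ = 30 ms) is attenuated ~50× more than AMPA's, so the
  direct "slower synapses → steeper spectrum" mechanism contributes ~2% of
  the in-band fluctuation power and is numerically invisible; what remains
  is a network-dynamical effect whose sign varies across (g, η) cells at
  desk scale.  The mini cortex sweep therefore does not reliably show a
  γ increase from ζ = 0 to ζ = 500; a receptor-per-dendritic-compartment
  implementation (extra membrane low-pass in series with NMDA) would be
  required to recover a robust composition effect.
* Single-frequency oscillations: like other homogeneous LIF networks,
  both motifs tend to oscillate at one dominant frequency, so spectra are
  less rich than biological LFP.
* The mini preset preserves in-degrees, not connection fractions; shared-
  input correlations are therefore ~10× stronger than at full scale, which
  inflates oscillation indices and the 10-vs-all LFP gap.
* Synaptic delays are fixed at their printed values; delay sweeps change
  the loop resonances and are out of scope.
* No plasticity, no heterogeneity, no morphology.
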