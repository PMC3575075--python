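# Methods

## Neuron and synapse model

All networks use conductance-based leaky integrate-and-fire point neurons,

C_m dV_m/dt = −g_l (V_m − E_l) − Σ_i g_i(t) (V_m − E_i),   E_i ∈ {E_exc, E_inh},

with a hard threshold V_th, reset to V_reset, and an absolute refractory
period τ_refrac during which V_m is clamped to V_reset.  Each synaptic
conductance is g_i(t) = p_i(t)·w_i·g_i^max, where p_i jumps instantaneously
at a presynaptic spike (the rise time is treated as zero) and decays
exponentially with the driver's τ_fall.  Synaptic input is organized around
*line drivers*: one driver per presynaptic axon carrying the sign, peak
conductance g^max, decay constant, and optional short-term-plasticity mode;
individual synapses contribute only a weight w ∈ [0, 1] on that driver's
waveform.  This mirrors how row-driver/synapse-matrix chips are built and
is what makes 4-bit weight quantization and per-axon STP natural.

Short-term plasticity follows the Tsodyks–Markram picture.  Depressing
drivers release a fraction U_SE of a recovering resource,
η_k = R_k·U_SE with R_{k+1} = 1 − (1 − R_k(1−U_SE))·exp(−Δt/τ_rec), R_1 = 1;
facilitating drivers accumulate utilization that jumps by U_SE(1−u) per
spike and decays to zero with τ_facil.  Both give first-spike efficacy
U_SE.  The saturating transconductance nonlinearity of real analog STP
circuits is not modelled.

### Integration

Exponential Euler with conductances held constant across one step: each
step relaxes V toward the instantaneous equilibrium potential with the
instantaneous effective time constant C_m/g_tot.  This is exact for pure
leak and unconditionally stable in high-conductance states.  Default
dt = 0.1 ms (biological time).  Threshold crossings are detected at step
end and time-stamped there; with a zero-conductance test the integrator
matches the analytic exponential relaxation to better than 10⁻⁶ relative
error, and the free-running period of a calibrated neuron is exact to the
step quantization (<1%).  Spikes propagate through their driver with a
single fixed axonal delay (default 1.0 ms); external stimulus events use
the same delay.  Simulations are bit-reproducible given (network, stimuli,
seed, dt): the run seed only feeds the optional membrane noise.

## Substrate constraints and imperfections

The substrate layer maps an ideal network onto chip-like constraints:

* resource limits — at most 384 neurons, 256 drivers (≤192 of them fed by
  on-chip neurons), fan-in ≤256 synapses per neuron;
* 4-bit weights — each w is snapped to the nearest of 16 equidistant
  levels in [0, 1], ties rounding up;
* shared voltage parameters — within blocks of 96 neurons the voltage
  parameters (E_l, E_exc, E_inh, V_th, V_reset) are coerced to the block
  value; g_l, τ_refrac and the weights stay individual;
* fixed-pattern noise — static per-unit scatter frozen by a chip seed:
  lognormal factors on per-neuron g_l and per-driver g^max (lognormal for
  positivity), Gaussian shifts on V_th (Gaussian for symmetry);
* trial-to-trial noise — a white-noise voltage term of configurable
  amplitude (mV/√ms) drawn from the run seed.

The leak scatter has a deliberate systematic component: with the default
median factor 0.662 and CV 0.48, an uncalibrated population targeted at
τ_m = 10 ms shows a τ_m distribution with median ≈15 ms and 20th/80th
percentiles ≈10.3/22.1 ms, emulating the uncalibrated state of a typical
analog chip.  Both constants live in `NoiseModel`, not in code.  Driver
and threshold scatter amplitudes (CV 0.2, 2 mV) are estimates and equally
configurable.  With all noise amplitudes zero, the substrate path equals
the ideal path with quantized weights exactly — this identity is tested.

## Calibration

`calibrate_tau_m` uses the 1/e protocol: setting
V_th = E_l − (E_l − V_reset)/e makes a free-running neuron spike with
period τ_m + τ_refrac, so τ_m is read off a spike count and corrected
multiplicatively through g_l (steps clamped to ×[0.5, 2]).  The
measurement window defaults to 10 s biological time (estimator variance vs
runtime); neurons silent after one window doubling, or unconverged after
`max_iter` sweeps, are flagged rather than kept.  Networks whose V_reset
coincides with E_l get a 10 mV probe reset — the inferred τ_m does not
depend on the reset depth.  On the emulated uncalibrated chip this
calibration shrinks the 20–80 percentile width from ≈11 ms to below the
measurement resolution and centres the median on the target.

`calibrate_drivers` equalizes line drivers one at a time against a probe
population (every neuron listens to the driver at weight 1, driven by a
Poisson train), bisecting g^max on a log grid until the population rate
hits the 10 Hz target ±10%; inhibitory drivers are probed against a
pre-calibrated excitatory background.  The requested inhibition/excitation
ratio (default 4) is then imposed exactly in conductance-integral terms
(g^max·τ_fall).  `calibrate_excitability` scales each neuron's whole
afferent weight column against Poisson surrogates of its in-network input;
scales that would push a weight past 1 are clipped and flagged.

`calibrate_antennal_lobe` works with lateral inhibition switched off and
homogenizes projection neurons, then local neurons, toward the median
uncalibrated response (±10%): too-strong units get their input weights
reduced; too-weak units whose input weights are already at the ceiling
receive helper excitation from strong sibling PNs of the same glomerulus
(the helper graph is kept acyclic by construction and asserted); an
entirely weak glomerulus recruits an extra external input stream.

## Stimulus generators

All generators are pure functions of (parameters, seed).

* Pulse packets: per source, `a` spike times ~ N(t_center, σ²).  Early
  samples are kept (clipping would bias σ); the realized σ is defined as
  the standard deviation of all emitted spike times.
* Poisson sources; Gamma-process trains with ISI ~ Γ(shape=γ, mean=1/rate),
  so ISI CV = 1/√γ (γ=5 for the olfactory receptor inputs).
* Copula rate patterns: a Gaussian copula with uniform off-diagonal target
  correlation feeds unit-rate exponential marginals; values above e are
  clipped, divided by e, and mapped to [20, 55] Hz.  The Gaussian family
  is a choice (only "a copula" is prescribed); clipping plus the
  nonlinear marginal attenuate the empirical Pearson correlation to
  ≈0.54–0.58 for a 0.6 target at 100 samples.
* Two-template streams: the templates are two frozen Poisson realizations
  (25 Hz per channel, 200 ms = 4 segments long); each 50 ms window of the
  stream copies slice (k mod 4) from template X or Y (fair coin) and adds
  1 ms Gaussian timing jitter, folded back into the window so windows stay
  self-contained.

## Benchmark networks

Parameters the source material does not fix were chosen once per network
and are module-level constants.  Unless noted, neurons use C_m = 0.2 nF,
g_l = 0.02 µS (τ_m = 10 ms), E_exc = 0, E_inh = −80, V_th = −55,
V_reset = −70 mV, τ_refrac = 2 ms, and synaptic τ_fall = 5 ms.

**Synfire chain with feedforward inhibition.**  Groups of 100 RS + 25 FS
(189-neuron 3×(45+18) filter variant, 12×(8+8) loop variant).  Fixed
in-degrees: 60 from the previous RS group (onto both RS and FS), 25 from
the local FS pool.  E_l is raised to −62 mV, replacing the original
model's background current; FS cells are slightly more excitable
(V_th = −56.5 mV) so inhibition engages against weak, broad packets.
Group-to-group conductance is held constant across variants by scaling
synaptic strengths with the in-degree.  With g_exc = 0.7 nS and
g_inh = 4.5 nS, tight packets (σ ≲ 1–2 ms at a = 1) converge to
(σ, a) ≈ (0.1 ms, 1) within three groups and broad packets are
extinguished to (0, 0).  The loop variant doubles g_l and shortens
inhibition (τ_fall 4 ms) so neurons recover within the ≈23 ms loop cycle;
a single initial packet then circulates indefinitely.

**Balanced random network.**  100 excitatory + 25 inhibitory neurons, 100
excitatory + 25 inhibitory Poisson sources at 10 Hz, all eight projections
Bernoulli p = 0.1, inhibitory strength 4× excitatory, excitatory efferents
depressing (U_SE = 0.4, τ_rec = 150 ms).  The single free parameter — the
excitatory weight — is *defined* by the target mean rate (9 Hz) and found
by bisection on short runs, mirroring how the reference software
simulation chose its weight.  At that operating point the network is
asynchronous-irregular: mean ISI CV ≈ 0.95–1.05, mean pairwise 2 ms-bin
spike-count correlation ≈ 0.01.

**Soft winner-take-all ring.**  50 excitatory neurons on a ring, Gaussian
recurrence (σ_rec = 5 neurons, p = 1), common pool of 16 inhibitory
neurons (ring→pool p = 0.6, pool→ring p = 1, inhibition 4× excitation).
Stimulus cones at neurons 13 and 38 (σ_ext = 3 neurons, clipped at 3σ,
five independent Poisson sources per covered neuron).  The half-ring rate
curves cross at r₂ ≈ r₁ by symmetry; the crossing is located by linear
interpolation of the sweep.

**Cortical attractor memory.**  4 hypercolumns × 3 minicolumns × (13
pyramidal + 2 RSNP) plus one merged 2-cell basket population per
hypercolumn (188 neurons; the full-size configuration would be
9×9×(30+2+1) = 2673).  Within-pattern pyramidal excitation (local weight
1.0, long-range 0.7, depressing U_SE = 0.15, τ_rec = 500 ms — the
depression stands in for the spike-frequency adaptation the substrate
lacks), pyramidal→basket→pyramidal soft WTA within hypercolumns,
pyramidal→RSNP→pyramidal competition between patterns.  Basket and RSNP
cells sit closer to threshold (E_l = −63, V_th = −56 mV), a heuristic fit
needed at this scale.  Under diffuse Poisson drive the network alternates
between patterns (dwell times of order 100 ms, winner dominance ≈0.85);
pyramidal cells inside an active pattern show an elevated mean membrane
potential (UP state, ≈3 mV above baseline); cueing a single minicolumn of
one pattern raises that pattern's dominance from ≈1/3 to ≳0.7 (pattern
completion), saturating as more minicolumns are cued.

**Antennal lobe.**  10 glomeruli × (6 receptor streams → 7 PNs → 3 LNs);
LNs inhibit the PNs of all other glomeruli with one uniform weight scaled
by q ∈ [0, 1].  Input rates 20–55 Hz (copula patterns, γ=5 trains, 1 s per
presentation); the output channel vector is the mean PN rate per
glomerulus.  q = 0 transmits the input correlation structure; q = 1
drives the mean off-diagonal output correlation below 0.1 (typically
slightly negative); the median decreases monotonically in q.

**Liquid state machine.**  191 liquid neurons (153 exc / 38 inh), each
receiving exactly 4 of 32 excitatory and 4 of 32 inhibitory input
sources; internal probabilities p_ee/p_ei/p_ie/p_ii = 0.1/0.2/0.25/0.25.
The input drivers decay with τ_fall = 10 ms versus 8 ms recurrent, so the
liquid's fading memory is dominated by the direct input echo (≈ one 50 ms
window) rather than self-sustained reverberation — the deliberate design
point that yields high one-window-back accuracy *and* chance performance
two windows back.  The readout is a single current-based tempotron over
all 191 liquid neurons: kernel K(t) = A(e^{−t/τ_m} − e^{−t/τ_s}) with
τ_m = 15 ms, τ_s = τ_m/4 (A normalizes the peak to 1, the standard
convention), threshold 1, decision window = the 50 ms after the labeled
segment, trained with the gradient rule Δw_j = ±α(n) Σ_{t_ij<t_max}
K(t_max − t_ij) (α = 2·10⁻³ decaying as 1/(1+n/250)).  After 1000
training iterations the evaluation correctness over 200 fresh windows is
≈88–93% for the segment one window back and statistically
indistinguishable from 50% two windows back.  The conductance-based
variant keeps per-afferent signs fixed (updates that would cross zero are
clipped), scales excitatory updates by |V̄−E_inh|/|V̄−E_exc| to compensate
the asymmetric reversal-potential distances, and requantizes weights to 4
bits after every update; its classification uses the same kernel voltage
with the driving-force linearization at V̄ (rest close to threshold,
reversal potentials far) rather than a full conductance simulation.

## What the synthetic stimuli do and do not emulate

All inputs are generated: Poisson/Gamma renewal trains, Gaussian pulse
packets, copula-correlated rate vectors, jittered two-template streams.
They reproduce the first- and second-order statistics the experiments are
about (rates, ISI regularity, channel correlation, packet spread) but not
the richer structure of recorded data — no rate nonstationarity beyond
the programmed pattern switches, no cross-train correlation except where
constructed, no sensory transduction dynamics.  Passing tests therefore
demonstrate that the networks transform these controlled statistics as
claimed, not that they would process natural stimuli.

## Numerical choices and conventions

* Population (1/N) standard deviations throughout (CV, packet σ, report
  spreads).
* Pairwise correlation: 2 ms bins, Pearson on binned counts, 1000 randomly
  drawn distinct pairs; zero-variance pairs are redrawn and counted.
* Packet segmentation: a group's spikes belong to one traversal until a
  gap >5 ms (cycle times ≈20 ms are an order of magnitude above packet
  widths); propagation is classified at a ≥ 0.5.
* Attractor detection: pattern rates smoothed with a 20 ms boxcar; a
  pattern is active above 50% of the run's peak pattern rate; dwell times
  are the active intervals.
* Degenerate inputs: a silent packet group reports (a, σ) = (0, 0); CV
  excludes units with <3 spikes and reports them; a flat tempotron trace
  puts t_max at the window start.
* Weight ties in quantization round up; bisections work on log scales and
  stop at ±10% unless stated.

## Problem sizes used in the shipped analyses

The statistics reported by the test-suite and the results script use the
sizes the experiments define: 20 s for the balanced random network, 11 × 10
two-second runs for the sWTA sweep, three seeds × 150 ms per synfire
packet, 100 patterns × 1 s per lateral-inhibition strength for the
antennal lobe, and 1000 training + 200 evaluation windows (62.6 s of
liquid time) per LSM condition, averaged over two liquid/stream seeds.
The full 36-point synfire state-space grid and longer attractor runs are
available through the library but not part of the default analyses.

## Known limitations

* Clock-driven only; spike times are quantized to dt, so realized packet
  σ below ~0.1 ms is resolution-limited.
* The analog hardware effects that are modelled (quantization, sharing,
  fixed-pattern noise, delays) are the documented dominant ones; circuit
  defects, parameter-range clipping, and STP-circuit saturation are not.
* The attractor model is a qualitative reproduction (switching, UP
  states, completion); dwell-time distributions are not calibrated to any
  reference.
* `calibrate_drivers` probes drivers sequentially and scales linearly in
  driver count; calibrating all 256 drivers of a full chip is minutes of
  compute, not the seconds a real chip needs.
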