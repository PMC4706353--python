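# Methods

This note describes the generative models, estimators and oracles in
`phaselock`, the calibrations and numerical choices behind them, and
what the validation suite does and does not establish.

## Phase-oscillator model

Two phase oscillators X and Y evolve under Euler integration (step
1 ms) as

    dφ_X/dt = 2π (ω_X + Np_X(t))
    dφ_Y/dt = 2π (ω_Y + κ sin(φ_X − φ_Y) + Np_Y(t))

with unidirectional coupling X→Y and a sinusoidal phase-response curve
whose attractor lies at zero phase difference. Frequencies `ω` and the
coupling `κ` are in Hz and are scaled by 2π inside the integrator, so
the noiseless 1:1 locking boundary (Arnold tongue edge) sits at
`|ω_X − ω_Y| = κ` in Hz. This convention makes the tongue analytically
checkable: the phase relation θ = φ_Y − φ_X obeys the Adler equation
`dθ/dt = 2π(Δ − κ sin θ)`, whose stationary density outside the tongue
is `p(θ) ∝ 1/|Δ − κ sin θ|`, giving the closed-form expected locking
`PL = (|Δ| − √(Δ² − κ²))/κ` (derived by residue calculus and
cross-checked against adaptive quadrature in the tests).

Trials are independent re-initializations with uniform random initial
phases; each trial runs 3 s and the first 2 s are discarded, leaving
the quasi-stationary segment. Defaults: 500 trials, gamma-range
frequencies (the frequency range itself is immaterial to the phase
dynamics).

**Intrinsic noise.** `Np` is pink (1/f) Gaussian noise generated by FFT
spectral shaping of seeded white noise and expressed as an
instantaneous-frequency perturbation; the shaping filter is normalized
analytically (not per realization), and scale 1 corresponds to an
instantaneous-frequency SD of 1.5 Hz per oscillator. The exponent
matters: with 1/f noise at this SD, the zero-detuning, κ = 1 pair sits
at PL² ≈ 0.26–0.31 (the partially synchronized operating point used
throughout the estimator comparisons); a steeper 1/f^1.5 spectrum at the
same SD concentrates power at the slowest wander and drives PL² down to
≈ 0.10. The 1/f choice is the one consistent with the toolkit's
partial-synchronization anchor; the steeper 1/f^1.5 exponent is used
where it belongs, in the spiking-network drive noise and in the
`"pink15"` extrinsic noise.

**Signals.** x = A·cos φ_X; y = A(1 + α cos θ)·cos φ_Y, i.e.
phase-relation-dependent amplitude modulation (PrAM) of strength α is
applied post hoc to Y only (α = 0.2 means the envelope spans
0.8–1.2 for A = 1). Each trial is demeaned.

**Extrinsic noise and SNR.** The SNR is the relative power ratio
`SNR(ω) = S_SN(ω)²/S_N(ω)² − 1` at the clean signal's trial-averaged
spectral peak. For each channel an independent noise realization (white
or 1/f^1.5) is drawn and its scale `c` is calibrated so the *realized*
ratio equals the requested SNR; the realized ratio is exactly quadratic
in `c`, so the calibration equation is solved in closed form and the
round-trip (`add_extrinsic_noise` → `estimate_snr`) recovers the
request to numerical precision. A consequence worth knowing: the SNR is
defined at one frequency bin, so a narrowband signal in white noise at
"SNR 50" still carries substantial in-band noise across a 30 Hz
analysis band — the PLV (which sees the whole band) therefore sits
below coherence (which looks at the peak bin) at equal nominal SNR.

## PING network model

Each of the two networks has 400 regular-spiking (RS, excitatory;
Izhikevich parameters a = 0.02, b = 0.2, c = −65, d = 8) and 100
fast-spiking neurons (FS, inhibitory; 0.1, 0.2, −65, 2), integrated by
Euler at 1 ms. Synapses are all-to-all (no self-connections) with
per-pair strengths drawn once per simulation, uniformly between 0 and
the type maximum (RS→FS 0.45, RS→RS 0.05, FS→RS −0.35, FS→FS −0.2 mV);
gating variables decay exponentially (AMPA 2 ms for RS, GABA-A 8 ms for
FS) and reset to 1 on a presynaptic spike; all connections have a 1 ms
conduction delay. Cross-network coupling is excitatory only: RS→FS
("E→I", default max 0.015 mV) and RS→RS ("E→E", default 0.007 mV),
bidirectional by default. RS cells receive a fixed 10 mV drive, private
white current noise (SD 3.5 mV per step) and a 1/f^1.5 drive noise
(SD 3.5 mV) shared within a network but independent between networks
(the network analogue of intrinsic phase noise, applied to RS cells
only); FS cells receive 3.5 mV fixed drive plus private noise. Trials
(default 300 × 1.3 s, first 0.3 s discarded) are integrated in parallel
with per-trial noise and a common weight draw.

The population field signal is the per-bin sum of RS spike indicators,
demeaned per trial and smoothed with a Gaussian kernel (SD 3 ms,
truncated at ±4 SD and renormalized). At the defaults this yields clean
PING: RS volleys (~18 Hz per-cell rate) followed by FS volleys, a
population spectral peak at 33–35 Hz, and RS spike phases strongly
coupled to the field (vector strength ≈ 0.7).

**Drive as the detuning knob.** The gamma peak frequency grows with the
RS drive at ≈ 0.3 Hz/mV in this network (measured uncoupled), and the
cross-coupling pulls both networks toward a common frequency until the
drive difference exceeds roughly 8–12 mV. Sweeps that need to traverse
the locked-to-drifting transition therefore use a 0–12 mV drive-delta
grid, and the connectivity grid fixes the drive difference at 8 mV —
about a 2 Hz intrinsic frequency difference — to sit in the partially
synchronized regime. Both knobs are parameters of the experiment
functions.

## Estimators

**Spectral coherence.** Per-trial DFTs over rectangular windows (no
taper, no zero-padding; trials may be cut into shorter windows — a
0.2 s window gives 5 Hz resolution). Two formulas: the classical
magnitude coherence (summed cross-spectrum over the root of summed
auto-spectra) and the per-trial-normalized variant (the mean resultant
vector length of cross-spectral phase factors), which is insensitive to
amplitude correlations and is the default everywhere. The squared peak
(DC and Nyquist excluded, ties broken toward the lower frequency,
default search band 20–60 Hz) is corrected for the finite trial count
as `(Coh²N − 1)/(N − 1)`; corrected values may be slightly negative and
are never clipped, so null averages stay unbiased. Bins whose per-trial
power is at floating-point rounding level (relative threshold 1e−24)
carry no phase information and are excluded from the per-trial
normalization.

**PLV.** The default decomposition is a zero-phase FIR band-pass
(three cycles of the band center as the filter length, reflected-edge
padding; gamma band 25–55 Hz) followed by the analytic signal. The
optional `"ssa_hilbert"` backend embeds each trial in a Hankel
trajectory matrix (window ≈ n/3, capped at 350), reconstructs elementary
SVD components by diagonal averaging, and keeps those whose dominant
frequency falls in the requested band; the extraction is applied twice
because near-degenerate singular subspaces (in-band and out-of-band
components of similar energy) mix under a single pass. PLV is the
squared mean resultant vector length of the instantaneous phase
relations concatenated over trials, corrected as `(PLV²T − 1)/(T − 1)`.
The expected (ground-truth) phase locking is the same statistic on the
noise-free generative phases (for networks: plain Hilbert phases of the
noise-free population signals). PrAM strength is estimated by linear
least squares of the envelope on `(1, cos θ, sin θ)`.

**Transfer entropy.** Plugin estimate over the 8 joint states of
(target next bin, target current bin, delayed source bin), in bits, at
delays 1–16 ms, on trial-concatenated binary trains. The per-delay
values are combined by maximum (configurable: mean, sum) — the
peak-transmission reading. Network TE subsamples RS neurons (seeded),
computes all ordered pairs via per-state matrix products, and averages;
both directions are returned and usually summed. No bias subtraction is
applied; under independence the per-delay plugin TE is asymptotically
`χ²₂/(2 n ln 2)`, and `independence_null_bound` turns that into an
upper envelope for the max-over-delays statistic (Bonferroni over
delays). This χ² envelope, not the expectation-level figure
`(states−1)/(2 n ln 2)`, is the right yardstick for a maximum.

## Analytic oracles

Besides the Adler locking formula: sideband amplitudes — partial
synchronization puts a component of amplitude `A·PL` exactly at the
driving oscillator's frequency (the frequency-modulation sideband), and
PrAM of strength α puts `A·α/2` at ± the precession frequency — and the
expected coherence of two constant phasors in independent noise with
Rayleigh (χ, 2 dof) amplitudes and uniform phases. Because the two
channels' noises are independent, that expectation factorizes into one
phasor-consistency integral per channel (evaluated by adaptive
quadrature, cross-validated against Monte Carlo); the SNR maps to the
signal amplitude via `S²/E[A²] = SNR` with `E[A²] = 2` for the unit
Rayleigh. When the oracle is compared with simulated coherence, the
sideband-to-carrier ratio is measured on the clean generative spectrum;
residual disagreement of a few hundredths of coherence remains from
finite-window leakage of the (off-bin) carrier into the sideband bin,
which the idealized oracle ignores.

## Validation protocol choices

* **Adler sweep windows.** The expected-locking validation (κ = 0.75,
  detuning 0–8 Hz in 0.25 Hz steps, 100 trials) uses 3 s analysis
  windows. The reason is sampling, not runtime: near the tongue edge the
  precession period grows (1.51 s at a 1 Hz detuning), and a window
  shorter than the period cannot sample the stationary density — the
  concatenated MRVL over 1 s windows converges to 0.551 instead of the
  true 0.451 at that grid point regardless of trial count. With 3 s
  windows the sweep matches the closed form with MSE ≈ 2–3 × 10⁻⁵.
* **Common random numbers.** Within a sweep cell all estimators consume
  the identical realizations; across cells the simulation seed is also
  held fixed, so only the manipulated parameter varies. This removes
  weight-draw and noise-path variability from between-cell contrasts.
* **Reduced scale.** The test suite runs the oscillator experiments at
  100–500 trials (the generative defaults) and the network experiments
  at 20–30 trials with 20 subsampled neurons for TE; these sizes keep
  every qualitative ordering stable under seed changes. The experiment
  functions accept the full-scale settings (300 trials, 80 neurons)
  unchanged.

## What the synthetic data do and do not establish

The generators produce the phenomena the estimators are meant to
disentangle — partial synchronization, frequency/amplitude modulation
sidebands, broadband field-like signals, spike-phase coupling — with
known ground truth, which real recordings never provide. They do not
emulate volume conduction or common reference artifacts, non-sinusoidal
waveform asymmetries, multi-band interactions, nonstationary coupling
strength within a trial, or measurement filtering; conclusions about
estimator *bias mechanisms* transfer to real data, absolute estimator
values do not.

## Known limitations

* The E→E/E→I interference regime — in which strengthening E→E
  connections *desynchronizes* the networks so that spike-level
  information flow falls while coherence (driven by the PrAM sideband)
  rises — does not occur in this implementation at the documented
  connection strengths: E→E is purely synchronizing over the probed
  range (PL² and TE both rise monotonically with E→E up to 0.1 mV).
  The corresponding opposite-trends check in the validation suite
  documents this as a failing assertion rather than hiding it. The
  phase preferences of the two coupling pathways depend on sub-cycle
  timing details (synaptic rise, conduction, volley shape) that the
  model pins down only partially.
* The spiking-network drive-to-frequency gain (~0.3 Hz/mV) is shallow;
  detuning experiments need drive differences of several mV, and the
  network TE contrasts at reduced scale are small relative to the
  plugin-null fluctuations unless coupling is varied directly.
* Euler integration at 1 ms quantizes spike timing to the bin width;
  the PING period is resolved to ~1 ms, so uncoupled frequency
  differences below ~0.5 Hz are not measurable on 1 s windows.
* The SSA backend is a generic singular-spectrum extraction with
  band-targeted component selection, not a reimplementation of any
  specific published decomposition pipeline; it is provided for
  robustness checks, and all default analyses use the filter–Hilbert
  path.
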