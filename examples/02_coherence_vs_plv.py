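"""Why spectral coherence overestimates phase locking and PLV does not.

A partially synchronized, intrinsically noisy oscillator pair is
corrupted with increasing levels of measurement noise.  The coherence
peak does not converge to the true (expected) phase locking as the SNR
grows — it is driven by the modulation sideband that synchronization
itself creates — whereas the PLV estimate, built on the reconstructed
instantaneous phase, converges to the ground truth.
"""

from phaselock import (
    OscillatorPairConfig,
    add_extrinsic_noise,
    bias_correct_plv2,
    coherence_spectrum,
    corrected_peak,
    decompose,
    expected_phase_locking,
    plv,
    simulate_phase_pair,
    spectra,
    synthesize_signals,
)

cfg = OscillatorPairConfig(
    omega_x=40.0, omega_y=42.0, kappa=1.0, intrinsic_noise_scale=1.0,
    n_trials=100, seed=3,
)
traj = simulate_phase_pair(cfg)
pl2 = expected_phase_locking(traj).value
clean = synthesize_signals(traj, cfg)
print(f"expected PL^2 (ground truth, noise-free phases): {pl2:.3f}\n")
print(f"{'SNR':>5} {'coh^2 peak':>11} {'PLV^2':>7}")
for snr in (0.8, 5.0, 10.0, 23.0, 47.0):
    noisy = add_extrinsic_noise(clean, snr, "white", seed=17)
    coh2 = corrected_peak(
        coherence_spectrum(spectra(noisy, 1.0)), (20.0, 60.0)
    ).value
    comp_x, comp_y = decompose(noisy, "bandpass_hilbert", (25.0, 55.0))
    raw = plv(comp_x.inst_phase, comp_y.inst_phase)
    plv2 = bias_correct_plv2(raw.value, raw.n_units)
    print(f"{snr:>5.1f} {coh2:>11.3f} {plv2:>7.3f}")
print(
    "\nWith increasing SNR, PLV^2 approaches the expected PL^2 from"
    "\nbelow, while the coherence peak keeps rising past the truth."
)
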