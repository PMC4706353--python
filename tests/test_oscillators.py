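import numpy as np
import pytest

from phaselock import (
    OscillatorPairConfig,
    TrialSignalSet,
    add_extrinsic_noise,
    adler_expected_pl,
    estimate_snr,
    pram_envelope,
    simulate_phase_pair,
    synthesize_signals,
)
from phaselock.oscillators import wrap_phase


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"dt": 0.0},
            {"trial_duration": 1.0, "discard": 1.5},
            {"pram_alpha": 1.2},
            {"amplitude": 0.0},
            {"prc": "vanderpol"},
            {"n_trials": 0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            OscillatorPairConfig(**kwargs)


class TestSimulatePhasePair:
    def test_uncoupled_precession_is_linear(self):
        """kappa=0, no noise, 3 Hz detuning: the unwrapped phase relation
        advances at exactly 2*pi*3 rad/s in every trial."""
        cfg = OscillatorPairConfig(
            omega_x=40.0, omega_y=43.0, kappa=0.0, n_trials=8, seed=0
        )
        traj = simulate_phase_pair(cfg)
        theta = np.unwrap(traj.phases_y - traj.phases_x, axis=1)
        rates = np.diff(theta, axis=1) / cfg.dt
        np.testing.assert_allclose(rates, 2 * np.pi * 3.0, rtol=1e-9)

    def test_full_synchrony_inside_tongue(self):
        """Detuning strictly inside the Arnold tongue, no noise: after the
        transient the phase relation is constant and expected PL = 1."""
        cfg = OscillatorPairConfig(
            omega_x=40.0, omega_y=40.5, kappa=1.0, n_trials=8, seed=0
        )
        traj = simulate_phase_pair(cfg)
        theta = traj.phase_relation()
        # trajectories starting near the repelling fixed point converge
        # slowest; a residual drift of order 1e-4 rad remains
        assert np.ptp(theta) < 1e-3
        from phaselock import resultant_length

        assert resultant_length(theta) > 1 - 1e-6

    def test_precession_dwells_at_prc_zero_crossing(self):
        """Partial synchronization: the instantaneous precession dtheta/dt,
        obtained by direct differencing, is slowest where the coupling term
        maximally opposes the detuning, i.e. near theta = +pi/2 for a
        +3 Hz detuning and kappa = 1."""
        cfg = OscillatorPairConfig(
            omega_x=40.0, omega_y=43.0, kappa=1.0, n_trials=4, seed=1
        )
        traj = simulate_phase_pair(cfg)
        theta = np.unwrap(traj.phases_y - traj.phases_x, axis=1)
        dtheta = np.diff(theta, axis=1) / cfg.dt / (2 * np.pi)  # Hz
        mid = wrap_phase(0.5 * (theta[:, 1:] + theta[:, :-1]))
        # the Adler equation says dtheta/dt = detuning - kappa*sin(theta):
        # minimum at theta = +pi/2
        idx = np.argmin(dtheta, axis=1)
        theta_at_min = mid[np.arange(mid.shape[0]), idx]
        np.testing.assert_allclose(theta_at_min, np.pi / 2, atol=0.15)
        # and the realized frequency modulation equals kappa*PRC(theta)
        pred = 3.0 - cfg.kappa * np.sin(mid)
        np.testing.assert_allclose(dtheta, pred, atol=0.05)

    def test_phases_wrapped_and_finite(self):
        cfg = OscillatorPairConfig(n_trials=3, seed=2, intrinsic_noise_scale=1.0)
        traj = simulate_phase_pair(cfg)
        for arr in (traj.phases_x, traj.phases_y):
            assert np.all(arr > -np.pi) and np.all(arr <= np.pi)
            assert np.isfinite(arr).all()

    def test_seed_reproducibility(self):
        cfg = OscillatorPairConfig(n_trials=3, seed=11, intrinsic_noise_scale=0.5)
        a = simulate_phase_pair(cfg)
        b = simulate_phase_pair(cfg)
        np.testing.assert_array_equal(a.phases_y, b.phases_y)


class TestSynthesizeSignals:
    def test_alpha_zero_is_pure_cosine(self):
        cfg = OscillatorPairConfig(
            omega_x=40.0, omega_y=43.0, kappa=0.0, n_trials=4, seed=3
        )
        traj = simulate_phase_pair(cfg)
        sig = synthesize_signals(traj, cfg)
        expected = np.cos(traj.phases_y)
        expected -= expected.mean(axis=1, keepdims=True)
        np.testing.assert_allclose(sig.y, expected, atol=1e-12)

    def test_pram_envelope_range(self, uncoupled_pram_signals):
        """alpha = 0.2 on a unit-amplitude oscillation: the instantaneous
        amplitude envelope spans [0.8, 1.2]."""
        cfg, traj, _ = uncoupled_pram_signals
        env = pram_envelope(traj, 0.2, 1.0)
        assert env.max() == pytest.approx(1.2, abs=1e-3)
        assert env.min() == pytest.approx(0.8, abs=1e-3)

    def test_pram_sidebands_at_detuning_offset(self, uncoupled_pram_signals):
        """Uncoupled pair, 3 Hz detuning, alpha=0.2: FFT of y shows
        sidebands at omega_y +/- 3 Hz with single-sided amplitude
        A*alpha/2 = 0.1."""
        cfg, traj, sig = uncoupled_pram_signals
        amp = 2 * np.abs(np.fft.rfft(sig.y, axis=1)).mean(axis=0) / sig.n_samples
        freqs = np.fft.rfftfreq(sig.n_samples, d=1 / sig.fs)
        for f_side in (40.0, 46.0):
            assert amp[freqs == f_side][0] == pytest.approx(0.1, rel=0.05)

    def test_trials_are_demeaned(self, partial_sync_signals):
        _, _, sig = partial_sync_signals
        assert np.abs(sig.x.mean(axis=1)).max() < 1e-12
        assert np.abs(sig.y.mean(axis=1)).max() < 1e-12

    def test_alpha_out_of_range_rejected(self, partial_sync_traj):
        _, traj = partial_sync_traj
        with pytest.raises(ValueError):
            pram_envelope(traj, 1.5)


class TestExtrinsicNoise:
    def test_huge_snr_leaves_signal_untouched(self, partial_sync_signals):
        """At SNR 1e6 the added noise SD is ~1e-2 of the peak amplitude;
        the worst-case deviation stays below a few noise SDs."""
        _, _, sig = partial_sync_signals
        noisy = add_extrinsic_noise(sig, 1e6, "white", seed=0)
        assert np.abs(noisy.y - sig.y).max() < 0.1
        assert np.corrcoef(noisy.y.ravel(), sig.y.ravel())[0, 1] > 0.999

    def test_snr_roundtrip_at_peak(self, partial_sync_signals):
        """Calibration round-trip: request SNR 5, re-measure the relative
        power ratio at the spectral peak, recover 5 within 5%."""
        _, _, sig = partial_sync_signals
        noisy = add_extrinsic_noise(sig, 5.0, "white", seed=1)
        noise_only = TrialSignalSet(noisy.x - sig.x, noisy.y - sig.y, fs=sig.fs)
        measured = estimate_snr(noisy, noise_only, 40.0)
        assert measured == pytest.approx(5.0, rel=0.05)

    def test_noise_independent_across_channels(self, partial_sync_signals):
        _, _, sig = partial_sync_signals
        noisy = add_extrinsic_noise(sig, 1.0, "white", seed=2)
        nx = (noisy.x - sig.x).ravel()
        ny = (noisy.y - sig.y).ravel()
        assert abs(np.corrcoef(nx, ny)[0, 1]) < 0.01

    def test_zero_power_signal_rejected(self):
        flat = TrialSignalSet(np.zeros((3, 100)), np.zeros((3, 100)), fs=1000.0)
        with pytest.raises(ValueError):
            add_extrinsic_noise(flat, 2.0, "white", seed=0)

    def test_invalid_snr_and_kind(self, partial_sync_signals):
        _, _, sig = partial_sync_signals
        with pytest.raises(ValueError):
            add_extrinsic_noise(sig, 0.0, "white")
        with pytest.raises(ValueError):
            add_extrinsic_noise(sig, 2.0, "blue")


class TestEstimateSnr:
    def test_noise_only_equals_noisy_gives_zero(self, rng):
        noise = rng.standard_normal((20, 500))
        s = TrialSignalSet(noise, noise.copy(), fs=1000.0)
        assert estimate_snr(s, s, 100.0) == pytest.approx(0.0, abs=1e-12)

    def test_relative_power_arithmetic(self):
        """Signal power equal to 2x the noise power at a bin gives SNR 1."""
        t = np.arange(1000) / 1000.0
        tone = np.cos(2 * np.pi * 50 * t)[None, :]
        noisy = TrialSignalSet(
            np.sqrt(2.0) * tone, np.sqrt(2.0) * tone, fs=1000.0
        )
        ref = TrialSignalSet(tone, tone, fs=1000.0)
        assert estimate_snr(noisy, ref, 50.0) == pytest.approx(1.0, abs=1e-9)

    def test_frequency_outside_nyquist_rejected(self, partial_sync_signals):
        _, _, sig = partial_sync_signals
        with pytest.raises(ValueError):
            estimate_snr(sig, sig, 600.0)


class TestLockingAgainstAdler:
    def test_expected_pl_matches_adler_at_moderate_detuning(self):
        """Sampling theta from the simulated stationary dynamics reproduces
        the closed-form Adler locking at detuning/kappa = 3."""
        cfg = OscillatorPairConfig(
            omega_x=40.0, omega_y=43.0, kappa=1.0, n_trials=100, seed=7
        )
        traj = simulate_phase_pair(cfg)
        from phaselock import resultant_length

        pl = resultant_length(traj.phase_relation())
        assert pl == pytest.approx(adler_expected_pl(3.0, 1.0), abs=0.02)
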