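import numpy as np
import pytest

from phaselock import (
    OscillatorPairConfig,
    TrialSignalSet,
    adler_expected_pl,
    bias_correct_plv2,
    decompose,
    estimate_pram,
    expected_phase_locking,
    plv,
    pram_envelope,
    resultant_length,
    simulate_phase_pair,
    synthesize_signals,
)


def _tone(freq=40.0, fs=1000.0, n_trials=4, n_samples=1000, noise_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) / fs
    x = np.cos(2 * np.pi * freq * t)[None, :].repeat(n_trials, axis=0)
    if noise_sd:
        x = x + noise_sd * rng.standard_normal(x.shape)
    return TrialSignalSet(x, x.copy(), fs=fs)


class TestPlv:
    def test_constant_relation_gives_one(self, rng):
        phase_y = rng.uniform(-np.pi, np.pi, (5, 300))
        phase_x = phase_y + 0.7
        est = plv(phase_x, phase_y)
        assert est.value == pytest.approx(1.0, abs=1e-12)
        assert est.n_units == 1500

    def test_uniform_grid_cancels_exactly(self):
        theta = np.linspace(-np.pi, np.pi, 361)[1:][None, :]
        est = plv(theta, np.zeros_like(theta))
        assert est.value == pytest.approx(0.0, abs=1e-20)

    def test_adler_density_sampling_matches_closed_form(self, rng):
        """Sampling theta from the stationary density p ~ 1/|dw+k*sin t|
        with dw/kappa = 2 reproduces the closed-form Adler MRVL."""
        # rejection-sample from the density on a fine grid
        grid = np.linspace(-np.pi, np.pi, 20001)[:-1]
        dens = 1.0 / np.abs(2.0 + np.sin(grid))
        dens /= dens.sum()
        t_draws = 200_000
        theta = rng.choice(grid, size=t_draws, p=dens)
        pl = resultant_length(theta)
        assert pl == pytest.approx(
            adler_expected_pl(2.0, 1.0), abs=2.0 / np.sqrt(t_draws)
        )

    def test_amplitude_invariance(self, partial_sync_signals):
        """PLV depends only on instantaneous phases: rescaling whole trials
        by arbitrary positive gains leaves the estimate unchanged."""
        _, _, sig = partial_sync_signals
        gains = np.random.default_rng(0).uniform(0.2, 5.0, (sig.n_trials, 1))
        scaled = TrialSignalSet(sig.x * gains, sig.y * 3.0, fs=sig.fs)
        a_x, a_y = decompose(sig, "bandpass_hilbert", (25.0, 55.0))
        b_x, b_y = decompose(scaled, "bandpass_hilbert", (25.0, 55.0))
        a = plv(a_x.inst_phase, a_y.inst_phase).value
        b = plv(b_x.inst_phase, b_y.inst_phase).value
        assert a == pytest.approx(b, abs=1e-10)

    def test_shape_mismatch_and_empty_rejected(self):
        with pytest.raises(ValueError):
            plv(np.zeros((2, 3)), np.zeros((3, 2)))
        with pytest.raises(ValueError):
            plv(np.empty((0,)), np.empty((0,)))


class TestBiasCorrection:
    @pytest.mark.parametrize(
        "plv2,t,expected",
        [
            (1.0, 1000, 1.0),
            (0.001, 1000, 0.0),  # 1/T null expectation
            (0.25, 1000, 249.0 / 999.0),
        ],
    )
    def test_arithmetic(self, plv2, t, expected):
        assert bias_correct_plv2(plv2, t) == pytest.approx(expected)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            bias_correct_plv2(0.5, 1)


class TestExpectedPhaseLocking:
    def test_fully_locked_pair_gives_one(self):
        cfg = OscillatorPairConfig(
            omega_x=40.0, omega_y=40.2, kappa=1.0, n_trials=6, seed=0
        )
        est = expected_phase_locking(simulate_phase_pair(cfg))
        assert est.value == pytest.approx(1.0, abs=1e-6)
        assert est.bias_corrected

    def test_uncoupled_pair_near_zero(self):
        cfg = OscillatorPairConfig(
            omega_x=40.0, omega_y=43.0, kappa=0.0, n_trials=100, seed=1
        )
        est = expected_phase_locking(simulate_phase_pair(cfg))
        assert abs(est.value) < 1e-3


class TestDecompose:
    def test_pure_tone_phase_ramp(self):
        """A clean 40 Hz cosine in a 30-50 Hz band: instantaneous phase is
        a linear ramp at 2*pi*40 rad/s, median inst. frequency 40 Hz."""
        sig = _tone(40.0)
        comp_x, _ = decompose(sig, "bandpass_hilbert", (30.0, 50.0))
        interior = slice(100, -100)  # away from edge effects
        assert np.median(comp_x.inst_freq[:, interior]) == pytest.approx(
            40.0, abs=0.1
        )
        unwrapped = np.unwrap(comp_x.inst_phase, axis=1)[:, interior]
        slopes = np.diff(unwrapped, axis=1) / (1 / sig.fs)
        np.testing.assert_allclose(
            np.median(slopes), 2 * np.pi * 40.0, rtol=1e-3
        )

    def test_component_reconstruction_identity(self):
        sig = _tone(40.0, noise_sd=0.3)
        comp_x, _ = decompose(sig, "bandpass_hilbert", (30.0, 50.0))
        recon = comp_x.inst_amp * np.cos(comp_x.inst_phase)
        np.testing.assert_allclose(recon, comp_x.component, atol=1e-8)

    def test_phase_error_decreases_with_snr(self):
        """Circular SD of the phase error around the true ramp shrinks as
        the white-noise SNR grows."""
        t = np.arange(1000) / 1000.0
        true_phase = 2 * np.pi * 40.0 * t
        sds = []
        for snr, seed in ((1.0, 0), (10.0, 1), (100.0, 2)):
            noise_sd = np.sqrt(0.5 / snr)
            sig = _tone(40.0, noise_sd=noise_sd, seed=seed)
            comp_x, _ = decompose(sig, "bandpass_hilbert", (30.0, 50.0))
            err = comp_x.inst_phase[:, 100:-100] - true_phase[None, 100:-100]
            r = np.abs(np.exp(1j * err).mean())
            sds.append(np.sqrt(-2 * np.log(r)))  # circular SD
        assert sds[0] > sds[1] > sds[2]
        assert sds[2] < 0.1

    @pytest.mark.parametrize("method", ["bandpass_hilbert", "ssa_hilbert"])
    def test_mixture_attenuates_out_of_band_component(self, method):
        """10 Hz + 40 Hz mixture, band 30-50: the extracted component
        peaks at 40 Hz with the 10 Hz line attenuated by >= 20 dB."""
        t = np.arange(1000) / 1000.0
        x = (np.cos(2 * np.pi * 10 * t) + np.cos(2 * np.pi * 40 * t))[None, :]
        sig = TrialSignalSet(x, x.copy(), fs=1000.0)
        comp_x, _ = decompose(sig, method, (30.0, 50.0))
        spec = np.abs(np.fft.rfft(comp_x.component[0]))
        freqs = np.fft.rfftfreq(1000, 0.001)
        assert freqs[np.argmax(spec)] == pytest.approx(40.0, abs=1.0)
        atten_db = 20 * np.log10(spec[freqs == 40.0][0] / spec[freqs == 10.0][0])
        assert atten_db >= 20.0

    def test_band_outside_nyquist_rejected(self):
        sig = _tone(40.0)
        with pytest.raises(ValueError):
            decompose(sig, "bandpass_hilbert", (30.0, 600.0))
        with pytest.raises(ValueError):
            decompose(sig, "wavelet", (30.0, 50.0))


class TestEstimatePram:
    def test_recovers_synthesized_modulation(self, uncoupled_pram_signals):
        """20% synthesized PrAM is recovered within 2 percentage points
        from the filtered envelope and the true phase relation."""
        cfg, traj, sig = uncoupled_pram_signals
        _, comp_y = decompose(sig, "bandpass_hilbert", (25.0, 55.0))
        alpha_hat = estimate_pram(comp_y, traj.phase_relation())
        assert alpha_hat == pytest.approx(20.0, abs=2.0)

    def test_null_recovery_below_one_percent(self):
        """No amplitude modulation present (uncoupled pair, alpha = 0):
        the estimated modulation stays at the sub-percent level."""
        cfg = OscillatorPairConfig(
            omega_x=40.0, omega_y=43.0, kappa=0.0, n_trials=50, seed=2
        )
        traj = simulate_phase_pair(cfg)
        sig = synthesize_signals(traj, cfg)
        _, comp_y = decompose(sig, "bandpass_hilbert", (25.0, 55.0))
        alpha_hat = estimate_pram(comp_y, traj.phase_relation())
        assert alpha_hat <= 1.0

    def test_constant_amplitude_gives_zero(self):
        from phaselock.plv import AnalyticComponent

        n = 500
        comp = AnalyticComponent(
            component=np.ones((1, n)),
            inst_phase=np.zeros((1, n)),
            inst_amp=np.ones((1, n)),
            inst_freq=np.zeros((1, n)),
            method="bandpass_hilbert",
            band=(30, 50),
            fs=1000.0,
        )
        theta = np.linspace(-np.pi, np.pi, n)[None, :]
        assert estimate_pram(comp, theta) == 0.0
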