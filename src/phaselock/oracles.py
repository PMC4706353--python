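"""Closed-form and quadrature ground truths for the estimators.

Three oracles anchor the toolkit's validation:

* :func:`adler_expected_pl` — expected phase locking of the noiseless
  Adler dynamics dtheta/dt = dw + kappa*sin(theta).  Inside the Arnold
  tongue (|dw| <= kappa) locking is complete (PL = 1); outside, the
  stationary phase-relation density is p(theta) ~ 1/|dw + kappa*sin(theta)|
  and its mean resultant vector length has the closed form
  (|dw| - sqrt(dw^2 - kappa^2))/kappa (derivable by residue calculus; the
  quadrature version is provided as an independent cross-check).

* :func:`sideband_amplitude` — the modulation-sideband amplitudes induced
  by phase-relation-dependent frequency modulation (A*PL) and amplitude
  modulation (A*alpha/2, valid when PL = 0).

* :func:`analytic_coherence` — the expected coherence at the frequency
  where oscillator X's peak meets oscillator Y's modulation sideband, for
  signals corrupted by independent noise whose Fourier amplitudes are
  chi(2)-distributed (Rayleigh) with uniform phases.  Because the two
  channels' noises are independent, the expectation of the cross-spectral
  unit phasor factorizes into one phasor-consistency factor per channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate

__all__ = [
    "adler_expected_pl",
    "adler_expected_pl_quadrature",
    "sideband_amplitude",
    "NoiseCoherenceSpec",
    "spec_from_snr",
    "analytic_coherence",
]


def adler_expected_pl(delta_omega: float, kappa: float) -> float:
    """Expected phase locking (MRVL, unsquared) of the noiseless Adler model.

    Parameters are in Hz (any common unit works — only the ratio enters).
    Returns 1 inside the tongue (|delta_omega| <= kappa) and
    (|dw| - sqrt(dw^2 - k^2))/k outside; continuous at the tongue edge.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    dw = abs(delta_omega)
    if dw <= kappa:
        return 1.0
    if kappa == 0.0:
        return 0.0
    return (dw - np.sqrt(dw**2 - kappa**2)) / kappa


def adler_expected_pl_quadrature(delta_omega: float, kappa: float) -> float:
    """Quadrature cross-check of :func:`adler_expected_pl` (unlocked regime).

    Integrates the stationary density p(theta) ~ 1/|dw + kappa*sin(theta)|
    directly; only valid for |delta_omega| > kappa, where the density is
    normalizable.
    """
    dw = abs(delta_omega)
    if dw <= kappa:
        raise ValueError("quadrature form only applies outside the tongue")

    def dens(th: float) -> float:
        return 1.0 / abs(dw + kappa * np.sin(th))

    norm, _ = integrate.quad(dens, -np.pi, np.pi, limit=200)
    re, _ = integrate.quad(lambda th: np.cos(th) * dens(th), -np.pi, np.pi, limit=200)
    im, _ = integrate.quad(lambda th: np.sin(th) * dens(th), -np.pi, np.pi, limit=200)
    return float(np.hypot(re, im) / norm)


def sideband_amplitude(
    amplitude: float, pl: float, alpha: float
) -> tuple[float, float]:
    """Predicted modulation-sideband amplitudes (SM_PrFM, SM_PrAM).

    SM_PrFM = A*PL is the amplitude of the sideband that frequency
    modulation places at the partner's frequency; SM_PrAM = A*alpha/2 is
    the amplitude-modulation sideband, derived under PL = 0 (a warning is
    emitted when both pl > 0 and alpha > 0, where the PrAM formula is an
    approximation).
    """
    if not 0.0 <= pl <= 1.0:
        raise ValueError("pl must lie in [0, 1]")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if pl > 0 and alpha > 0:
        warnings.warn(
            "SM_PrAM = A*alpha/2 assumes PL = 0; with pl > 0 it is approximate",
            RuntimeWarning,
            stacklevel=2,
        )
    return amplitude * pl, amplitude * alpha / 2.0


@dataclass(frozen=True)
class NoiseCoherenceSpec:
    """Inputs of the noise-corrupted coherence integral.

    ``s_x`` is the Fourier amplitude of oscillator X's spectral peak and
    ``s_y_sideband`` the amplitude of Y's modulation sideband at that same
    frequency; ``noise_amp_scale`` scales the Rayleigh (chi, 2 dof)
    distributed noise amplitudes of both channels; ``phase_offset`` is the
    fixed phase relation between X and Y's sideband (it rotates the mean
    cross-phasor and leaves the coherence magnitude unchanged).
    """

    s_x: float
    s_y_sideband: float
    noise_amp_scale: float = 1.0
    phase_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.s_x < 0 or self.s_y_sideband < 0 or self.noise_amp_scale < 0:
            raise ValueError("amplitudes and noise scale must be >= 0")


def spec_from_snr(snr_x: float, snr_y_sideband: float) -> NoiseCoherenceSpec:
    """Build a spec from per-channel SNRs (relative power ratios).

    With unit-Rayleigh noise, E[A^2] = 2, and the SNR definition
    S^2/E[A^2] = SNR gives S = sqrt(2*SNR).
    """
    return NoiseCoherenceSpec(
        s_x=float(np.sqrt(2.0 * snr_x)),
        s_y_sideband=float(np.sqrt(2.0 * snr_y_sideband)),
        noise_amp_scale=1.0,
    )


def _channel_factor_quadrature(s_over_scale: float) -> float:
    """E[cos(arg(s + A*exp(i*phi)))] for Rayleigh A, uniform phi.

    The imaginary part vanishes by symmetry; the integral is the mean
    phasor length of one noisy channel.
    """
    s = s_over_scale
    if s == 0.0:
        return 0.0

    def integrand(phi: float, a: float) -> float:
        num = s + a * np.cos(phi)
        den = np.sqrt(s**2 + a**2 + 2.0 * s * a * np.cos(phi))
        return a * np.exp(-0.5 * a**2) * num / den / (2.0 * np.pi)

    val, err = integrate.dblquad(
        integrand, 0.0, np.inf, -np.pi, np.pi, epsabs=1e-10, epsrel=1e-9
    )
    if not np.isfinite(val) or err > 1e-4:
        raise RuntimeError("quadrature did not converge")
    return float(val)


def _montecarlo(spec: NoiseCoherenceSpec, n_draws: int, seed: int | None) -> float:
    rng = np.random.default_rng(seed)
    scale = spec.noise_amp_scale
    ax = rng.rayleigh(scale, n_draws)
    ay = rng.rayleigh(scale, n_draws)
    px = rng.uniform(-np.pi, np.pi, n_draws)
    py = rng.uniform(-np.pi, np.pi, n_draws)
    zx = spec.s_x + ax * np.exp(1j * px)
    zy = spec.s_y_sideband * np.exp(1j * spec.phase_offset) + ay * np.exp(1j * py)
    z = zx * np.conj(zy)
    return float(np.abs(np.mean(z / np.abs(z))))


def analytic_coherence(
    spec: NoiseCoherenceSpec,
    method: str = "quadrature",
    n_draws: int = 1_000_000,
    seed: int | None = None,
) -> float:
    """Expected coherence of two constant phasors in independent noise.

    Returns |E[exp(i*arg(Z_x * conj(Z_y)))]| where Z_c = S_c + noise_c with
    Rayleigh amplitudes and uniform phases.  For ``method="quadrature"``
    the independence of the two channels is used to factorize the
    expectation into per-channel phasor-consistency integrals; a
    non-convergent quadrature falls back to Monte Carlo with a warning.
    """
    if spec.noise_amp_scale == 0.0:
        # noise-free: the fixed phase relation survives exactly
        return 1.0 if (spec.s_x > 0 and spec.s_y_sideband > 0) else 0.0
    if method == "montecarlo":
        if n_draws < 1e5:
            raise ValueError("montecarlo requires n_draws >= 1e5")
        return _montecarlo(spec, int(n_draws), seed)
    if method != "quadrature":
        raise ValueError(f"unknown method {method!r}")
    try:
        cx = _channel_factor_quadrature(spec.s_x / spec.noise_amp_scale)
        cy = _channel_factor_quadrature(spec.s_y_sideband / spec.noise_amp_scale)
        return cx * cy
    except RuntimeError:
        warnings.warn(
            "quadrature failed to converge; falling back to Monte Carlo",
            RuntimeWarning,
            stacklevel=2,
        )
        return _montecarlo(spec, int(max(n_draws, 1_000_000)), seed)
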