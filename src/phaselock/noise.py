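"""Colored-noise generation by FFT spectral shaping.

Both generative models use 1/f^1.5 ("pink-ish") noise: as an intrinsic
instantaneous-frequency perturbation of the phase oscillators and as a
shared drive / extrinsic noise term for the spiking networks.  The noise is
produced by shaping seeded white Gaussian noise in the frequency domain with
an amplitude profile f^(-beta/2), so the power spectrum falls off as
1/f^beta.  The shaping filter is normalized analytically (not per
realization), so the output has unit variance in expectation and scaling is
deterministic.
"""

from __future__ import annotations

import numpy as np

__all__ = ["powerlaw_noise"]


def _shaping_amplitudes(n_samples: int, exponent: float) -> np.ndarray:
    """Amplitude profile a_k = k^(-exponent/2) for rfft bins, DC removed."""
    k = np.arange(n_samples // 2 + 1, dtype=float)
    amps = np.zeros_like(k)
    amps[1:] = k[1:] ** (-exponent / 2.0)
    return amps


def _unit_variance_norm(n_samples: int, amps: np.ndarray) -> float:
    # For white input w with Var=1, the shaped output s = irfft(rfft(w)*a)
    # has E[sum s_t^2] = a_0^2 + 2*sum_{0<k<N/2} a_k^2 + a_{N/2}^2 (N even),
    # which follows from E|W_k|^2 = N and Parseval for the rfft.
    sq = amps**2
    if n_samples % 2 == 0:
        total = sq[0] + 2.0 * sq[1:-1].sum() + sq[-1]
    else:
        total = sq[0] + 2.0 * sq[1:].sum()
    return float(np.sqrt(total / n_samples))


def powerlaw_noise(
    shape: tuple[int, ...],
    exponent: float = 1.5,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f**exponent along the last axis.

    The DC component is zeroed (output is zero-mean by construction up to the
    white-noise mean) and the output has unit variance in expectation; scale
    by the desired standard deviation at the call site.

    Parameters
    ----------
    shape
        Output shape; the last axis is time.
    exponent
        Spectral exponent beta of the 1/f**beta power law (1.5 throughout
        the toolkit; 0 would be white).
    rng, seed
        Pass an existing generator or a seed (``rng`` wins).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n = shape[-1]
    if n < 2:
        raise ValueError("need at least 2 samples of noise")
    if exponent == 0:
        return rng.standard_normal(shape)
    white = rng.standard_normal(shape)
    amps = _shaping_amplitudes(n, exponent)
    shaped = np.fft.irfft(np.fft.rfft(white, axis=-1) * amps, n=n, axis=-1)
    return shaped / _unit_variance_norm(n, amps)
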