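"""Fourier spectra and trial-normalized spectral coherence.

Per-trial discrete Fourier transforms (no taper, no padding), power and
cross-spectra, two coherence estimators and the finite-trial bias
correction:

* ``"eq14"``: classical magnitude coherence,
  |sum_n S_xy| / sqrt(sum_n S_xx * sum_n S_yy);
* ``"eq15"``: per-trial-normalized coherence,
  |1/N sum_n S_xy / sqrt(S_xx*S_yy)|, insensitive to amplitude
  correlations — the mean resultant vector length of the cross-spectral
  phases.  This is the default estimator throughout the toolkit.

Squared coherence is corrected for the finite trial count as
(Coh^2*N - 1)/(N - 1); corrected values may be slightly negative and are
reported without clipping so that null averages stay unbiased.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .oscillators import TrialSignalSet

__all__ = [
    "SpectralEstimate",
    "CoherenceSpectrum",
    "LockingEstimate",
    "spectra",
    "coherence_spectrum",
    "coherence_peak",
    "bias_correct_coh2",
    "corrected_peak",
]


@dataclass
class SpectralEstimate:
    """Per-trial Fourier coefficients and (cross-)spectra of a signal pair."""

    freqs: np.ndarray  # Hz
    s_x: np.ndarray  # complex, (n_trials, n_freqs)
    s_y: np.ndarray
    window: float  # seconds

    @property
    def n_trials(self) -> int:
        return self.s_x.shape[0]

    @property
    def s_xx(self) -> np.ndarray:
        return np.abs(self.s_x) ** 2

    @property
    def s_yy(self) -> np.ndarray:
        return np.abs(self.s_y) ** 2

    @property
    def s_xy(self) -> np.ndarray:
        return self.s_x * np.conj(self.s_y)


@dataclass
class CoherenceSpectrum:
    """Coherence per frequency together with the per-frequency unit count."""

    freqs: np.ndarray
    coh: np.ndarray
    n_trials: np.ndarray  # effective trial count per frequency
    formula: str
    window: float


@dataclass
class LockingEstimate:
    """A squared phase-locking number with its estimator identity.

    ``value`` is squared locking; bias-corrected values can be slightly
    negative (lower bound -1/(n_units - 1)), uncorrected values lie in
    [0, 1].  ``n_units`` counts trials for coherence and time points for
    PLV-type estimates.
    """

    value: float
    estimator: str
    bias_corrected: bool
    n_units: int
    peak_freq: float | None = None

    def __post_init__(self) -> None:
        if not self.bias_corrected and not -1e-12 <= self.value <= 1 + 1e-12:
            raise ValueError("uncorrected locking values must lie in [0, 1]")


def spectra(signals: TrialSignalSet, window: float) -> SpectralEstimate:
    """Per-trial DFT over non-overlapping windows of ``window`` seconds.

    Each trial is cut into floor(n_samples/n_win) windows and every window
    counts as one estimation unit (splitting 1 s trials into 0.2 s windows
    restricts the frequency resolution to 5 Hz).  No taper and no
    zero-padding are applied.
    """
    n_win_f = window * signals.fs
    n_win = int(round(n_win_f))
    if abs(n_win_f - n_win) > 1e-9 or n_win < 2:
        raise ValueError("window must be an integer number of samples (>= 2)")
    if n_win > signals.n_samples:
        raise ValueError("window exceeds the trial length")
    n_seg = signals.n_samples // n_win
    x = signals.x[:, : n_seg * n_win].reshape(-1, n_win)
    y = signals.y[:, : n_seg * n_win].reshape(-1, n_win)
    freqs = np.fft.rfftfreq(n_win, d=1.0 / signals.fs)
    return SpectralEstimate(
        freqs=freqs,
        s_x=np.fft.rfft(x, axis=1),
        s_y=np.fft.rfft(y, axis=1),
        window=float(window),
    )


def coherence_spectrum(
    est: SpectralEstimate, formula: str = "eq15"
) -> CoherenceSpectrum:
    """Coherence per frequency from per-trial (cross-)spectra.

    ``"eq14"`` normalizes the summed cross-spectrum by the summed
    auto-spectra; ``"eq15"`` (default) normalizes every trial's
    cross-spectral coefficient by that trial's auto-spectra before
    averaging.  For eq15, trials with zero auto-power at a frequency are
    excluded at that frequency with an adjusted count and a warning.
    """
    if est.n_trials < 2:
        raise ValueError("need at least 2 trials/windows for coherence")
    s_xx, s_yy, s_xy = est.s_xx, est.s_yy, est.s_xy
    n = est.n_trials
    if formula == "eq14":
        denom = np.sqrt(s_xx.sum(axis=0) * s_yy.sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            coh = np.abs(s_xy.sum(axis=0)) / denom
        coh = np.where(denom > 0, coh, 0.0)
        counts = np.full(coh.shape, n)
    elif formula == "eq15":
        denom = np.sqrt(s_xx * s_yy)
        # bins whose per-trial power is at rounding-noise level carry no
        # phase information; treat them as zero-power (relative threshold)
        tol_x = 1e-24 * s_xx.max(axis=1, keepdims=True)
        tol_y = 1e-24 * s_yy.max(axis=1, keepdims=True)
        valid = (s_xx > tol_x) & (s_yy > tol_y)
        if not valid.all():
            warnings.warn(
                "zero auto-power in some trials; those trials were excluded "
                "at the affected frequencies",
                RuntimeWarning,
                stacklevel=2,
            )
        ratio = np.where(valid, s_xy, 0.0) / np.where(valid, denom, 1.0)
        counts = valid.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            coh = np.abs(ratio.sum(axis=0)) / counts
        coh = np.where(counts > 0, coh, 0.0)
    else:
        raise ValueError(f"unknown coherence formula {formula!r}")
    return CoherenceSpectrum(
        freqs=est.freqs,
        coh=coh,
        n_trials=counts,
        formula=formula,
        window=est.window,
    )


def coherence_peak(
    cohspec: CoherenceSpectrum, band: tuple[float, float]
) -> LockingEstimate:
    """Maximum squared coherence over ``band`` (Hz), peak frequency recorded.

    DC and Nyquist bins are excluded from the search; ties are broken
    toward the lower frequency.
    """
    lo, hi = band
    nyq = cohspec.freqs[-1]
    mask = (cohspec.freqs >= lo) & (cohspec.freqs <= hi)
    mask &= (cohspec.freqs > 0) & (cohspec.freqs < nyq)
    if not mask.any():
        raise ValueError("empty frequency band")
    idx = np.flatnonzero(mask)
    best = idx[int(np.argmax(cohspec.coh[idx]))]  # argmax -> lowest freq on ties
    return LockingEstimate(
        value=float(cohspec.coh[best] ** 2),
        estimator=f"coh2_{cohspec.formula}",
        bias_corrected=False,
        n_units=int(cohspec.n_trials[best]),
        peak_freq=float(cohspec.freqs[best]),
    )


def bias_correct_coh2(coh2: float, n_trials: int) -> float:
    """Trial-count bias correction (Coh^2*N - 1)/(N - 1)."""
    if n_trials < 2:
        raise ValueError("bias correction requires at least 2 trials")
    if not 0.0 <= coh2 <= 1.0 + 1e-12:
        raise ValueError("uncorrected coh2 must lie in [0, 1]")
    return (coh2 * n_trials - 1.0) / (n_trials - 1.0)


def corrected_peak(
    cohspec: CoherenceSpectrum, band: tuple[float, float]
) -> LockingEstimate:
    """Convenience: bias-corrected squared coherence peak over ``band``."""
    est = coherence_peak(cohspec, band)
    return LockingEstimate(
        value=bias_correct_coh2(est.value, est.n_units),
        estimator=est.estimator,
        bias_corrected=True,
        n_units=est.n_units,
        peak_freq=est.peak_freq,
    )
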