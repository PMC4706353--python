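"""Reduced-scale sweeps comparing coherence, PLV and transfer entropy.

Every sweep follows a paired design: within one sweep cell, all estimators
consume the identical signal realizations (same simulation, same noise
draw), so differences between estimators are estimator-driven rather than
sampling-driven.  Results are tidy tables (one row per cell/condition)
plus a manifest of seeds and configuration.

* :func:`run_detuning_sweep` — phase-oscillator detuning sweep (the 1/2
  cross-section of the Arnold tongue at fixed coupling), with extrinsic
  noise levels and optional PrAM; includes the analytic coherence
  prediction for the noiseless-phase-dynamics regime.
* :func:`run_drive_sweep` — PING network pairs with a drive difference to
  network Y's excitatory cells (the network detuning knob), plus
  spike-train transfer entropy.
* :func:`run_connectivity_grid` — factorial E→E x E→I cross-connection
  grid at fixed drive difference, recording TE, coh², PLV² and the
  estimated PrAM strength.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import coherence as coh
from .networks import (
    NetworkPairConfig,
    population_signal_pair,
    simulate_ping_pair,
)
from .oracles import adler_expected_pl, analytic_coherence, spec_from_snr
from .oscillators import (
    OscillatorPairConfig,
    add_extrinsic_noise,
    simulate_phase_pair,
    synthesize_signals,
)
from .plv import (
    bias_correct_plv2,
    decompose,
    estimate_pram,
    expected_phase_locking,
    expected_phase_locking_signals,
    plv as _plv,
)
from .te import network_te

__all__ = [
    "SweepResult",
    "run_detuning_sweep",
    "run_drive_sweep",
    "run_connectivity_grid",
    "explained_variance",
]

GAMMA_PEAK_BAND = (20.0, 60.0)
GAMMA_PLV_BAND = (25.0, 55.0)


@dataclass
class SweepResult:
    """A tidy sweep table plus the run manifest (seeds, configuration)."""

    table: pd.DataFrame
    manifest: dict

    def write(self, path: str | Path) -> None:
        """Write the table as TSV and the manifest as JSON next to it."""
        path = Path(path)
        self.table.to_csv(path, sep="\t", index=False)
        with open(path.with_suffix(path.suffix + ".manifest.json"), "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)


def explained_variance(a_series, b_series) -> float:
    """Squared Pearson correlation between two equal-length series."""
    a = np.asarray(a_series, dtype=float)
    b = np.asarray(b_series, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("need two equal-length 1-D series of length >= 3")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("explained variance undefined for a constant series")
    r = np.corrcoef(a, b)[0, 1]
    return float(r**2)


def _coh2_corrected(signals, window: float, band) -> tuple[float, float]:
    spec = coh.spectra(signals, window)
    est = coh.corrected_peak(coh.coherence_spectrum(spec, "eq15"), band)
    return est.value, est.peak_freq


def _plv2_corrected(signals, band) -> float:
    comp_x, comp_y = decompose(signals, "bandpass_hilbert", band)
    raw = _plv(comp_x.inst_phase, comp_y.inst_phase)
    return bias_correct_plv2(raw.value, raw.n_units)


def _oracle_coh2(clean, pl: float, snr: float, amplitude: float) -> float:
    """Analytic coherence prediction at the X-peak/Y-sideband frequency.

    The generative side supplies the clean single-sided amplitudes: Y's
    sideband amplitude at X's peak bin relative to Y's own carrier sets
    the sideband SNR, given that noise is calibrated at each channel's
    carrier.  Valid for the noiseless-phase-dynamics regime.
    """
    spec_x = np.abs(np.fft.rfft(clean.x, axis=1)).mean(axis=0)
    spec_y = np.abs(np.fft.rfft(clean.y, axis=1)).mean(axis=0)
    spec_x[0] = spec_y[0] = 0.0
    kx = int(np.argmax(spec_x))
    carrier_y = spec_y.max()
    sideband_y = spec_y[kx]
    snr_sideband = snr * (sideband_y / carrier_y) ** 2
    value = analytic_coherence(spec_from_snr(snr, snr_sideband))
    return float(value**2)


def run_detuning_sweep(
    config: OscillatorPairConfig | None = None,
    detunings=np.arange(0.0, 8.25, 0.25),
    snr_list=(500.0, 50.0, 10.0, 5.0, 2.0),
    pram_list=(0.0,),
    windows=(1.0, 0.2),
    peak_band=GAMMA_PEAK_BAND,
    plv_band=GAMMA_PLV_BAND,
    seed: int = 0,
    with_oracle: bool | None = None,
) -> SweepResult:
    """Detuning sweep: omega_X fixed, omega_Y stepped upward.

    For each (detuning, PrAM, SNR) cell: simulate phases once, synthesize
    signals, add calibrated white noise, and record expected PL², the
    bias-corrected coh² peak for each window length, the bias-corrected
    PLV², and (noiseless-phase regime only) the analytic coherence
    prediction.  ``snr_list`` may contain ``inf`` for the noiseless case.
    """
    if config is None:
        config = OscillatorPairConfig(kappa=0.75, n_trials=100)
    if with_oracle is None:
        with_oracle = config.intrinsic_noise_scale == 0
    rows = []
    for i, dw in enumerate(detunings):
        cfg = replace(
            config,
            omega_y=config.omega_x + float(dw),
            pram_alpha=0.0,
            seed=seed + 1000 * i,
        )
        traj = simulate_phase_pair(cfg)
        pl2 = expected_phase_locking(traj).value
        pl_analytic = (
            adler_expected_pl(dw, cfg.kappa)
            if cfg.intrinsic_noise_scale == 0
            else np.nan
        )
        for alpha in pram_list:
            clean = synthesize_signals(traj, replace(cfg, pram_alpha=float(alpha)))
            for j, snr in enumerate(snr_list):
                if np.isinf(snr):
                    noisy = clean
                else:
                    noisy = add_extrinsic_noise(
                        clean, float(snr), "white", seed=seed + 1000 * i + j + 1
                    )
                row = {
                    "detuning": float(dw),
                    "pram_alpha": float(alpha),
                    "snr": float(snr),
                    "pl2": pl2,
                    "pl_analytic": pl_analytic,
                    "plv2": _plv2_corrected(noisy, plv_band),
                }
                for w in windows:
                    c2, pf = _coh2_corrected(noisy, w, peak_band)
                    key = f"coh2_w{w:g}".replace(".", "p")
                    row[key] = c2
                    row[f"peakf_w{w:g}".replace(".", "p")] = pf
                if with_oracle and np.isfinite(snr):
                    row["coh2_pred"] = _oracle_coh2(
                        clean, pl_analytic, float(snr), cfg.amplitude
                    )
                else:
                    row["coh2_pred"] = np.nan
                rows.append(row)
    return SweepResult(
        table=pd.DataFrame(rows),
        manifest={
            "sweep": "detuning",
            "seed": seed,
            "config": asdict(config),
            "detunings": list(map(float, detunings)),
            "snr_list": list(map(float, snr_list)),
            "pram_list": list(map(float, pram_list)),
        },
    )


def run_drive_sweep(
    net_config: NetworkPairConfig | None = None,
    drive_deltas=(0.0, 3.0, 6.0, 9.0, 12.0),
    snr_list=(0.3, 2.2, 4.8, 9.1, 36.2),
    peak_band=GAMMA_PEAK_BAND,
    plv_band=GAMMA_PLV_BAND,
    n_te_neurons: int = 20,
    seed: int = 0,
) -> SweepResult:
    """PING drive-difference sweep with network transfer entropy.

    For each drive difference: one network-pair simulation; expected PL²
    from the clean population signals; network TE (both directions
    summed) from the spike rasters; per SNR, pink extrinsic noise is
    added to the population signals and coh²/PLV² recorded.  The default
    drive grid spans 0-12 mV: at this network's drive-to-frequency gain
    that carries the pair from inside the effective locking range into
    free frequency drift.
    """
    if net_config is None:
        net_config = NetworkPairConfig(n_trials=60)
    rows = []
    for i, delta in enumerate(drive_deltas):
        # common random numbers: identical weight draw and noise streams in
        # every cell, so only the drive difference varies between cells
        cfg = replace(net_config, drive_rs_delta=float(delta), seed=seed)
        rast_x, rast_y = simulate_ping_pair(cfg)
        clean = population_signal_pair(rast_x, rast_y)
        pl2 = expected_phase_locking_signals(clean).value
        te_xy, te_yx = network_te(
            rast_x, rast_y, n_neurons=n_te_neurons, seed=seed + 1
        )
        te_sum = te_xy.combined + te_yx.combined
        for j, snr in enumerate(snr_list):
            noisy = add_extrinsic_noise(
                clean, float(snr), "pink15", seed=seed + 2 + j
            )
            c2, pf = _coh2_corrected(noisy, 1.0, peak_band)
            rows.append(
                {
                    "drive_delta": float(delta),
                    "snr": float(snr),
                    "pl2": pl2,
                    "te": te_sum,
                    "coh2": c2,
                    "peak_freq": pf,
                    "plv2": _plv2_corrected(noisy, plv_band),
                }
            )
    return SweepResult(
        table=pd.DataFrame(rows),
        manifest={
            "sweep": "drive",
            "seed": seed,
            "config": asdict(net_config),
            "drive_deltas": list(map(float, drive_deltas)),
            "snr_list": list(map(float, snr_list)),
            "n_te_neurons": n_te_neurons,
        },
    )


def run_connectivity_grid(
    net_config: NetworkPairConfig | None = None,
    ee_grid=(0.0, 0.007, 0.014, 0.02),
    ei_grid=(0.0, 0.007, 0.014, 0.02),
    snr: float = 10.0,
    drive_delta: float = 8.0,
    peak_band=GAMMA_PEAK_BAND,
    plv_band=GAMMA_PLV_BAND,
    n_te_neurons: int = 20,
    seed: int = 0,
) -> SweepResult:
    """Factorial cross-connection grid at a fixed drive difference.

    Records TE (directions summed), bias-corrected coh² and PLV² on
    pink-noise-corrupted population signals at one SNR, the expected PL²,
    and the estimated PrAM strength of network Y's signal.  The default
    ``drive_delta`` of 8 mV produces an intrinsic frequency difference of
    about 2 Hz between the uncoupled networks at this network's realized
    drive-to-frequency gain, placing the grid in the partially
    synchronized regime.
    """
    if net_config is None:
        net_config = NetworkPairConfig(n_trials=60)
    rows = []
    cell = 0
    for ee in ee_grid:
        for ei in ei_grid:
            # common random numbers across cells: only the cross-network
            # connection strengths differ between grid cells
            cfg = replace(
                net_config,
                w_cross_ee=float(ee),
                w_cross_ei=float(ei),
                drive_rs_delta=float(drive_delta),
                seed=seed,
            )
            rast_x, rast_y = simulate_ping_pair(cfg)
            clean = population_signal_pair(rast_x, rast_y)
            pl2 = expected_phase_locking_signals(clean).value
            te_xy, te_yx = network_te(
                rast_x, rast_y, n_neurons=n_te_neurons, seed=seed + 1
            )
            noisy = add_extrinsic_noise(
                clean, snr, "pink15", seed=seed + 2
            )
            c2, _ = _coh2_corrected(noisy, 1.0, peak_band)
            comp_x, comp_y = decompose(noisy, "bandpass_hilbert", plv_band)
            theta = comp_x.inst_phase - comp_y.inst_phase
            raw = _plv(comp_x.inst_phase, comp_y.inst_phase)
            rows.append(
                {
                    "ee": float(ee),
                    "ei": float(ei),
                    "pl2": pl2,
                    "te": te_xy.combined + te_yx.combined,
                    "coh2": c2,
                    "plv2": bias_correct_plv2(raw.value, raw.n_units),
                    "pram_hat": estimate_pram(comp_y, theta),
                }
            )
            cell += 1
    return SweepResult(
        table=pd.DataFrame(rows),
        manifest={
            "sweep": "connectivity",
            "seed": seed,
            "config": asdict(net_config),
            "ee_grid": list(map(float, ee_grid)),
            "ei_grid": list(map(float, ei_grid)),
            "snr": snr,
            "drive_delta": drive_delta,
            "n_te_neurons": n_te_neurons,
        },
    )
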