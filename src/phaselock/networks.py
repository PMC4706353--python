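"""Two weakly coupled excitatory–inhibitory spiking networks (PING gamma).

Each network holds regular-spiking (RS, excitatory) and fast-spiking (FS,
inhibitory) Izhikevich neurons,

    dv/dt = 0.04 v^2 + 5 v + 140 - u + I,   du/dt = a (b v - u),
    if v >= 30 mV: v <- c, u <- u + d,

integrated by the Euler method at 1 ms steps.  All-to-all synapses are
exponentially decaying gating variables (AMPA 2 ms for RS, GABA-A 8 ms for
FS) that reset to 1 when the presynaptic neuron fires; pairwise strengths
are drawn once, uniformly between 0 and the per-type maximum; all
connections have a 1 ms conduction delay.  Cross-network coupling is
excitatory only, onto the other network's FS (E→I) and RS (E→E) cells.

RS cells are driven by a fixed current plus private white noise plus a
1/f^1.5 noise shared within a network but uncorrelated between networks
(the network analogue of intrinsic phase noise); FS cells receive a fixed
current plus private white noise.  The reciprocal RS→FS→RS loop then
generates pyramidal–interneuron gamma.  A population field-like signal is
the demeaned, Gaussian-smoothed sum of RS spike trains.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .noise import powerlaw_noise
from .oscillators import TrialSignalSet

__all__ = [
    "NetworkPairConfig",
    "SpikeRaster",
    "simulate_ping_pair",
    "population_signal",
    "spectral_peak_frequency",
    "intrinsic_frequency_difference",
]


@dataclass(frozen=True)
class NetworkPairConfig:
    """All parameters of the coupled PING network pair.

    Voltages and synaptic strengths are in mV; times in ms unless noted.
    ``drive_rs_delta`` is added to the RS drive of network Y only and is
    the detuning knob (gamma frequency follows excitatory drive).
    """

    n_rs: int = 400
    n_fs: int = 100
    izh_rs: tuple[float, float, float, float] = (0.02, 0.2, -65.0, 8.0)
    izh_fs: tuple[float, float, float, float] = (0.1, 0.2, -65.0, 2.0)
    w_rs_fs: float = 0.45  # within-network E->I max strength
    w_rs_rs: float = 0.05
    w_fs_rs: float = -0.35
    w_fs_fs: float = -0.2
    tau_ampa: float = 2.0  # ms
    tau_gaba: float = 8.0  # ms
    w_cross_ei: float = 0.015  # cross-network RS->FS max strength
    w_cross_ee: float = 0.007  # cross-network RS->RS max strength
    delay_ms: float = 1.0
    drive_rs: float = 10.0
    drive_fs: float = 3.5
    drive_rs_delta: float = 0.0
    noise_private_sd: float = 3.5
    noise_shared_sd: float = 3.5
    dt_ms: float = 1.0
    trial_duration: float = 1.3  # s
    discard: float = 0.3  # s
    n_trials: int = 300
    seed: int = 0
    bidirectional: bool = True

    def __post_init__(self) -> None:
        if self.n_rs <= 0 or self.n_fs <= 0:
            raise ValueError("neuron counts must be positive")
        if self.delay_ms < self.dt_ms:
            raise ValueError("conduction delay must be at least one step")
        if self.trial_duration <= self.discard:
            raise ValueError("trial_duration must exceed discard")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    @property
    def n_total(self) -> int:
        return self.n_rs + self.n_fs


@dataclass
class SpikeRaster:
    """Binary spike occupancy (neuron, trial, 1 ms bin) for one network."""

    occupancy: np.ndarray  # bool, (n_neurons, n_trials, n_bins)
    is_rs: np.ndarray  # bool, (n_neurons,)
    bin_ms: float = 1.0

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        self.is_rs = np.asarray(self.is_rs, dtype=bool)
        if self.occupancy.ndim != 3:
            raise ValueError("occupancy must be (n_neurons, n_trials, n_bins)")
        if self.is_rs.shape != (self.occupancy.shape[0],):
            raise ValueError("is_rs must have one entry per neuron")

    @property
    def n_neurons(self) -> int:
        return self.occupancy.shape[0]

    @property
    def n_trials(self) -> int:
        return self.occupancy.shape[1]

    @property
    def n_bins(self) -> int:
        return self.occupancy.shape[2]

    def events(self, network: str = "") -> pd.DataFrame:
        """Spike events as a tidy table (network, neuron, type, trial, t_ms)."""
        neuron, trial, t_bin = np.nonzero(self.occupancy)
        return pd.DataFrame(
            {
                "network": network,
                "neuron": neuron,
                "type": np.where(self.is_rs[neuron], "RS", "FS"),
                "trial": trial,
                "t_ms": t_bin * self.bin_ms,
            }
        )


def _weight_matrix(config: NetworkPairConfig, rng: np.random.Generator) -> np.ndarray:
    """W[post, pre] for the combined two-network system, drawn once."""
    n = config.n_total
    n_rs = config.n_rs
    w = np.zeros((2 * n, 2 * n), dtype=np.float64)

    def fill(post_sl, pre_sl, max_strength):
        block = rng.uniform(0.0, 1.0, (post_sl.stop - post_sl.start,
                                       pre_sl.stop - pre_sl.start))
        w[post_sl, pre_sl] = block * max_strength

    for net in (0, 1):
        rs = slice(net * n, net * n + n_rs)
        fs = slice(net * n + n_rs, (net + 1) * n)
        fill(fs, rs, config.w_rs_fs)
        fill(rs, rs, config.w_rs_rs)
        fill(rs, fs, config.w_fs_rs)
        fill(fs, fs, config.w_fs_fs)
    cross = [(0, 1)] + ([(1, 0)] if config.bidirectional else [])
    for pre_net, post_net in cross:
        pre_rs = slice(pre_net * n, pre_net * n + n_rs)
        post_rs = slice(post_net * n, post_net * n + n_rs)
        post_fs = slice(post_net * n + n_rs, (post_net + 1) * n)
        fill(post_fs, pre_rs, config.w_cross_ei)
        fill(post_rs, pre_rs, config.w_cross_ee)
    np.fill_diagonal(w, 0.0)  # no self-connections
    return w.astype(np.float32)


def simulate_ping_pair(
    config: NetworkPairConfig,
) -> tuple[SpikeRaster, SpikeRaster]:
    """Simulate the coupled network pair; returns post-discard rasters (X, Y).

    Trials are integrated in parallel; each trial has independent noise and
    an independent shared 1/f^1.5 drive realization per network, while the
    synaptic strengths are drawn once per simulation.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_total
    n2 = 2 * n
    nt = config.n_trials
    n_steps = int(round(config.trial_duration * 1000.0 / config.dt_ms))
    n_disc = int(round(config.discard * 1000.0 / config.dt_ms))

    w = _weight_matrix(config, rng)

    a = np.empty(n2, dtype=np.float32)
    b = np.empty(n2, dtype=np.float32)
    c = np.empty(n2, dtype=np.float32)
    d = np.empty(n2, dtype=np.float32)
    is_rs = np.zeros(n2, dtype=bool)
    decay = np.empty(n2, dtype=np.float32)
    i_base = np.empty(n2, dtype=np.float32)
    for net in (0, 1):
        rs = slice(net * n, net * n + config.n_rs)
        fs = slice(net * n + config.n_rs, (net + 1) * n)
        for sl, params in ((rs, config.izh_rs), (fs, config.izh_fs)):
            a[sl], b[sl], c[sl], d[sl] = params
        is_rs[rs] = True
        decay[rs] = np.exp(-config.dt_ms / config.tau_ampa)
        decay[fs] = np.exp(-config.dt_ms / config.tau_gaba)
        i_base[rs] = config.drive_rs + (config.drive_rs_delta if net == 1 else 0.0)
        i_base[fs] = config.drive_fs

    # shared 1/f^1.5 drive: one realization per network per trial, RS only
    shared = (
        config.noise_shared_sd
        * powerlaw_noise((2, nt, n_steps), 1.5, rng=rng)
    ).astype(np.float32)

    v = np.full((n2, nt), -65.0, dtype=np.float32)
    u = b[:, None] * v
    gate = np.zeros((n2, nt), dtype=np.float32)
    gate_prev = np.zeros_like(gate)  # 1 ms conduction delay

    spikes = np.zeros((n2, nt, n_steps - n_disc), dtype=bool)
    dt = np.float32(config.dt_ms)
    sd = np.float32(config.noise_private_sd)
    net_of = np.repeat(np.arange(2), n)

    for t in range(n_steps):
        i_syn = w @ gate_prev
        i_noise = sd * rng.standard_normal((n2, nt), dtype=np.float32)
        i_total = i_base[:, None] + i_noise + i_syn
        i_total[is_rs] += shared[net_of[is_rs], :, t]
        v = v + dt * (0.04 * v * v + 5.0 * v + 140.0 - u + i_total)
        u = u + dt * a[:, None] * (b[:, None] * v - u)
        fired = v >= 30.0
        v = np.where(fired, c[:, None], v)
        u = np.where(fired, u + d[:, None], u)
        gate_prev = gate
        gate = gate * decay[:, None]
        gate[fired] = 1.0
        if t >= n_disc:
            spikes[:, :, t - n_disc] = fired
        if not np.isfinite(v).all():
            bad = np.argwhere(~np.isfinite(v))
            raise FloatingPointError(
                f"membrane state diverged at step {t} for (neuron, trial) "
                f"{bad[0].tolist()}"
            )

    rasters = []
    for net in (0, 1):
        sl = slice(net * n, (net + 1) * n)
        rasters.append(
            SpikeRaster(spikes[sl], is_rs[sl], bin_ms=config.dt_ms)
        )
    return rasters[0], rasters[1]


def population_signal(raster: SpikeRaster) -> np.ndarray:
    """Field-like population signal: summed RS spikes, demeaned, smoothed.

    Per trial, RS spike indicators are summed per 1 ms bin, demeaned, and
    convolved with a Gaussian kernel (SD 3 ms, truncated at ±4 SD and
    renormalized).  Returns an (n_trials, n_bins) array at 1000 Hz.
    """
    if raster.n_neurons == 0 or raster.n_bins == 0:
        raise ValueError("empty raster")
    if not raster.is_rs.any():
        raise ValueError("raster contains no RS neurons")
    counts = raster.occupancy[raster.is_rs].sum(axis=0).astype(float)
    counts -= counts.mean(axis=1, keepdims=True)
    sd_bins = 3.0 / raster.bin_ms
    half = int(np.ceil(4 * sd_bins))
    tt = np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (tt / sd_bins) ** 2)
    kernel /= kernel.sum()
    return sps.fftconvolve(counts, kernel[None, :], mode="same", axes=1)


def population_signal_pair(
    raster_x: SpikeRaster, raster_y: SpikeRaster
) -> TrialSignalSet:
    """Population signals of both networks bundled as a TrialSignalSet."""
    fs = 1000.0 / raster_x.bin_ms
    return TrialSignalSet(
        population_signal(raster_x), population_signal(raster_y), fs=fs
    )


def spectral_peak_frequency(
    signals: np.ndarray, fs: float, band: tuple[float, float] = (30.0, 80.0)
) -> float:
    """Peak frequency (Hz) of the trial-averaged power spectrum in ``band``."""
    power = np.mean(np.abs(np.fft.rfft(signals, axis=-1)) ** 2, axis=0)
    freqs = np.fft.rfftfreq(signals.shape[-1], d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():
        raise ValueError("search band contains no frequency bins")
    idx = np.flatnonzero(mask)
    return float(freqs[idx[np.argmax(power[idx])]])


def intrinsic_frequency_difference(
    config: NetworkPairConfig,
    drive_delta_grid,
    band: tuple[float, float] = (30.0, 80.0),
) -> pd.DataFrame:
    """Intrinsic (uncoupled) frequency difference vs. RS drive difference.

    Cross-network strengths are forced to zero so the two networks run at
    their natural frequencies; for each drive difference, the difference
    of the trial-averaged spectral peak frequencies of the two population
    signals is returned.
    """
    rows = []
    for delta in drive_delta_grid:
        cfg = replace(
            config, w_cross_ee=0.0, w_cross_ei=0.0, drive_rs_delta=float(delta)
        )
        rx, ry = simulate_ping_pair(cfg)
        fs = 1000.0 / rx.bin_ms
        f_x = spectral_peak_frequency(population_signal(rx), fs, band)
        f_y = spectral_peak_frequency(population_signal(ry), fs, band)
        rows.append(
            {"drive_delta": float(delta), "f_x": f_x, "f_y": f_y,
             "delta_f": f_y - f_x}
        )
    return pd.DataFrame(rows)
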