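"""Two coupled PING networks: gamma generation and phase locking.

Simulates a pair of excitatory-inhibitory Izhikevich networks that
generate pyramidal-interneuron gamma, extracts the field-like population
signals, and shows (i) the gamma-band spectral peak, (ii) the coupling
of spike timing to the population phase, and (iii) how cross-network
excitatory-to-inhibitory connections create phase locking between the
two networks.
"""

import numpy as np
from dataclasses import replace
from scipy.signal import hilbert

from phaselock import (
    NetworkPairConfig,
    expected_phase_locking_signals,
    population_signal,
    population_signal_pair,
    simulate_ping_pair,
    spectral_peak_frequency,
)

cfg = NetworkPairConfig(n_trials=15, seed=7)
rast_x, rast_y = simulate_ping_pair(cfg)
sig_x = population_signal(rast_x)
rate = rast_x.occupancy[rast_x.is_rs].mean() * 1000
peak = spectral_peak_frequency(sig_x, 1000.0, (20.0, 80.0))
print(f"network X: RS rate {rate:.1f} Hz, population peak {peak:.0f} Hz")

phase = np.angle(hilbert(sig_x, axis=1))
spikes = rast_x.occupancy[rast_x.is_rs]
vs = np.abs(np.exp(1j * np.broadcast_to(phase[None], spikes.shape)[spikes]).mean())
print(f"RS spike-phase vector strength: {vs:.3f} (spikes ride the gamma cycle)")

print("\ncross-network E->I strength vs. phase locking of the two fields:")
for ei in (0.0, 0.015, 0.05):
    c = replace(cfg, w_cross_ei=ei, w_cross_ee=0.0, seed=11)
    ra, rb = simulate_ping_pair(c)
    pl2 = expected_phase_locking_signals(population_signal_pair(ra, rb)).value
    print(f"  E->I max = {ei:5.3f} mV  ->  PL^2 = {pl2:.4f}")
print("\nStronger excitatory drive onto the partner's interneurons pulls"
      "\nthe two gamma rhythms into partial synchronization.")
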