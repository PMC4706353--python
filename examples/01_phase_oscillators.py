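"""Coupled phase oscillators: simulated locking versus the Adler oracle.

Simulates two unidirectionally coupled phase oscillators at several
detunings and compares the expected phase locking (the mean resultant
vector length of the simulated phase relations) with the closed-form
value from the Adler equation.  Inside the Arnold tongue (|detuning| <=
coupling) locking is complete; outside it decays as the oscillators
precess.
"""

import numpy as np

from phaselock import (
    OscillatorPairConfig,
    adler_expected_pl,
    resultant_length,
    simulate_phase_pair,
)

kappa = 0.75
print(f"coupling kappa = {kappa} Hz; 100 trials x 3 s per detuning")
print(f"{'detuning':>9} {'simulated PL':>13} {'Adler PL':>9}")
for dw in (0.0, 0.5, 1.0, 2.0, 4.0, 8.0):
    cfg = OscillatorPairConfig(
        omega_x=40.0, omega_y=40.0 + dw, kappa=kappa,
        trial_duration=5.0, discard=2.0, n_trials=100, seed=int(10 * dw),
    )
    traj = simulate_phase_pair(cfg)
    pl_sim = resultant_length(traj.phase_relation())
    pl_true = adler_expected_pl(dw, kappa)
    print(f"{dw:>7.2f}Hz {pl_sim:>13.4f} {pl_true:>9.4f}")
print(
    "\nPL = 1 inside the tongue (detuning <= 0.75 Hz); outside, the"
    "\nsimulated mean resultant vector length follows the analytic"
    "\nstationary-density prediction (dw - sqrt(dw^2 - k^2))/k."
)
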