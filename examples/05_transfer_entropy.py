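"""Delayed transfer entropy on spike trains.

First a constructed example with a known answer: a spike train copied
with a 5 ms delay, where TE peaks exactly at the copy delay and equals
the train's conditional entropy rate.  Then network-level TE between two
coupled PING networks, compared with its uncoupled control.
"""

import numpy as np
from dataclasses import replace

from phaselock import (
    NetworkPairConfig,
    independence_null_bound,
    network_te,
    simulate_ping_pair,
    transfer_entropy_pair,
)

rng = np.random.default_rng(0)
i_train = (rng.random(200_000) < 0.05).astype(np.int8)
j_train = np.roll(i_train, 5)
res = transfer_entropy_pair(i_train, j_train)
best = res.delays[np.argmax(res.te_per_delay)]
print("delayed-copy pair (5 ms):")
print(f"  TE peaks at delay {best} ms with {res.te_per_delay.max():.4f} bits"
      f" (entropy rate of the train: "
      f"{-(0.05*np.log2(0.05) + 0.95*np.log2(0.95)):.4f} bits)")

print("\nnetwork-level TE (20 excitatory neurons per network, both directions):")
cfg = NetworkPairConfig(n_trials=20, seed=42)
for tag, kw in (("coupled (default)", {}),
                ("uncoupled", dict(w_cross_ee=0.0, w_cross_ei=0.0))):
    rx, ry = simulate_ping_pair(replace(cfg, **kw))
    te_xy, te_yx = network_te(rx, ry, n_neurons=20, seed=1)
    total = te_xy.combined + te_yx.combined
    print(f"  {tag:18s}: TE(X->Y)+TE(Y->X) = {total:.5f} bits")
n_bins = 20 * 1000
print(f"  single-pair independence envelope (for scale): "
      f"{independence_null_bound(n_bins):.5f} bits")
print("\nThe uncoupled pair is the null reference: its TE is pure plugin"
      "\nbias. Coupling raises the pair-averaged information flow above it.")
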