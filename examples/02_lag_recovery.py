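"""Recover a known followership lag from a one-way coupled dyad.

The subject copies 80 % of the actor's motion with a 2 s delay. The
cross-correlation of the two kinetic-energy series should peak at
+2 s (positive lag = subject moves after the actor), and its centre of
mass should land within half a second of the true lag.
"""

import numpy as np

from dyadsync import (
    DyadSimParams,
    center_of_mass,
    cross_correlation,
    gen_energy_dyad,
    synchrony_score,
)

de, gt = gen_energy_dyad(DyadSimParams(
    duration=200, coupling_sa=0.8, lag_sa=2.0, noise_sd=0.1, seed=1))
cc = cross_correlation(de.subject, de.actor, max_lag=int(15 * de.fps), fps=de.fps)

print(f"true lag        = +{gt['lag_sa']:.1f} s")
print(f"argmax c(tau)   = {cc.peak_lag_seconds:+.2f} s")
print(f"centre of mass  = {center_of_mass(cc, T=15.0):+.2f} s")
print(f"synchrony c(0)  = {synchrony_score(cc):+.3f} (low: coupling is lagged, not simultaneous)")
print(f"peak height     = {cc.values.max():.3f}")
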