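"""Jitter band power tracks the high-frequency content of motion.

Jitter — rapid 1.5-5 Hz weaving of a follower's motion — is measured as
spectral power of the energy series in that band. Increasing the
generator's jitter amplitude must increase the measured band power.
"""

from dyadsync import DyadSimParams, band_power, gen_energy_dyad, power_spectrum

print("jitter_amp -> band power (1.5-5 Hz), fraction of non-DC power")
for amp in (0.0, 0.3, 0.6, 1.2):
    de, _ = gen_energy_dyad(DyadSimParams(
        duration=120, coupling_sa=0.6, lag_sa=1.5, jitter_amp=amp, seed=5))
    spec = power_spectrum(de.subject, de.fps)
    bp = band_power(spec)
    frac = band_power(spec, normalize=True)
    print(f"  {amp:4.1f}      -> {bp:8.2f}  ({100 * frac:.0f} %)")
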