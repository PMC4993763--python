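"""Power spectrum of motion energy and the high-frequency jitter band.

The spectrum describes what portion of the kinetic energy fluctuation
comes from motion at each frequency. "Jitter" — rapid weaving of a
follower's motion around the leader's — shows up as power in the
1.5–5 Hz band of the energy series and serves as a kinematic marker of
followership.

Convention: one-sided periodogram with ``P[k] = |X[k]|^2 / N^2``, doubled
at interior frequencies, so the total power over all bins equals the mean
square of the (detrended) series and the non-DC total equals its
variance (Parseval).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .errors import DomainError

#: Jitter band (Hz) used for followership analysis.
JITTER_BAND = (1.5, 5.0)


@dataclass
class Spectrum:
    """One-sided power spectrum on a non-negative frequency grid."""

    freqs: np.ndarray   # Hz, 0..Nyquist, strictly increasing
    power: np.ndarray   # energy^2 units

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.power = np.asarray(self.power, dtype=np.float64)
        if self.freqs.shape != self.power.shape:
            raise DomainError("freqs and power must align")
        if (np.diff(self.freqs) <= 0).any() or self.freqs[0] < 0:
            raise DomainError("freqs must be non-negative and strictly increasing")
        if (self.power < -1e-12).any():
            raise DomainError("power must be non-negative")

    @property
    def nyquist(self) -> float:
        return float(self.freqs[-1])

    @property
    def total_power(self) -> float:
        """Sum of power over all bins (mean square of the series)."""
        return float(self.power.sum())

    @property
    def nondc_power(self) -> float:
        """Sum of power excluding the zero-frequency bin (variance)."""
        return float(self.power[1:].sum())


def power_spectrum(e, fps: float, detrend: bool = True) -> Spectrum:
    """One-sided periodogram of an energy series.

    Parameters
    ----------
    e : array-like
        Energy series, length >= 8.
    fps : float
        Sampling rate in Hz.
    detrend : bool
        If True (default) remove a least-squares linear trend first, so
        slow drift does not leak into low-frequency bins; the DC bin
        then carries only the (zero) residual mean.
    """
    e = np.asarray(e, dtype=np.float64)
    if e.ndim != 1 or e.size < 8:
        raise DomainError(f"energy series must be 1-D with >= 8 samples, got {e.shape}")
    if fps <= 0:
        raise DomainError("fps must be positive")
    if detrend:
        e = _signal.detrend(e, type="linear")
    n = e.size
    spec = np.abs(np.fft.rfft(e)) ** 2 / n ** 2
    # double interior bins; DC (and Nyquist, when n is even) appear once
    mult = np.full(spec.size, 2.0)
    mult[0] = 1.0
    if n % 2 == 0:
        mult[-1] = 1.0
    return Spectrum(freqs=np.fft.rfftfreq(n, d=1.0 / fps), power=spec * mult)


def band_power(spec: Spectrum, f_lo: float = JITTER_BAND[0],
               f_hi: float = JITTER_BAND[1], normalize: bool = False) -> float:
    """Total spectral power in ``[f_lo, f_hi]`` (inclusive).

    With ``normalize=True`` the band power is divided by the total
    non-DC power, giving the fraction of energy fluctuation carried by
    the band (in [0, 1]); the absolute value (default) is what group
    comparisons of jitter use.
    """
    if not 0 <= f_lo < f_hi:
        raise DomainError(f"need 0 <= f_lo < f_hi, got [{f_lo}, {f_hi}]")
    if f_hi > spec.nyquist + 1e-9:
        raise DomainError(f"f_hi {f_hi} exceeds Nyquist {spec.nyquist}")
    in_band = (spec.freqs >= f_lo) & (spec.freqs <= f_hi)
    bp = float(spec.power[in_band].sum())
    if not normalize:
        return bp
    total = spec.nondc_power
    return bp / total if total > 0 else 0.0
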