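"""Cross-correlation synchrony, entrainment and dominance analysis.

Given the paired kinetic-energy series :math:`E_S(n)` (subject) and
:math:`E_A(n)` (actor), the normalized lagged cross-correlation is

.. math::

    c(\\tau) = \\frac{\\sum_n \\tilde E_S(n+\\tau)\\,\\tilde E_A(n)}
                    {(N-|\\tau|)\\,\\mathrm{std}(E_S)\\,\\mathrm{std}(E_A)}

with :math:`\\tilde E = E - \\bar E`, so that :math:`c(0)` is the Pearson
correlation of the two series. The sign convention is that **positive lag
means the subject's activity echoes the actor's earlier activity** — the
subject moves after the actor.

Derived quantities:

* **synchrony** ``x = c(0)`` — simultaneous co-movement;
* **entrainment / followership** ``y`` — the centre of mass of
  :math:`c(\\tau)` over lags :math:`[-T, T]`, in seconds; positive when
  the correlation mass sits at positive lags (subject follows actor),
  near zero when followership is mutual/symmetric;
* **windowed entrainment** — the same centre of mass over a moving
  window (default 20 s), giving a time-resolved leader/follower signal;
* **dominance bouts** — maximal runs of windows with a constant
  leadership sign, whose mean-duration ratio quantifies turn-taking
  balance.

Centre-of-mass weighting: correlation values are noisy, and a centre of
mass needs non-negative weights. The default (``weights="significant"``)
subtracts an estimate of the sampling-noise floor — ``z_thresh`` times
the RMS of the negative correlation values, which for non-negatively
coupled dyads are noise — and clips at zero, so only correlation mass
that stands out of the noise contributes. If nothing survives the
threshold the plain clipped weights are used instead. ``weights="clip"``
(clip at zero) and ``weights="raw"`` (signed values) are available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal as _signal

from .errors import DegenerateInputError, DomainError, UndefinedRatioError
from .motion import DyadEnergy

#: Default maximum lag (s) for whole-recording cross-correlation.
DEFAULT_MAX_LAG_S = 15.0
#: Default moving-window length (s) for time-resolved entrainment.
DEFAULT_WINDOW_S = 20.0
#: Default hop between window starts (s).
DEFAULT_HOP_S = 1.0
#: Default per-window maximum lag (s).
DEFAULT_WINDOW_MAX_LAG_S = 5.0


@dataclass
class CrossCorrelation:
    """Normalized cross-correlation on a symmetric integer-lag grid."""

    lags: np.ndarray       # frames, -T..+T
    values: np.ndarray
    fps: float

    def __post_init__(self):
        self.lags = np.asarray(self.lags)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.lags.shape != self.values.shape:
            raise DomainError("lags and values must align")
        if not np.isfinite(self.values).all():
            raise DomainError("cross-correlation values must be finite")

    @property
    def lag_seconds(self) -> np.ndarray:
        return self.lags / self.fps

    def at_lag(self, lag: int) -> float:
        idx = np.flatnonzero(self.lags == lag)
        if idx.size == 0:
            raise DomainError(f"lag {lag} outside grid")
        return float(self.values[idx[0]])

    @property
    def peak_lag_seconds(self) -> float:
        """Lag (s) of the maximum correlation."""
        return float(self.lags[int(np.argmax(self.values))] / self.fps)


@dataclass
class EntrainmentProfile:
    """Windowed centre-of-mass entrainment; NaN marks degenerate windows."""

    window_centers: np.ndarray  # s
    com_values: np.ndarray      # s, NaN where a window was constant
    window_len: float
    hop: float

    def __post_init__(self):
        if self.window_len <= 0 or self.hop <= 0:
            raise DomainError("window_len and hop must be positive")
        self.window_centers = np.asarray(self.window_centers, dtype=np.float64)
        self.com_values = np.asarray(self.com_values, dtype=np.float64)
        if self.window_centers.shape != self.com_values.shape:
            raise DomainError("centers and values must align")


@dataclass
class DominanceBouts:
    """Durations (s) of maximal constant-sign leadership runs."""

    subject_bouts: list
    actor_bouts: list


def cross_correlation(e_s, e_a, max_lag: int, fps: float = 1.0,
                      normalization: str = "pearson") -> CrossCorrelation:
    """Normalized cross-correlation of subject vs actor energy.

    Parameters
    ----------
    e_s, e_a : array-like
        Equal-length energy series (subject, actor).
    max_lag : int
        Half-width of the lag grid, in frames; must satisfy
        ``max_lag < N / 2``.
    fps : float
        Frame rate, used only to express lags in seconds.
    normalization : {"pearson", "raw"}
        "pearson" mean-centres and divides each lag sum by
        ``(N - |tau|) * std(E_S) * std(E_A)`` so that ``c(0)`` is the
        Pearson correlation and ``|c| <= 1``. "raw" divides the plain
        lagged product sum by ``std(E_S) * std(E_A)`` only.

    Notes
    -----
    Positive lag means subject-after-actor: ``c(tau)`` correlates
    :math:`E_S(n+\\tau)` with :math:`E_A(n)`.
    """
    e_s = np.asarray(e_s, dtype=np.float64)
    e_a = np.asarray(e_a, dtype=np.float64)
    if e_s.shape != e_a.shape or e_s.ndim != 1:
        raise DomainError("energy series must be equal-length 1-D")
    n = e_s.size
    max_lag = int(max_lag)
    if max_lag < 0 or max_lag >= n / 2:
        raise DomainError(f"max_lag must lie in [0, N/2), got {max_lag} for N={n}")
    std_s, std_a = e_s.std(), e_a.std()
    if std_s == 0 or std_a == 0:
        raise DegenerateInputError("constant energy series: correlation undefined")
    if normalization not in ("pearson", "raw"):
        raise DomainError(f"unknown normalization {normalization!r}")

    if normalization == "pearson":
        xs, xa = e_s - e_s.mean(), e_a - e_a.mean()
    else:
        xs, xa = e_s, e_a
    # full[k] = sum_j xs[j] * xa[j - (k - (n-1))]  ->  lag tau at index n-1+tau
    full = _signal.correlate(xs, xa, mode="full", method="auto")
    lags = np.arange(-max_lag, max_lag + 1)
    sums = full[n - 1 - max_lag: n + max_lag]
    if normalization == "pearson":
        values = sums / ((n - np.abs(lags)) * std_s * std_a)
    else:
        values = sums / (std_s * std_a)
    return CrossCorrelation(lags=lags, values=values, fps=fps)


def synchrony_score(cc: CrossCorrelation) -> float:
    """Synchrony ``x``: the zero-lag cross-correlation ``c(0)``."""
    return cc.at_lag(0)


def _com_weights(values: np.ndarray, weights: str, z_thresh: float) -> np.ndarray:
    if weights == "raw":
        return values
    clipped = np.clip(values, 0.0, None)
    if weights == "clip":
        return clipped
    if weights != "significant":
        raise DomainError(f"unknown weight mode {weights!r}")
    neg = values[values < 0]
    sigma = np.sqrt(np.mean(neg ** 2)) if neg.size else 0.0
    thresholded = np.clip(values - z_thresh * sigma, 0.0, None)
    return thresholded if thresholded.sum() > 0 else clipped


def center_of_mass(cc: CrossCorrelation, T: Optional[float] = None,
                   weights: str = "significant", z_thresh: float = 3.0) -> float:
    """Entrainment ``y``: centre of mass (s) of ``c(tau)`` over ``[-T, T]``.

    Positive values mean the correlation mass sits at positive lags —
    the subject follows the actor; values near zero mean symmetric,
    mutual followership.

    Parameters
    ----------
    cc : CrossCorrelation
    T : float, optional
        Lag range bound in seconds; defaults to the full grid.
    weights : {"significant", "clip", "raw"}
        See module docstring.
    z_thresh : float
        Noise-floor multiplier for ``weights="significant"``.
    """
    tau = cc.lag_seconds
    vals = cc.values
    if T is not None:
        if T <= 0:
            raise DomainError("T must be positive")
        keep = np.abs(tau) <= T + 1e-12
        tau, vals = tau[keep], vals[keep]
        if tau.size == 0:
            raise DomainError(f"no lags within [-{T}, {T}] s")
    w = _com_weights(vals, weights, z_thresh)
    total = w.sum()
    if total == 0:
        raise DegenerateInputError("all centre-of-mass weights are zero")
    return float((tau * w).sum() / total)


def windowed_entrainment(de: DyadEnergy,
                         window_len: float = DEFAULT_WINDOW_S,
                         hop: float = DEFAULT_HOP_S,
                         max_lag: float = DEFAULT_WINDOW_MAX_LAG_S,
                         weights: str = "significant",
                         z_thresh: float = 3.0) -> EntrainmentProfile:
    """Centre-of-mass entrainment over a moving window.

    Windows are fully contained in the recording (no partial windows),
    advance by ``hop`` seconds, and each contributes one centre-of-mass
    value; windows where either person's energy is constant yield NaN.

    Raises
    ------
    DomainError
        If the recording is shorter than one window or
        ``max_lag >= window_len / 2``.
    """
    if window_len <= 0 or hop <= 0:
        raise DomainError("window_len and hop must be positive")
    if max_lag >= window_len / 2:
        raise DomainError("per-window max_lag must be < window_len / 2")
    n = len(de)
    win = int(round(window_len * de.fps))
    step = int(round(hop * de.fps))
    lag_frames = int(round(max_lag * de.fps))
    if win > n:
        raise DomainError(
            f"recording ({n / de.fps:.1f} s) shorter than one window ({window_len} s)"
        )
    centers, coms = [], []
    for start in range(0, n - win + 1, step):
        seg_s = de.subject[start:start + win]
        seg_a = de.actor[start:start + win]
        centers.append((start + win / 2) / de.fps)
        if seg_s.std() == 0 or seg_a.std() == 0:
            coms.append(np.nan)
            continue
        cc = cross_correlation(seg_s, seg_a, lag_frames, fps=de.fps)
        try:
            coms.append(center_of_mass(cc, weights=weights, z_thresh=z_thresh))
        except DegenerateInputError:
            coms.append(np.nan)
    return EntrainmentProfile(np.array(centers), np.array(coms),
                              window_len=window_len, hop=hop)


def dominance_bouts(profile: EntrainmentProfile) -> DominanceBouts:
    """Run-length encode the leadership sign of a windowed profile.

    Consecutive windows with positive centre of mass (subject follows)
    form actor-led bouts; negative runs form subject-led bouts. NaN and
    exactly-zero windows break runs and belong to neither person. Bout
    duration is run length times the hop.
    """
    if profile.com_values.size == 0:
        raise DomainError("empty entrainment profile")
    signs = np.zeros(profile.com_values.size, dtype=int)
    with np.errstate(invalid="ignore"):
        signs[profile.com_values > 0] = 1
        signs[profile.com_values < 0] = -1
    subject, actor = [], []
    run_sign, run_len = 0, 0
    for s in np.append(signs, 0):  # sentinel flushes the last run
        if s == run_sign:
            run_len += 1
            continue
        if run_sign == 1:
            actor.append(run_len * profile.hop)
        elif run_sign == -1:
            subject.append(run_len * profile.hop)
        run_sign, run_len = s, 1
    return DominanceBouts(subject_bouts=subject, actor_bouts=actor)


def dominance_ratio(bouts: DominanceBouts) -> float:
    """Mean subject-led bout duration over mean actor-led bout duration.

    A ratio near 1 means balanced turn-taking; an undefined ratio (one
    person never leads) raises ``UndefinedRatioError``.
    """
    if not bouts.subject_bouts or not bouts.actor_bouts:
        raise UndefinedRatioError(
            "dominance ratio undefined: "
            f"{len(bouts.subject_bouts)} subject-led / {len(bouts.actor_bouts)} actor-led bouts"
        )
    return float(np.mean(bouts.subject_bouts) / np.mean(bouts.actor_bouts))
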