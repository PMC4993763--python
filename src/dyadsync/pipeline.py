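"""Per-dyad and cohort orchestration of the analysis stages.

Glue between the measurement modules: from a :class:`DyadEnergy` compute
the full metric set (synchrony, entrainment, windowed dominance, jitter),
and from a labelled collection build the cohort table that the group
statistics and the classifier consume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import spectral, synchrony
from .cohort import DyadMetrics
from .errors import DomainError, UndefinedRatioError
from .motion import DyadEnergy


@dataclass(frozen=True)
class AnalysisParams:
    """Knobs of the per-dyad analysis, with study-scale defaults."""

    max_lag_s: float = synchrony.DEFAULT_MAX_LAG_S
    window_len_s: float = synchrony.DEFAULT_WINDOW_S
    hop_s: float = synchrony.DEFAULT_HOP_S
    window_max_lag_s: float = synchrony.DEFAULT_WINDOW_MAX_LAG_S
    jitter_band: tuple = spectral.JITTER_BAND
    com_weights: str = "significant"
    com_z_thresh: float = 3.0
    detrend: bool = True


@dataclass
class DyadAnalysis:
    """Full analysis output for one dyad."""

    metrics: DyadMetrics
    cc: synchrony.CrossCorrelation
    profile: Optional[synchrony.EntrainmentProfile]
    bouts: Optional[synchrony.DominanceBouts]
    spectrum_subject: spectral.Spectrum
    spectrum_actor: spectral.Spectrum
    params: AnalysisParams


def analyze_dyad(de: DyadEnergy, dyad_id: str = "dyad",
                 label: Optional[str] = None,
                 params: Optional[AnalysisParams] = None) -> DyadAnalysis:
    """Compute every per-dyad metric from a paired energy series.

    The windowed stage (entrainment profile, bouts, dominance ratio) is
    skipped — metrics set to None/NaN — when the recording is shorter
    than one window; the whole-recording metrics never are.
    """
    params = params or AnalysisParams()
    # short recordings cannot support the default lag range; cap below N/2
    max_lag = min(int(round(params.max_lag_s * de.fps)), (len(de) - 1) // 2 - 1)
    if max_lag < 1:
        raise DomainError(f"recording too short to correlate ({len(de)} samples)")
    cc = synchrony.cross_correlation(de.subject, de.actor, max_lag, fps=de.fps)
    x = synchrony.synchrony_score(cc)
    y = synchrony.center_of_mass(cc, T=max_lag / de.fps,
                                 weights=params.com_weights,
                                 z_thresh=params.com_z_thresh)

    profile = bouts = None
    ratio = float("nan")
    if de.duration >= params.window_len_s:
        profile = synchrony.windowed_entrainment(
            de, window_len=params.window_len_s, hop=params.hop_s,
            max_lag=params.window_max_lag_s, weights=params.com_weights,
            z_thresh=params.com_z_thresh)
        bouts = synchrony.dominance_bouts(profile)
        try:
            ratio = synchrony.dominance_ratio(bouts)
        except UndefinedRatioError:
            ratio = float("nan")

    spec_s = spectral.power_spectrum(de.subject, de.fps, detrend=params.detrend)
    spec_a = spectral.power_spectrum(de.actor, de.fps, detrend=params.detrend)
    lo, hi = params.jitter_band
    metrics = DyadMetrics(
        dyad_id=dyad_id, x=x, y=y,
        jitter_subject=spectral.band_power(spec_s, lo, hi),
        jitter_actor=spectral.band_power(spec_a, lo, hi),
        dominance_ratio=ratio, label=label,
    )
    return DyadAnalysis(metrics=metrics, cc=cc, profile=profile, bouts=bouts,
                        spectrum_subject=spec_s, spectrum_actor=spec_a,
                        params=params)


def cohort_table(dyads, params: Optional[AnalysisParams] = None) -> pd.DataFrame:
    """Metrics table for a labelled collection of dyads.

    ``dyads`` is an iterable of ``(DyadEnergy, label)`` pairs or of
    ``(DyadEnergy, label, extra)`` triples (extras ignored), e.g. the
    output of :func:`dyadsync.simulate.gen_cohort`.
    """
    rows = []
    for i, item in enumerate(dyads):
        de, label = item[0], item[1]
        m = analyze_dyad(de, dyad_id=f"dyad{i:03d}", label=label, params=params).metrics
        rows.append({
            "dyad_id": m.dyad_id, "x": m.x, "y": m.y,
            "jitter_subject": m.jitter_subject, "jitter_actor": m.jitter_actor,
            "dominance_ratio": m.dominance_ratio, "label": m.label,
        })
    if not rows:
        raise DomainError("no dyads supplied")
    return pd.DataFrame(rows)
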