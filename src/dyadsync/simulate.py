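"""Synthetic dyads with known coupling, lag and jitter content.

Real recordings of seated dyads are rarely shareable, so every pipeline
stage is exercised against synthetic dyads whose ground truth is known
by construction, at two levels:

* **energy level** — paired kinetic-energy series generated from coupled
  latent velocities (:func:`gen_energy_dyad`, :func:`gen_cohort`);
* **video level** — rendered frame sequences of textured blobs moving on
  each side of the frame, with analytic per-frame energy
  (:func:`gen_video`).

Energy model
------------
Each person has a latent velocity drive composed of a slow component
(low-pass filtered Gaussian noise, cutoff ``base_cutoff``) modelling
posture shifts and gestures, plus a small broadband component
(``fast_frac``) modelling fast motion. Followership mixes the other
person's *delayed* drive into one's own velocity, and simultaneous
co-activation (moving at the same moments, e.g. with the flow of the
conversation) enters as a shared zero-lag drive ``g`` both people carry
with amplitude ``sync_strength``:

    v_S(t) = (1 - k_SA) d_S(t) + k_SA d_A(t - lag_SA) + s g(t) + jitter
    v_A(t) = (1 - k_AS) d_A(t) + k_AS d_S(t - lag_AS) + s g(t) + jitter

where ``k_SA`` is the subject-follows-actor coupling strength. The
shared drive is what produces zero-lag synchrony ``c(0)`` in the energy
series (squaring makes ``c(0)`` approximately the squared velocity
correlation, so ``s`` values near 0.5–0.9 span the reported 0.1–0.35
range). A
follower additionally carries jitter — band-limited 1.5–5 Hz noise with
amplitude ``jitter_amp`` scaled by that person's followership strength,
emulating the rapid corrective weaving of followers. Kinetic energy is
the squared velocity plus rectified measurement noise, guaranteeing
non-negativity:

    E(t) = v(t)^2 + noise_sd * |eta(t)|

Scenario presets
----------------
``PRESET_A`` ("disengaged"): one-way followership — the subject follows
the actor (k_SA = 0.55, k_AS = 0.05) at a 2 s lag, weak shared drive,
little jitter. ``PRESET_B`` ("engaged"): mutual followership — equal
couplings (k = 0.6) at 1.5 s lags, strong shared drive and high jitter.
These land the group-level
contrasts (higher synchrony, symmetric followership and more jitter in
B) that the analysis is designed to detect. Cohorts draw per-dyad
parameter perturbations and durations around the preset.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal as _signal

from .errors import DomainError
from .ingest import FrameSequence
from .motion import DyadEnergy


@dataclass(frozen=True)
class DyadSimParams:
    """Parameter record of one synthetic dyad; fully determines its output."""

    duration: float = 210.0      # s; study-like encounter length
    fps: float = 25.0            # Hz
    base_cutoff: float = 0.4     # Hz, low-pass cutoff of the slow drive
    fast_frac: float = 0.35      # std of the broadband velocity component
    sync_strength: float = 0.0   # amplitude of the shared zero-lag drive
    coupling_sa: float = 0.0     # subject-follows-actor strength in [0, 1]
    coupling_as: float = 0.0     # actor-follows-subject strength in [0, 1]
    lag_sa: float = 2.0          # s, subject's followership delay
    lag_as: float = 2.0          # s
    jitter_amp: float = 0.0      # amplitude of the 1.5-5 Hz follower component
    jitter_band: tuple = (1.5, 5.0)   # Hz
    noise_sd: float = 0.3        # rectified measurement-noise scale
    seed: int = 0

    def __post_init__(self):
        if self.duration <= 0 or self.fps <= 0:
            raise DomainError("duration and fps must be positive")
        for k in ("coupling_sa", "coupling_as"):
            v = getattr(self, k)
            if not 0 <= v <= 1:
                raise DomainError(f"{k}={v} outside [0, 1]")
        max_lag = max(abs(self.lag_sa), abs(self.lag_as))
        if self.duration * self.fps < 2 * max_lag * self.fps:
            raise DomainError("recording shorter than twice the coupling lag")
        if self.fps <= 2 * self.jitter_band[1]:
            raise DomainError(
                f"fps {self.fps} cannot carry jitter up to {self.jitter_band[1]} Hz"
            )
        if self.jitter_amp < 0 or self.noise_sd < 0:
            raise DomainError("amplitudes must be non-negative")


@dataclass(frozen=True)
class ScenarioPreset:
    """Named parameter template for one performance scenario."""

    name: str
    params: DyadSimParams


#: One-way followership, long lag, weak co-activation, little jitter
#: ("disengaged" scenario).
PRESET_A = ScenarioPreset("A", DyadSimParams(
    sync_strength=0.5, coupling_sa=0.55, coupling_as=0.05,
    lag_sa=2.0, lag_as=2.0, jitter_amp=0.25))
#: Mutual followership, shorter lags, strong co-activation, high jitter
#: ("engaged" scenario).
PRESET_B = ScenarioPreset("B", DyadSimParams(
    sync_strength=0.85, coupling_sa=0.6, coupling_as=0.6,
    lag_sa=1.5, lag_as=1.5, jitter_amp=0.8))

PRESETS = {"A": PRESET_A, "B": PRESET_B}

#: Observed encounter-duration range (s) used when cohorts draw durations.
DURATION_RANGE = (123.0, 379.0)
DURATION_MEAN = 210.0
DURATION_SD = 49.0


def _lowpass_noise(n: int, fps: float, cutoff: float, rng) -> np.ndarray:
    w = rng.standard_normal(n)
    b, a = _signal.butter(4, cutoff / (fps / 2), "low")
    x = _signal.filtfilt(b, a, w)
    return x / x.std()


def _bandpass_noise(n: int, fps: float, band, rng) -> np.ndarray:
    w = rng.standard_normal(n)
    b, a = _signal.butter(4, [band[0] / (fps / 2), band[1] / (fps / 2)], "band")
    x = _signal.filtfilt(b, a, w)
    return x / x.std()


def gen_energy_dyad(params: DyadSimParams):
    """Generate one synthetic dyad's paired energy series.

    Returns
    -------
    de : DyadEnergy
    ground_truth : dict
        The full parameter record plus derived quantities (lag in
        frames); everything needed to reproduce or score the dyad.
    """
    rng = np.random.default_rng(params.seed)
    fps = params.fps
    n = int(round(params.duration * fps))
    pad = int(round((max(abs(params.lag_sa), abs(params.lag_as)) + 10) * fps))

    def drive():
        return (_lowpass_noise(n + pad, fps, params.base_cutoff, rng)
                + params.fast_frac * rng.standard_normal(n + pad))

    d_a = drive()
    d_s = drive()
    shared = drive()  # zero-lag co-activation both people carry
    k_sa = int(round(params.lag_sa * fps))
    k_as = int(round(params.lag_as * fps))
    v_s = ((1 - params.coupling_sa) * d_s[pad:pad + n]
           + params.coupling_sa * d_a[pad - k_sa:pad - k_sa + n]
           + params.sync_strength * shared[pad:pad + n])
    v_a = ((1 - params.coupling_as) * d_a[pad:pad + n]
           + params.coupling_as * d_s[pad - k_as:pad - k_as + n]
           + params.sync_strength * shared[pad:pad + n])
    if params.jitter_amp > 0:
        if params.coupling_sa > 0:
            v_s = v_s + (params.jitter_amp * params.coupling_sa
                         * _bandpass_noise(n, fps, params.jitter_band, rng))
        if params.coupling_as > 0:
            v_a = v_a + (params.jitter_amp * params.coupling_as
                         * _bandpass_noise(n, fps, params.jitter_band, rng))
    e_s = v_s ** 2 + params.noise_sd * np.abs(rng.standard_normal(n))
    e_a = v_a ** 2 + params.noise_sd * np.abs(rng.standard_normal(n))

    gt = asdict(params)
    gt.update(lag_sa_frames=k_sa, lag_as_frames=k_as, n_samples=n)
    return DyadEnergy(subject=e_s, actor=e_a, fps=fps), gt


def _perturbed(base: DyadSimParams, rng, duration: float, seed: int) -> DyadSimParams:
    """Per-dyad multiplicative scatter around a preset (log-normal, ~20-30%)."""
    def mul(sd):
        return float(np.exp(rng.normal(0.0, sd)))
    return replace(
        base,
        duration=duration,
        sync_strength=base.sync_strength * mul(0.15),
        coupling_sa=min(1.0, base.coupling_sa * mul(0.2)),
        coupling_as=min(1.0, base.coupling_as * mul(0.2)),
        lag_sa=base.lag_sa * mul(0.2),
        lag_as=base.lag_as * mul(0.2),
        jitter_amp=base.jitter_amp * mul(0.3),
        seed=seed,
    )


def gen_cohort(n_a: int, n_b: int,
               presets: Sequence[ScenarioPreset] = (PRESET_A, PRESET_B),
               seed: int = 0):
    """Generate a labelled cohort of synthetic dyads.

    ``n_a`` dyads from the first preset and ``n_b`` from the second, with
    per-dyad parameter perturbations and encounter durations drawn from
    a clipped normal matching the observed range. Deterministic per seed.

    Returns a list of ``(DyadEnergy, label, ground_truth)`` triples.
    """
    if n_a < 1 or n_b < 1:
        raise DomainError("need at least one dyad per scenario")
    rng = np.random.default_rng(seed)
    out = []
    for preset, count in zip(presets, (n_a, n_b)):
        for _ in range(count):
            duration = float(np.clip(rng.normal(DURATION_MEAN, DURATION_SD),
                                     *DURATION_RANGE))
            child_seed = int(rng.integers(0, 2 ** 31 - 1))
            p = _perturbed(preset.params, rng, duration, child_seed)
            de, gt = gen_energy_dyad(p)
            gt["label"] = preset.name
            out.append((de, preset.name, gt))
    return out


# --- video-level generation ------------------------------------------------

@dataclass
class BlobTrack:
    """Trajectory of one textured square blob within one half-frame.

    ``positions`` are per-frame (row, col) centres in pixels; they are
    rounded to integer pixels at render time so the analytic ground-truth
    energy (blob area x squared per-frame displacement) is exact.
    """

    positions: np.ndarray        # (n_frames, 2) float
    half_size: int = 10          # blob is (2h+1) x (2h+1)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise DomainError("positions must be (n_frames, 2)")
        if len(self.positions) < 2:
            raise DomainError("a track needs at least 2 frames")

    @property
    def area(self) -> int:
        return (2 * self.half_size + 1) ** 2


def static_track(n_frames: int, row: float, col: float, half_size: int = 10) -> BlobTrack:
    return BlobTrack(np.tile([row, col], (n_frames, 1)), half_size)


def oscillating_track(n_frames: int, fps: float, row: float, col: float,
                      freq: float, amp: float, axis: int = 1,
                      half_size: int = 10) -> BlobTrack:
    """Blob oscillating sinusoidally at ``freq`` Hz with amplitude ``amp`` px."""
    t = np.arange(n_frames) / fps
    pos = np.tile(np.asarray([row, col], dtype=np.float64), (n_frames, 1))
    pos[:, axis] += amp * np.sin(2 * np.pi * freq * t)
    return BlobTrack(pos, half_size)


def linear_track(n_frames: int, start, velocity, half_size: int = 10) -> BlobTrack:
    """Constant-velocity track; ``velocity`` in px/frame (row, col)."""
    steps = np.arange(n_frames)[:, None]
    return BlobTrack(np.asarray(start)[None, :] + steps * np.asarray(velocity)[None, :],
                     half_size)


def gen_video(subject_track: BlobTrack, actor_track: BlobTrack,
              frame_size=(80, 128), fps: float = 25.0,
              texture: bool = True, seed: int = 0,
              contrast: float = 0.15, texture_scale: float = 1.5):
    """Render a two-blob synthetic recording with analytic ground truth.

    One textured blob moves in each half of the frame (subject left,
    actor right of the midline split). Textures are band-limited
    (Gaussian-smoothed noise, correlation length ``texture_scale`` px):
    aliased white-noise texture defeats gradient-based flow estimation
    at odd single-pixel shifts. The static background carries the same
    contrast as the blobs when ``texture`` is on — so dense estimators
    have well-conditioned gradients everywhere and do not smear blob
    motion into a flat surround — and is flat otherwise. Blob centres
    are rounded to integer pixels, making the rendered motion an exact
    integer translation.

    Returns
    -------
    frames : FrameSequence
    gt : dict with per-frame-pair analytic energies
        ``subject_energy[n] = area * |pos[n+1] - pos[n]|^2`` (px^2/frame^2)
        and likewise for the actor; plus the boundary column.

    Raises
    ------
    DomainError
        If a blob's extent would cross the midline boundary or leave the
        frame.
    """
    n_rows, n_cols = frame_size
    boundary = n_cols // 2
    n_frames = len(subject_track.positions)
    if len(actor_track.positions) != n_frames:
        raise DomainError("tracks must have equal length")
    rng = np.random.default_rng(seed)

    from scipy.ndimage import gaussian_filter

    def textured(shape):
        t = gaussian_filter(rng.random(shape), texture_scale)
        t = 0.5 + contrast * (t - t.mean()) / t.std()
        return np.round(np.clip(t, 0, 1) * 255) / 255  # 8-bit-safe intensities

    if texture:
        base = textured((n_rows, n_cols))
    else:
        base = np.full((n_rows, n_cols), 0.5)

    def patch(h):
        return textured((2 * h + 1, 2 * h + 1))

    tex_s = patch(subject_track.half_size)
    tex_a = patch(actor_track.half_size)

    def validate(track: BlobTrack, lo_col: int, hi_col: int, who: str):
        h = track.half_size
        pos = np.round(track.positions).astype(int)
        if ((pos[:, 0] - h < 0).any() or (pos[:, 0] + h >= n_rows).any()
                or (pos[:, 1] - h < lo_col).any() or (pos[:, 1] + h >= hi_col).any()):
            raise DomainError(f"{who} track leaves its half-frame [{lo_col}, {hi_col})")
        return pos

    pos_s = validate(subject_track, 0, boundary, "subject")
    pos_a = validate(actor_track, boundary, n_cols, "actor")

    frames = []
    for i in range(n_frames):
        f = base.copy()
        for pos, tex, h in ((pos_s[i], tex_s, subject_track.half_size),
                            (pos_a[i], tex_a, actor_track.half_size)):
            r, c = pos
            f[r - h:r + h + 1, c - h:c + h + 1] = tex
        frames.append(f)

    def analytic(pos, area):
        d = np.diff(pos.astype(np.float64), axis=0)
        return area * (d ** 2).sum(axis=1)

    gt = {
        "boundary_col": boundary,
        "fps": fps,
        "subject_energy": analytic(pos_s, subject_track.area),
        "actor_energy": analytic(pos_a, actor_track.area),
        "seed": seed,
    }
    return FrameSequence(frames, fps, source_id=f"gen_video(seed={seed})"), gt


def write_dyad(de: DyadEnergy, gt: dict, out_dir, stem: str) -> None:
    """Write one synthetic dyad as energy CSV + ground-truth JSON."""
    from .ingest import write_energy_csv
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_energy_csv(de, out_dir / f"{stem}.csv")
    clean = {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in gt.items()}
    with open(out_dir / f"{stem}.groundtruth.json", "w") as fh:
        json.dump(clean, fh, indent=2)
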