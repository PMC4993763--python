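"""Input handling: frames, region splits, and energy CSV round-trips.

A recording enters the pipeline either as a sequence of grayscale frames
(an image-sequence directory or a multi-frame image file) or, skipping the
video stage, as a two-column kinetic-energy CSV. The camera is fixed and
the two interlocutors sit on opposite sides of a vertical boundary, so a
single column index splits every frame into a subject part and an actor
part.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DomainError,
    FormatError,
    InputError,
    ValidationError,
)
from .motion import DyadEnergy

#: Rec.601 luma weights used for grayscale conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".tif", ".tiff", ".bmp"}


@dataclass
class FrameSequence:
    """An ordered stack of equally sized grayscale frames at a fixed rate.

    Parameters
    ----------
    frames : list of ndarray
        2-D float arrays (rows x cols), identical shapes.
    fps : float
        Frame rate in Hz, > 0.
    source_id : str
        Free-text provenance (path, generator record, ...).
    """

    frames: list
    fps: float
    source_id: str = ""

    def __post_init__(self):
        if len(self.frames) < 2:
            raise FormatError("a frame sequence needs at least 2 frames")
        if self.fps <= 0:
            raise ConfigurationError(f"fps must be positive, got {self.fps}")
        shape = np.asarray(self.frames[0]).shape
        for i, f in enumerate(self.frames):
            f = np.asarray(f)
            if f.ndim != 2 or f.shape != shape:
                raise FormatError(
                    f"frame {i} has shape {f.shape}, expected {shape}"
                )

    def __len__(self):
        return len(self.frames)

    @property
    def shape(self):
        """(rows, cols) of each frame."""
        return np.asarray(self.frames[0]).shape

    @property
    def duration(self):
        """Recording duration in seconds."""
        return len(self.frames) / self.fps

    def trim(self, start_s: float = 0.0, end_s: Optional[float] = None) -> "FrameSequence":
        """Return the sub-sequence between ``start_s`` and ``end_s`` seconds.

        Trimming is how the analysed portion of an encounter is selected
        (e.g. from the moment both people are seated); the cut points are
        configuration, not inferred from content.
        """
        i0 = int(round(start_s * self.fps))
        i1 = len(self.frames) if end_s is None else int(round(end_s * self.fps))
        if not (0 <= i0 < i1 <= len(self.frames)):
            raise DomainError(f"trim window [{start_s}, {end_s}] s outside recording")
        return FrameSequence(self.frames[i0:i1], self.fps,
                             f"{self.source_id}[{start_s}:{end_s}]")


@dataclass(frozen=True)
class RegionSplit:
    """Vertical two-person partition of the frame.

    Columns ``[0, boundary_col)`` form the left region and
    ``[boundary_col, frame_width)`` the right region; ``subject_side`` says
    which of the two belongs to the subject (the other is the actor's).
    """

    frame_width: int
    boundary_col: int
    subject_side: str  # "left" | "right"

    def __post_init__(self):
        if not 0 < self.boundary_col < self.frame_width:
            raise DomainError(
                f"boundary_col {self.boundary_col} outside (0, {self.frame_width})"
            )
        if self.subject_side not in ("left", "right"):
            raise DomainError(f"subject_side must be 'left' or 'right', got {self.subject_side!r}")

    @property
    def subject_columns(self) -> slice:
        if self.subject_side == "left":
            return slice(0, self.boundary_col)
        return slice(self.boundary_col, self.frame_width)

    @property
    def actor_columns(self) -> slice:
        if self.subject_side == "left":
            return slice(self.boundary_col, self.frame_width)
        return slice(0, self.boundary_col)

    def masks(self, n_rows: int):
        """Boolean (subject, actor) masks of shape ``(n_rows, frame_width)``."""
        subject = np.zeros((n_rows, self.frame_width), dtype=bool)
        subject[:, self.subject_columns] = True
        return subject, ~subject


def split_regions(frame_width: int, boundary_col: Optional[int] = None,
                  subject_side: str = "left") -> RegionSplit:
    """Build the two-person region split for frames of the given width.

    ``boundary_col`` defaults to the frame midline (``frame_width // 2``);
    where the desk midline is off-centre in the camera view, pass the true
    column.
    """
    if boundary_col is None:
        boundary_col = frame_width // 2
    return RegionSplit(frame_width, boundary_col, subject_side)


def _to_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[2] in (3, 4):
        r, g, b = LUMA_WEIGHTS
        return r * img[..., 0] + g * img[..., 1] + b * img[..., 2]
    raise FormatError(f"cannot interpret image of shape {img.shape} as a frame")


def read_frames(path, fps_override: Optional[float] = None) -> FrameSequence:
    """Read a video file or an image-sequence directory into a FrameSequence.

    Directories are read as lexicographically sorted image files (PNG, JPEG,
    TIFF, BMP); their frame rate has no container metadata so ``fps_override``
    is required. Single files are read through imageio; if the reader
    exposes an ``fps`` metadata entry it is used unless overridden.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such input: {path}")

    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES)
        if not files:
            raise InputError(f"no image files in directory {path}")
        try:
            frames = [_to_gray(iio.imread(p)) for p in files]
        except FormatError:
            raise
        except Exception as exc:  # decoder errors vary by plugin
            raise InputError(f"failed to decode frames in {path}: {exc}") from exc
        fps = fps_override
        if fps is None:
            raise ConfigurationError(
                f"{path} is an image directory; pass fps_override (no container metadata)"
            )
    else:
        try:
            raw = list(iio.imiter(path))
        except Exception as exc:
            raise InputError(f"failed to decode {path}: {exc}") from exc
        if not raw:
            raise InputError(f"{path} contains no frames")
        frames = [_to_gray(f) for f in raw]
        fps = fps_override
        if fps is None:
            try:
                meta = iio.immeta(path)
            except Exception:
                meta = {}
            fps = meta.get("fps")
            if fps is None:
                raise ConfigurationError(
                    f"{path} carries no fps metadata; pass fps_override"
                )

    shape = frames[0].shape
    for i, f in enumerate(frames):
        if f.shape != shape:
            raise FormatError(f"frame {i} has shape {f.shape}, expected {shape}")
    return FrameSequence(frames, float(fps), source_id=str(path))


# --- energy CSV round-trip -------------------------------------------------

_FPS_RE = re.compile(r"#\s*fps\s*[:=]\s*([0-9.]+)")


def write_energy_csv(de: DyadEnergy, path, meta: Optional[dict] = None) -> None:
    """Write a DyadEnergy to CSV with the fps in a header comment.

    An optional JSON sidecar ``<path>.json`` records extra provenance
    (boundary column, flow estimator parameters, seed, ...).
    """
    path = Path(path)
    df = pd.DataFrame({
        "frame_index": np.arange(len(de.subject)),
        "subject_energy": de.subject,
        "actor_energy": de.actor,
    })
    with open(path, "w") as fh:
        fh.write(f"# fps: {de.fps!r}\n")
        # shortest round-trippable decimal form -> bit-exact re-read
        df.to_csv(fh, index=False, float_format=lambda v: repr(float(v)))
    if meta is not None:
        sidecar = dict(meta)
        sidecar.setdefault("fps", de.fps)
        with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
            json.dump(sidecar, fh, indent=2)


def read_energy_csv(path, fps: Optional[float] = None) -> DyadEnergy:
    """Read a (frame_index, subject_energy, actor_energy) CSV.

    The frame rate is taken from, in order of precedence: the ``fps``
    argument, a ``# fps:`` header comment, or a ``<path>.json`` sidecar.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    with open(path) as fh:
        first = fh.readline()
    if fps is None:
        m = _FPS_RE.match(first)
        if m:
            fps = float(m.group(1))
        else:
            sidecar = path.with_suffix(path.suffix + ".json")
            if sidecar.exists():
                fps = json.load(open(sidecar)).get("fps")
    if fps is None:
        raise ConfigurationError(
            f"{path}: no fps header, sidecar, or explicit fps argument"
        )
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:
        raise FormatError(f"unparseable energy CSV {path}: {exc}") from exc
    required = {"frame_index", "subject_energy", "actor_energy"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: columns {sorted(df.columns)} lack {sorted(required)}")
    if df[list(required)].isna().any().any():
        raise FormatError(f"{path}: ragged or missing values")
    subject = df["subject_energy"].to_numpy(dtype=np.float64)
    actor = df["actor_energy"].to_numpy(dtype=np.float64)
    if (subject < 0).any() or (actor < 0).any():
        raise ValidationError(f"{path}: negative kinetic energy values")
    return DyadEnergy(subject=subject, actor=actor, fps=float(fps))
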