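"""Loading and normalization of facial video clips.

A clip enters the pipeline as a directory of numbered image frames (or an
explicit ordered list of paths) and leaves as a :class:`FrameSequence` — a
``T x H x W`` float array of gray intensities in ``[0, 255]``.  Two
normalization steps bring heterogeneous clips onto a common footing:

* spatial resizing (bilinear) to a uniform resolution, and
* temporal length normalization to a fixed frame count (default 20) by
  per-pixel linear interpolation over normalized time ``[0, 1]``.

The temporal step is a deliberately simple, deterministic stand-in for
graph-embedding temporal interpolation models: it preserves the first and
last frames exactly, keeps constant clips constant, and is idempotent.
Clips are assumed pre-cropped to the face region; no detection or landmark
alignment happens here.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize as _sk_resize

__all__ = [
    "RawSample",
    "FrameSequence",
    "FrameLoadError",
    "load_frame_sequence",
    "resize_sequence",
    "interpolate_length",
    "read_manifest",
]

#: ITU-R BT.601 luma weights used for color -> gray conversion.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

DEFAULT_TARGET_LEN = 20


class FrameLoadError(RuntimeError):
    """A frame file is missing or cannot be decoded."""


@dataclass(frozen=True)
class RawSample:
    """One manifest entry: a labeled clip belonging to one subject."""

    sample_id: str
    subject_id: str
    class_label: str
    frame_paths: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.frame_paths) == 0:
            raise ValueError(f"sample {self.sample_id!r} has no frames")


@dataclass
class FrameSequence:
    """A stack of equally sized grayscale frames.

    ``pixels`` has shape ``(T, H, W)`` and dtype float64 so that the signed
    arithmetic of the descriptors (differences, zero-sum mask responses up
    to 8*255 in magnitude) is exact.
    """

    pixels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3:
            raise ValueError(f"pixels must be (T, H, W), got shape {self.pixels.shape}")
        t, h, w = self.pixels.shape
        if t < 2 or h < 3 or w < 3:
            raise ValueError(f"sequence too small: T={t}, H={h}, W={w}")

    @property
    def T(self) -> int:
        return self.pixels.shape[0]

    @property
    def H(self) -> int:
        return self.pixels.shape[1]

    @property
    def W(self) -> int:
        return self.pixels.shape[2]

    def copy(self) -> "FrameSequence":
        return FrameSequence(self.pixels.copy())


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Convert one decoded frame to gray via BT.601 luma; pass gray through."""
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim == 2:
        return frame
    if frame.ndim == 3 and frame.shape[2] in (3, 4):
        return frame[:, :, :3] @ LUMA_WEIGHTS
    raise ValueError(f"unsupported frame shape {frame.shape}")


def load_frame_sequence(sample: RawSample) -> FrameSequence:
    """Decode a sample's frames in manifest order into a FrameSequence.

    Raises
    ------
    FrameLoadError
        If a file is missing or cannot be decoded (the message names the
        offending path).
    ValueError
        If the decoded frames do not all share the same size.
    """
    frames = []
    for path in sample.frame_paths:
        try:
            with Image.open(path) as img:
                frames.append(to_grayscale(np.asarray(img)))
        except (FileNotFoundError, OSError) as exc:
            raise FrameLoadError(f"cannot load frame {path!r}: {exc}") from exc
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"sample {sample.sample_id!r} has inconsistent frame sizes: {sorted(shapes)}")
    return FrameSequence(np.stack(frames))


def resize_sequence(seq: FrameSequence, out_h: int, out_w: int) -> FrameSequence:
    """Bilinearly resample every frame to ``out_h x out_w``; T is unchanged."""
    if out_h < 3 or out_w < 3:
        raise ValueError(f"target size must be at least 3x3, got {out_h}x{out_w}")
    if (out_h, out_w) == (seq.H, seq.W):
        return seq.copy()
    out = _sk_resize(
        seq.pixels,
        (seq.T, out_h, out_w),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return FrameSequence(out)


def interpolate_length(seq: FrameSequence, target_len: int = DEFAULT_TARGET_LEN) -> FrameSequence:
    """Normalize clip length by per-pixel linear interpolation in time.

    Input and output frame indices are both mapped onto normalized time
    [0, 1]; endpoints are preserved exactly.
    """
    if target_len < 3:
        raise ValueError(f"target_len must be >= 3, got {target_len}")
    if seq.T == target_len:
        return seq.copy()
    # position of each output frame on the input index axis
    pos = np.linspace(0.0, 1.0, target_len) * (seq.T - 1)
    i0 = np.minimum(np.floor(pos).astype(int), seq.T - 2)
    frac = (pos - i0)[:, None, None]
    out = (1.0 - frac) * seq.pixels[i0] + frac * seq.pixels[i0 + 1]
    return FrameSequence(out)


_IMAGE_EXTS = (".png", ".jpg", ".jpeg")


def read_manifest(path: str | os.PathLike) -> list[RawSample]:
    """Read a CSV manifest with header sample_id,subject_id,label,frames_dir.

    Frames within each ``frames_dir`` are taken in lexicographic order.
    Relative ``frames_dir`` entries are resolved against the manifest's own
    directory.
    """
    path = Path(path)
    table = pd.read_csv(path, dtype=str)
    required = {"sample_id", "subject_id", "label", "frames_dir"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    samples = []
    for row in table.itertuples(index=False):
        frames_dir = Path(row.frames_dir)
        if not frames_dir.is_absolute():
            frames_dir = path.parent / frames_dir
        paths = sorted(
            str(p) for p in frames_dir.iterdir() if p.suffix.lower() in _IMAGE_EXTS
        ) if frames_dir.is_dir() else []
        if not paths:
            raise FrameLoadError(f"no frames found in {frames_dir} for sample {row.sample_id!r}")
        samples.append(
            RawSample(
                sample_id=row.sample_id,
                subject_id=row.subject_id,
                class_label=row.label,
                frame_paths=tuple(paths),
            )
        )
    return samples
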