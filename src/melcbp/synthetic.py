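"""Synthetic micro-expression-like video generator.

Real micro-expressions are brief (a fraction of a second), low-amplitude,
spatially localized facial movements riding on a person-specific facial
appearance.  The generator emulates exactly those statistics at desk
scale: each clip is a subject-specific smooth background texture plus one
small, low-contrast spatiotemporal event whose type, location and drift
direction are class-specific, plus per-frame Gaussian pixel noise.

Three event archetypes mirror the sensitivities of the three descriptor
streams:

* ``brighten`` — a localized monotone brightening ramp drifting east,
* ``darken``   — a localized monotone darkening ramp drifting south,
* ``pulse``    — an onset-apex-offset brightness pulse drifting north-east.

The background field is reused across all clips of a subject, so
leave-one-subject-out evaluation on this data is a genuine test of
generalizing across appearance, not clip memorization.  What the data do
*not* emulate: facial geometry, landmark motion, compression artifacts,
illumination drift.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .descriptors import GridSpec
from .preprocessing import FrameSequence
from .sparse import MultiGridDesign

__all__ = [
    "SynthParams",
    "SynthDataset",
    "CLASS_NAMES",
    "generate_sequence",
    "generate_dataset",
    "ground_truth_cells",
    "write_dataset",
    "signal_design",
]

#: Class labels in index order (class_id 1, 2, 3).
CLASS_NAMES = ("brighten", "darken", "pulse")

# per-class event geometry: anchor as (row, col) fractions of (H, W),
# drift direction as a unit-ish (dy, dx), and temporal profile kind
_EVENTS = (
    {"anchor": (0.15, 0.12), "direction": (0.0, 1.0), "kind": "ramp", "polarity": 1.0},
    {"anchor": (0.15, 0.62), "direction": (1.0, 0.0), "kind": "ramp", "polarity": -1.0},
    {"anchor": (0.62, 0.25), "direction": (-0.7, 0.7), "kind": "pulse", "polarity": 1.0},
)


@dataclass(frozen=True)
class SynthParams:
    """Generation parameters; ``seed`` fixes all randomness."""

    height: int = 64
    width: int = 64
    frames: int = 20
    n_classes: int = 3
    n_subjects: int = 10
    clips_per_subject_per_class: int = 2
    amplitude: float = 12.0  # event contrast in gray levels
    noise_sigma: float = 2.0  # per-pixel per-frame Gaussian noise
    background_contrast: float = 4.0  # std of the smooth background field
    background_smoothness: float = 8.0  # gaussian sigma of the field, px
    event_size: int = 14  # event box side, px
    edge_softness: float = 1.5  # gaussian sigma of the event edge, px
    drift: float = 6.0  # total event displacement over the clip, px
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.amplitude > 0 and self.noise_sigma >= self.amplitude:
            raise ValueError("event amplitude must exceed the noise level")
        if not (1 <= self.n_classes <= len(CLASS_NAMES)):
            raise ValueError(f"n_classes must be in 1..{len(CLASS_NAMES)}")
        if self.frames < 3 or self.height < 8 or self.width < 8:
            raise ValueError("need at least 3 frames and 8x8 pixels")


@dataclass
class SynthDataset:
    """Generated clips plus their manifest."""

    sequences: list[FrameSequence] = field(repr=False)
    sample_ids: list[str]
    subject_ids: list[str]
    labels: list[str]
    params: SynthParams
    manifest: pd.DataFrame = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.sequences)


def _subject_rng(params: SynthParams, subject_id: str) -> np.random.Generator:
    # stable across clips of the subject; crc32 keeps string ids deterministic
    return np.random.default_rng([params.seed % (2**31), zlib.crc32(str(subject_id).encode())])


def _background(params: SynthParams, subject_id: str) -> np.ndarray:
    rng = _subject_rng(params, subject_id)
    field_ = gaussian_filter(
        rng.standard_normal((params.height, params.width)), params.background_smoothness
    )
    std = field_.std()
    if std > 0:
        field_ = field_ / std * params.background_contrast
    offset = rng.uniform(-10.0, 10.0)
    return 128.0 + offset + field_


def _temporal_profile(kind: str, T: int) -> np.ndarray:
    t = np.arange(T) / (T - 1)
    if kind == "ramp":
        return t
    if kind == "pulse":
        return np.sin(np.pi * t)
    raise ValueError(f"unknown profile kind {kind!r}")


def _event_footprint(params: SynthParams, top: float, left: float) -> np.ndarray:
    """Soft-edged rectangular bump with peak value 1, full-frame array."""
    mask = np.zeros((params.height, params.width))
    r0 = int(round(top))
    c0 = int(round(left))
    r1 = min(r0 + params.event_size, params.height)
    c1 = min(c0 + params.event_size, params.width)
    mask[max(r0, 0) : r1, max(c0, 0) : c1] = 1.0
    mask = gaussian_filter(mask, params.edge_softness)
    peak = mask.max()
    return mask / peak if peak > 0 else mask


def _event_track(params: SynthParams, class_id: int) -> list[tuple[float, float]]:
    """(top, left) of the event box at each frame, following the class drift."""
    spec = _EVENTS[class_id - 1]
    a_r, a_c = spec["anchor"]
    d = np.asarray(spec["direction"], dtype=float)
    d = d / np.linalg.norm(d)
    top0 = a_r * params.height
    left0 = a_c * params.width
    out = []
    for t in range(params.frames):
        frac = t / (params.frames - 1)
        out.append((top0 + d[0] * params.drift * frac, left0 + d[1] * params.drift * frac))
    return out


def generate_sequence(
    class_id: int,
    subject_id: str,
    params: SynthParams,
    seed: int | np.random.SeedSequence | None = None,
) -> FrameSequence:
    """One clip: subject background + class event + pixel noise, in [0, 255].

    The background depends only on (params.seed, subject_id); ``seed``
    drives the per-clip noise, so clips of one subject share appearance.
    """
    if not (1 <= class_id <= params.n_classes):
        raise ValueError(f"class_id {class_id} out of range 1..{params.n_classes}")
    spec = _EVENTS[class_id - 1]
    bg = _background(params, subject_id)
    profile = _temporal_profile(spec["kind"], params.frames)
    track = _event_track(params, class_id)
    rng = np.random.default_rng(seed)

    frames = np.empty((params.frames, params.height, params.width))
    for t in range(params.frames):
        img = bg.copy()
        if params.amplitude > 0:
            foot = _event_footprint(params, *track[t])
            img += spec["polarity"] * params.amplitude * profile[t] * foot
        if params.noise_sigma > 0:
            img += rng.normal(0.0, params.noise_sigma, img.shape)
        frames[t] = np.clip(img, 0.0, 255.0)
    return FrameSequence(frames)


def generate_dataset(params: SynthParams | None = None) -> SynthDataset:
    """Full factorial subjects x classes x clips dataset with manifest."""
    params = params or SynthParams()
    sequences, sample_ids, subject_ids, labels = [], [], [], []
    for si in range(params.n_subjects):
        subject = f"s{si + 1:02d}"
        for class_id in range(1, params.n_classes + 1):
            for rep in range(params.clips_per_subject_per_class):
                clip_seed = np.random.SeedSequence(
                    entropy=params.seed % (2**31), spawn_key=(si, class_id, rep)
                )
                sequences.append(generate_sequence(class_id, subject, params, clip_seed))
                sample_ids.append(f"{subject}_{CLASS_NAMES[class_id - 1]}_{rep}")
                subject_ids.append(subject)
                labels.append(CLASS_NAMES[class_id - 1])
    manifest = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "subject_id": subject_ids,
            "label": labels,
            "frames_dir": [f"frames/{sid}" for sid in sample_ids],
        }
    )
    return SynthDataset(
        sequences=sequences,
        sample_ids=sample_ids,
        subject_ids=subject_ids,
        labels=labels,
        params=params,
        manifest=manifest,
    )


def ground_truth_cells(params: SynthParams, grid: GridSpec) -> dict[str, set[tuple[int, int]]]:
    """Grid cells whose pixels the event of each class touches (over the
    whole drift track, soft edge included)."""
    cell_h = max(params.height // grid.rows, 1)
    cell_w = max(params.width // grid.cols, 1)
    out: dict[str, set[tuple[int, int]]] = {}
    for class_id in range(1, params.n_classes + 1):
        cells: set[tuple[int, int]] = set()
        for top, left in _event_track(params, class_id):
            foot = _event_footprint(params, top, left)
            ys, xs = np.nonzero(foot > 0.05)
            rows = np.minimum(ys // cell_h, grid.rows - 1)
            cols = np.minimum(xs // cell_w, grid.cols - 1)
            cells.update(zip(rows.tolist(), cols.tolist()))
        out[CLASS_NAMES[class_id - 1]] = cells
    return out


def write_dataset(dataset: SynthDataset, out_dir: str | Path) -> Path:
    """Write PNG frame directories, the CSV manifest, and a params sidecar."""
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for seq, sid in zip(dataset.sequences, dataset.sample_ids):
        frame_dir = out_dir / "frames" / sid
        frame_dir.mkdir(parents=True, exist_ok=True)
        for t in range(seq.T):
            img = Image.fromarray(np.round(seq.pixels[t]).astype(np.uint8))
            img.save(frame_dir / f"frame_{t:03d}.png")
    manifest_path = out_dir / "manifest.csv"
    dataset.manifest.to_csv(manifest_path, index=False)
    (out_dir / "params.json").write_text(
        json.dumps({k: getattr(dataset.params, k) for k in dataset.params.__dataclass_fields__}, indent=2)
    )
    return manifest_path


def signal_design(
    n_grids: int = 16,
    n_signal: int = 4,
    n_samples: int = 60,
    n_classes: int = 3,
    dim: int = 12,
    noise_sigma: float = 0.5,
    signal_scale: float = 0.25,
    seed: int = 0,
) -> tuple[MultiGridDesign, np.ndarray]:
    """Synthetic multi-grid regression design with known signal grids.

    ``n_signal`` randomly chosen grids carry class-dependent mean patterns
    (Gaussian prototypes of scale ``signal_scale``); the rest are pure
    noise.  The default separation sits below the noise floor, matching
    the low-intensity regime the descriptors target.  Returns the design
    and the sorted indices of the signal grids — the ground truth for
    feature-selection recovery checks.
    """
    if n_signal > n_grids:
        raise ValueError("n_signal cannot exceed n_grids")
    rng = np.random.default_rng(seed)
    labels = np.tile(np.arange(1, n_classes + 1), n_samples // n_classes + 1)[:n_samples]
    rng.shuffle(labels)
    signal_grids = np.sort(rng.choice(n_grids, size=n_signal, replace=False))
    X = []
    for g in range(n_grids):
        noise = rng.normal(0.0, noise_sigma, (n_samples, dim))
        if g in signal_grids:
            prototypes = rng.standard_normal((n_classes, dim)) * signal_scale
            X.append(prototypes[labels - 1] + noise)
        else:
            X.append(noise)
    return MultiGridDesign(X=X, labels=labels, n_classes=n_classes), signal_grids
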