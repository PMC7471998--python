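"""Enhanced Local Cube Binary Pattern (Enhanced LCBP) descriptors.

Every descriptor is computed on 3x3x3 intensity cubes: the 3x3 spatial
neighborhood of a pixel taken at frames ``t - dt``, ``t`` and ``t + dt``.
Three complementary binary code streams are extracted per cube:

Spatial Difference codes
    For each of the three temporal center pixels ``c_i``, an 8-bit LBP-style
    code comparing the eight neighbors of the *last* frame in the cube
    against ``c_i`` (bit set when ``neighbor - c_i >= 0``).  Encodes spatial
    texture together with the inter-frame drift of the center.

Temporal Direction codes
    Four 3x3 "temporal planes" are cut through the cube center (horizontal,
    vertical and the two diagonal spatial lines, each tracked across the
    three frames).  Eight zero-sum compass masks are correlated with each
    plane; the code ``8*argmax + argmin`` of the eight responses (0..63)
    summarizes the dominant and weakest local motion direction per plane.

Temporal Gradient codes
    A center-surround (Laplacian-like) response ``S`` is computed per frame;
    the 2-bit code records the signs of the two inter-frame gradients of
    ``S`` (brightening/darkening/pulse patterns).

Because all codes are built from differences or zero-sum mask responses,
adding a constant to every pixel leaves every stream unchanged (gray-shift
invariance).  Codes are aggregated into per-grid-cell histograms to retain
spatial location, and concatenated into a spatial block (3 x 256 bins per
cell) and a temporal block (4 x 64 + 4 bins per cell).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocessing import FrameSequence

__all__ = [
    "GridSpec",
    "CubeView",
    "EnhancedLCBPFeature",
    "NEIGHBOR_OFFSETS",
    "PLANE_OFFSETS",
    "build_direction_masks",
    "single_frame_mask",
    "cube_view",
    "extract_temporal_planes",
    "spatial_difference_codes",
    "temporal_direction_codes",
    "temporal_gradient_codes",
    "grid_histograms",
    "extract_enhanced_lcbp",
    "save_feature_table",
    "load_feature_table",
]

SPATIAL_BINS = 256
DIRECTION_BINS = 64
GRADIENT_BINS = 4

#: 8-neighbor offsets (dy, dx) starting at the top-left corner, clockwise.
#: Bit n (weight 2^n) of a spatial-difference code corresponds to entry n.
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1),
)

#: Spatial offsets (dy, dx) of the three pixels on each temporal plane's
#: line, in raster order.  P1 horizontal, P2 vertical, P3 main diagonal,
#: P4 anti-diagonal; together with time they cover all 27 cube cells.
PLANE_OFFSETS: tuple[tuple[tuple[int, int], ...], ...] = (
    ((0, -1), (0, 0), (0, 1)),
    ((-1, 0), (0, 0), (1, 0)),
    ((-1, -1), (0, 0), (1, 1)),
    ((-1, 1), (0, 0), (1, -1)),
)

#: Boundary ring of a 3x3 patch in compass order N, NE, E, SE, S, SW, W, NW.
_RING: tuple[tuple[int, int], ...] = (
    (0, 1), (0, 2), (1, 2), (2, 2), (2, 1), (2, 0), (1, 0), (0, 0),
)


@dataclass(frozen=True)
class GridSpec:
    """Spatial grid dividing each frame into rows x cols cells."""

    rows: int
    cols: int

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError(f"grid must be at least 1x1, got {self.rows}x{self.cols}")

    @property
    def n_cells(self) -> int:
        return self.rows * self.cols

    def validate_for(self, h: int, w: int) -> None:
        # each codable pixel (1-pixel margin removed) must fall in some cell
        if self.rows > h - 2 or self.cols > w - 2:
            raise ValueError(
                f"grid {self.rows}x{self.cols} too fine for {h}x{w} frames"
            )


@dataclass(frozen=True)
class CubeView:
    """A single 3x3x3 patch: (t-dt, t, t+dt) x 3 rows x 3 cols."""

    values: np.ndarray
    center: tuple[int, int, int]  # (t, y, x)
    dt: int

    def __post_init__(self) -> None:
        if np.asarray(self.values).shape != (3, 3, 3):
            raise ValueError("cube must be 3x3x3")


def cube_view(seq: FrameSequence, t: int, y: int, x: int, dt: int = 1) -> CubeView:
    """Extract the cube centered at (t, y, x); must lie fully inside."""
    if not (dt <= t <= seq.T - 1 - dt and 1 <= y <= seq.H - 2 and 1 <= x <= seq.W - 2):
        raise ValueError(f"cube center ({t},{y},{x}) with dt={dt} is not interior")
    vals = np.stack(
        [seq.pixels[t + k * dt, y - 1 : y + 2, x - 1 : x + 2] for k in (-1, 0, 1)]
    )
    return CubeView(values=vals, center=(t, y, x), dt=dt)


def build_direction_masks() -> np.ndarray:
    """Eight signed 3x3 compass masks, ordered N, NE, E, SE, S, SW, W, NW.

    Mask i carries +1 on the boundary cell in compass direction i and its
    two ring neighbors, and -3 at the center; all other cells are 0, so
    every mask sums to zero (uniform patches give zero response).
    """
    masks = np.zeros((8, 3, 3), dtype=np.int64)
    for i in range(8):
        for k in (-1, 0, 1):
            masks[i][_RING[(i + k) % 8]] = 1
        masks[i, 1, 1] = -3
    return masks


def single_frame_mask() -> np.ndarray:
    """Center-surround 3x3 mask: 8 at the center, -1 elsewhere (zero-sum)."""
    m = -np.ones((3, 3), dtype=np.int64)
    m[1, 1] = 8
    return m


def extract_temporal_planes(cube: CubeView) -> np.ndarray:
    """The four 3x3 temporal planes of a cube, shape (4, 3, 3).

    Rows are time ascending (t-dt, t, t+dt); columns follow the plane's
    spatial line in raster order, so the middle column of every plane is
    the three temporal center pixels.
    """
    planes = np.empty((4, 3, 3), dtype=cube.values.dtype)
    for j, offs in enumerate(PLANE_OFFSETS):
        for b, (dy, dx) in enumerate(offs):
            planes[j, :, b] = cube.values[:, 1 + dy, 1 + dx]
    return planes


def _frame_triples(seq: FrameSequence, dt: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if dt < 1:
        raise ValueError(f"dt must be >= 1, got {dt}")
    if seq.T < 2 * dt + 1:
        raise ValueError(f"sequence of length {seq.T} too short for dt={dt}")
    px = seq.pixels
    n = seq.T - 2 * dt
    return px[:n], px[dt : dt + n], px[2 * dt : 2 * dt + n]


def _shifted(frames: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Interior window of `frames` shifted by (dy, dx) relative to center."""
    h, w = frames.shape[1:]
    return frames[:, 1 + dy : h - 1 + dy, 1 + dx : w - 1 + dx]


def spatial_difference_codes(seq: FrameSequence, dt: int = 1) -> np.ndarray:
    """Spatial Difference LCBP codes, shape (3, T-2dt, H-2, W-2), ints 0..255.

    Stream i compares the eight neighbors of frame t+dt against center
    pixel c_i of frame t + (i-1)*dt; a bit is set when the difference is
    non-negative.
    """
    f0, f1, f2 = _frame_triples(seq, dt)
    centers = (_shifted(f0, 0, 0), _shifted(f1, 0, 0), _shifted(f2, 0, 0))
    codes = np.zeros((3,) + centers[0].shape, dtype=np.int64)
    for n, (dy, dx) in enumerate(NEIGHBOR_OFFSETS):
        xn = _shifted(f2, dy, dx)
        for i, ci in enumerate(centers):
            codes[i] += (xn >= ci).astype(np.int64) << n
    return codes


def temporal_direction_codes(seq: FrameSequence, dt: int = 1) -> np.ndarray:
    """Temporal Direction LCBP codes, shape (4, T-2dt, H-2, W-2), ints 0..63.

    For each plane j the eight mask responses are computed and the code is
    ``8 * argmax + argmin``; ties go to the lowest mask index.
    """
    f0, f1, f2 = _frame_triples(seq, dt)
    masks = build_direction_masks().astype(np.float64)
    codes = np.empty((4,) + _shifted(f1, 0, 0).shape, dtype=np.int64)
    for j, offs in enumerate(PLANE_OFFSETS):
        # plane stack: (n, Hi, Wi, time, line-position)
        plane = np.stack(
            [
                np.stack([_shifted(f, dy, dx) for (dy, dx) in offs], axis=-1)
                for f in (f0, f1, f2)
            ],
            axis=-2,
        )
        resp = np.einsum("nhwab,mab->nhwm", plane, masks)
        codes[j] = 8 * np.argmax(resp, axis=-1) + np.argmin(resp, axis=-1)
    return codes


def _surround_response(frames: np.ndarray) -> np.ndarray:
    """Response of the center-surround mask: 9*center - sum of 3x3 patch."""
    patch_sum = np.zeros_like(_shifted(frames, 0, 0))
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            patch_sum = patch_sum + _shifted(frames, dy, dx)
    return 9.0 * _shifted(frames, 0, 0) - patch_sum


def temporal_gradient_codes(seq: FrameSequence, dt: int = 1) -> np.ndarray:
    """Temporal Gradient LCBP codes, shape (T-2dt, H-2, W-2), ints 0..3.

    With g1 = (S_t - S_{t-dt})/dt and g2 = (S_{t+dt} - S_t)/dt, the code is
    the 2-bit pattern (g1>=0, g2>=0): 3 = steadily brightening, 0 = steadily
    darkening, 2 = brightened then darkened, 1 = darkened then brightened.
    """
    f0, f1, f2 = _frame_triples(seq, dt)
    s0, s1, s2 = (_surround_response(f) for f in (f0, f1, f2))
    g1 = (s1 - s0) / dt
    g2 = (s2 - s1) / dt
    return 2 * (g1 >= 0).astype(np.int64) + (g2 >= 0).astype(np.int64)


def _cell_index_maps(h: int, w: int, grid: GridSpec, margin: int) -> tuple[np.ndarray, np.ndarray]:
    # cell width = floor(size/count); the last row/column absorbs the remainder
    ys = margin + np.arange(h - 2 * margin)
    xs = margin + np.arange(w - 2 * margin)
    row = np.minimum(ys // max(h // grid.rows, 1), grid.rows - 1)
    col = np.minimum(xs // max(w // grid.cols, 1), grid.cols - 1)
    return row, col


def grid_histograms(
    codes: np.ndarray,
    frame_shape: tuple[int, int],
    grid: GridSpec,
    n_bins: int,
    normalize: bool = True,
    margin: int = 1,
) -> np.ndarray:
    """Accumulate one histogram per grid cell from a code map.

    Parameters
    ----------
    codes
        Integer code map of shape ``(..., H - 2*margin, W - 2*margin)``;
        leading axes (time, or streams x time) are pooled into the same
        cell histograms.
    frame_shape
        Original (H, W); cell boundaries are laid out on the full frame and
        positions are offset by ``margin``.

    Returns an array of shape ``(rows, cols, n_bins)``.  With
    ``normalize=True`` each cell histogram is L1-normalized (all-zero cells
    stay zero).
    """
    h, w = frame_shape
    codes = np.asarray(codes)
    if codes.min() < 0 or codes.max() >= n_bins:
        raise ValueError(
            f"codes outside [0, {n_bins}): range [{codes.min()}, {codes.max()}]"
        )
    row, col = _cell_index_maps(h, w, grid, margin)
    cell = (row[:, None] * grid.cols + col[None, :]).astype(np.int64)
    flat = (cell * n_bins + codes).ravel()
    hist = np.bincount(flat, minlength=grid.n_cells * n_bins).astype(np.float64)
    hist = hist.reshape(grid.rows, grid.cols, n_bins)
    if normalize:
        sums = hist.sum(axis=-1, keepdims=True)
        np.divide(hist, sums, out=hist, where=sums > 0)
    return hist


@dataclass
class EnhancedLCBPFeature:
    """Per-sample Enhanced LCBP feature: a spatial and a temporal block.

    ``spatial`` concatenates, cell by cell, the three 256-bin spatial
    difference histograms (768 values per cell); ``temporal`` concatenates
    the four 64-bin direction histograms and the 4-bin gradient histogram
    (260 values per cell).  ``layout`` records grid, bins, offsets, dt and
    normalization for serialization.
    """

    spatial: np.ndarray = field(repr=False)
    temporal: np.ndarray = field(repr=False)
    grid: GridSpec
    normalized: bool
    layout: dict = field(default_factory=dict)

    SPATIAL_PER_CELL = 3 * SPATIAL_BINS
    TEMPORAL_PER_CELL = 4 * DIRECTION_BINS + GRADIENT_BINS

    def spatial_by_cell(self) -> np.ndarray:
        """Spatial block as (n_cells, 768)."""
        return self.spatial.reshape(self.grid.n_cells, self.SPATIAL_PER_CELL)

    def temporal_by_cell(self) -> np.ndarray:
        """Temporal block as (n_cells, 260)."""
        return self.temporal.reshape(self.grid.n_cells, self.TEMPORAL_PER_CELL)


def extract_enhanced_lcbp(
    seq: FrameSequence,
    grid: GridSpec,
    dt: int = 1,
    normalize: bool = True,
) -> EnhancedLCBPFeature:
    """Compute the full Enhanced LCBP feature of one sequence."""
    grid.validate_for(seq.H, seq.W)
    shape = (seq.H, seq.W)

    sd = spatial_difference_codes(seq, dt)
    spatial_cells = [
        grid_histograms(sd[i], shape, grid, SPATIAL_BINS, normalize) for i in range(3)
    ]
    # (rows, cols, 3*256) -> flat, cell-major
    spatial = np.concatenate(spatial_cells, axis=-1).ravel()

    td = temporal_direction_codes(seq, dt)
    tg = temporal_gradient_codes(seq, dt)
    temporal_cells = [
        grid_histograms(td[j], shape, grid, DIRECTION_BINS, normalize) for j in range(4)
    ]
    temporal_cells.append(grid_histograms(tg, shape, grid, GRADIENT_BINS, normalize))
    temporal = np.concatenate(temporal_cells, axis=-1).ravel()

    layout = {
        "grid": [grid.rows, grid.cols],
        "dt": dt,
        "normalize": normalize,
        "spatial_bins": [SPATIAL_BINS] * 3,
        "temporal_bins": [DIRECTION_BINS] * 4 + [GRADIENT_BINS],
        "spatial_per_cell": EnhancedLCBPFeature.SPATIAL_PER_CELL,
        "temporal_per_cell": EnhancedLCBPFeature.TEMPORAL_PER_CELL,
        "cell_order": "row-major",
    }
    return EnhancedLCBPFeature(
        spatial=spatial, temporal=temporal, grid=grid, normalized=normalize, layout=layout
    )


def save_feature_table(
    path: str | Path,
    sample_ids: list[str],
    subject_ids: list[str],
    labels: list[str],
    features: list[EnhancedLCBPFeature],
) -> None:
    """Write one row per sample (ids, label, spatial then temporal values)
    as TSV, plus a JSON sidecar describing the block layout."""
    path = Path(path)
    mat = np.stack([np.concatenate([f.spatial, f.temporal]) for f in features])
    table = pd.DataFrame(mat)
    table.insert(0, "label", labels)
    table.insert(0, "subject_id", subject_ids)
    table.insert(0, "sample_id", sample_ids)
    table.to_csv(path, sep="\t", index=False)
    layout = dict(features[0].layout)
    layout["spatial_length"] = int(features[0].spatial.size)
    layout["temporal_length"] = int(features[0].temporal.size)
    Path(str(path) + ".layout.json").write_text(json.dumps(layout, indent=2))


def load_feature_table(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read a feature table and its layout sidecar."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    layout = json.loads(Path(str(path) + ".layout.json").read_text())
    return table, layout
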