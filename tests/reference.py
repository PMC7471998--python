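"""Naive scalar reference implementations of the three code streams.

These are deliberately written as literal per-pixel loops from the code
definitions — explicit mask tables, explicit plane index lists, explicit
bit accumulation — independent of the vectorized package code, to serve
as oracles in equivalence tests.
"""

import numpy as np

# eight neighbors, top-left then clockwise (bit n has weight 2^n)
_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)]

# compass masks N, NE, E, SE, S, SW, W, NW written out by hand
_MASKS = [
    [[1, 1, 1], [0, -3, 0], [0, 0, 0]],       # N
    [[0, 1, 1], [0, -3, 1], [0, 0, 0]],       # NE
    [[0, 0, 1], [0, -3, 1], [0, 0, 1]],       # E
    [[0, 0, 0], [0, -3, 1], [0, 1, 1]],       # SE
    [[0, 0, 0], [0, -3, 0], [1, 1, 1]],       # S
    [[0, 0, 0], [1, -3, 0], [1, 1, 0]],       # SW
    [[1, 0, 0], [1, -3, 0], [1, 0, 0]],       # W
    [[1, 1, 0], [1, -3, 0], [0, 0, 0]],       # NW
]

# spatial line of each temporal plane, in raster order:
# horizontal, vertical, main diagonal, anti-diagonal
_PLANE_LINES = [
    [(0, -1), (0, 0), (0, 1)],
    [(-1, 0), (0, 0), (1, 0)],
    [(-1, -1), (0, 0), (1, 1)],
    [(-1, 1), (0, 0), (1, -1)],
]


def naive_spatial_codes(pixels: np.ndarray, dt: int = 1) -> np.ndarray:
    """(3, T-2dt, H-2, W-2) spatial-difference codes, one bit at a time."""
    T, H, W = pixels.shape
    out = np.zeros((3, T - 2 * dt, H - 2, W - 2), dtype=np.int64)
    for ti, t in enumerate(range(dt, T - dt)):
        for y in range(1, H - 1):
            for x in range(1, W - 1):
                centers = [pixels[t - dt, y, x], pixels[t, y, x], pixels[t + dt, y, x]]
                for i, c in enumerate(centers):
                    code = 0
                    for n, (dy, dx) in enumerate(_NEIGHBORS):
                        if pixels[t + dt, y + dy, x + dx] - c >= 0:
                            code += 2**n
                    out[i, ti, y - 1, x - 1] = code
    return out


def naive_direction_codes(pixels: np.ndarray, dt: int = 1) -> np.ndarray:
    """(4, T-2dt, H-2, W-2) direction codes from all 32 mask responses."""
    T, H, W = pixels.shape
    out = np.zeros((4, T - 2 * dt, H - 2, W - 2), dtype=np.int64)
    for ti, t in enumerate(range(dt, T - dt)):
        for y in range(1, H - 1):
            for x in range(1, W - 1):
                for j, line in enumerate(_PLANE_LINES):
                    # plane: rows = time ascending, cols = line position
                    plane = [
                        [pixels[t + k * dt, y + dy, x + dx] for (dy, dx) in line]
                        for k in (-1, 0, 1)
                    ]
                    responses = []
                    for mask in _MASKS:
                        r = 0.0
                        for a in range(3):
                            for b in range(3):
                                r += mask[a][b] * plane[a][b]
                        responses.append(r)
                    max_i = responses.index(max(responses))
                    min_i = responses.index(min(responses))
                    out[j, ti, y - 1, x - 1] = 8 * max_i + min_i
    return out


def naive_gradient_codes(pixels: np.ndarray, dt: int = 1) -> np.ndarray:
    """(T-2dt, H-2, W-2) gradient codes from center-surround responses."""
    T, H, W = pixels.shape

    def s_response(t, y, x):
        r = 8.0 * pixels[t, y, x]
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dy, dx) != (0, 0):
                    r -= pixels[t, y + dy, x + dx]
        return r

    out = np.zeros((T - 2 * dt, H - 2, W - 2), dtype=np.int64)
    for ti, t in enumerate(range(dt, T - dt)):
        for y in range(1, H - 1):
            for x in range(1, W - 1):
                s0 = s_response(t - dt, y, x)
                s1 = s_response(t, y, x)
                s2 = s_response(t + dt, y, x)
                g1 = (s1 - s0) / dt
                g2 = (s2 - s1) / dt
                out[ti, y - 1, x - 1] = 2 * (g1 >= 0) + (g2 >= 0)
    return out
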