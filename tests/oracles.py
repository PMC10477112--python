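"""Independent brute-force oracles used to check the image primitives.

Each oracle recomputes a quantity by direct enumeration (plain loops, dense
convolution, breadth-first flood fill) with no code shared with the library
paths it checks.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def dense_gaussian_blur(volume: np.ndarray, sigma: float) -> np.ndarray:
    """Separable Gaussian blur via explicit shifted-slab accumulation.

    Kernel: sampled Gaussian truncated at 4 sigma and normalized; boundaries
    mirrored (half-sample symmetric).
    """
    radius = int(4.0 * sigma + 0.5)
    offsets = np.arange(-radius, radius + 1)
    kernel = np.exp(-(offsets**2) / (2.0 * sigma**2))
    kernel /= kernel.sum()
    out = volume.astype(np.float64)
    for axis in range(3):
        pad = [(radius, radius) if a == axis else (0, 0) for a in range(3)]
        padded = np.pad(out, pad, mode="symmetric")
        acc = np.zeros_like(out)
        for j, w in enumerate(kernel):
            sl = [slice(None)] * 3
            sl[axis] = slice(j, j + out.shape[axis])
            acc += w * padded[tuple(sl)]
        out = acc
    return out


def li_scan_oracle(plane: np.ndarray) -> float:
    """Exhaustive scan of the minimum-cross-entropy objective, plain loops.

    Candidate thresholds are every distinct intensity above the minimum;
    background is v < t, foreground v >= t; zero-mass classes contribute 0.
    Returns the lowest candidate attaining the minimum objective.
    """
    values = np.asarray(plane, dtype=np.float64).ravel()
    candidates = sorted(set(values.tolist()))[1:]
    best_t, best_obj = None, None
    for t in candidates:
        bg = values[values < t]
        fg = values[values >= t]
        obj = 0.0
        if bg.size and bg.sum() > 0:
            obj -= bg.sum() * math.log(bg.mean())
        if fg.size and fg.sum() > 0:
            obj -= fg.sum() * math.log(fg.mean())
        if best_obj is None or obj < best_obj:
            best_obj, best_t = obj, t
    return float(best_t)


def triangle_geometric_oracle(plane: np.ndarray, bins: int = 256) -> float:
    """Point-to-chord distance scan for the Triangle threshold.

    Explicit geometric construction: normalize the histogram to unit peak,
    pick the longer-tail side, walk every bin between the peak and the
    farthest non-empty bin computing the perpendicular distance to the chord,
    and return the intensity cut at the winning bin.
    """
    values = np.asarray(plane, dtype=np.float64).ravel()
    vmin, vmax = values.min(), values.max()
    hist, edges = np.histogram(values, bins=bins, range=(vmin, vmax))
    peak = int(np.argmax(hist))
    nonzero = [i for i, h in enumerate(hist) if h > 0]
    first_nz, last_nz = nonzero[0], nonzero[-1]

    flipped = (peak - first_nz) > (last_nz - peak)
    if flipped:
        hist = hist[::-1]
        peak = bins - 1 - peak
        last_nz = bins - 1 - first_nz

    end = last_nz
    if end - peak < 2:
        cut = peak
    else:
        y = hist / hist[peak]
        # chord through (peak, 1) and (end, y[end]) as ax + by + c = 0
        a = y[end] - 1.0
        b = float(peak - end)
        c = -(a * peak + b * 1.0)
        denom = math.hypot(a, b)
        cut, best = None, -math.inf
        for i in range(peak + 1, end):
            signed = (a * i + b * y[i] + c) / denom  # > 0 below the chord
            if signed > best:
                best, cut = signed, i

    if flipped:
        return float(edges[bins - 1 - cut])
    return float(edges[cut + 1])


def flood_fill_sizes(binary: np.ndarray, connectivity: int = 26) -> list[int]:
    """Connected-component sizes by breadth-first flood fill."""
    binary = np.asarray(binary, dtype=bool)
    if connectivity == 26:
        neigh = [(dz, dy, dx)
                 for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                 if (dz, dy, dx) != (0, 0, 0)]
    else:
        neigh = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    seen = np.zeros_like(binary, dtype=bool)
    sizes = []
    Z, Y, X = binary.shape
    for z in range(Z):
        for y in range(Y):
            for x in range(X):
                if binary[z, y, x] and not seen[z, y, x]:
                    queue = deque([(z, y, x)])
                    seen[z, y, x] = True
                    size = 0
                    while queue:
                        cz, cy, cx = queue.popleft()
                        size += 1
                        for dz, dy, dx in neigh:
                            nz, ny, nx = cz + dz, cy + dy, cx + dx
                            if (0 <= nz < Z and 0 <= ny < Y and 0 <= nx < X
                                    and binary[nz, ny, nx] and not seen[nz, ny, nx]):
                                seen[nz, ny, nx] = True
                                queue.append((nz, ny, nx))
                    sizes.append(size)
    return sizes


def threshold_fixture_planes(n: int = 24, seed: int = 20_260_920) -> list[np.ndarray]:
    """Fixed 8-bit planes exercising varied histogram shapes.

    Mixtures of two populations, spike-plus-geometric-tail, uniform fields
    with a bright blob — all generated from one frozen seed.
    """
    rng = np.random.default_rng(seed)
    planes = []
    for k in range(n):
        kind = k % 3
        if kind == 0:  # two Gaussian populations
            frac = 0.05 + 0.03 * (k % 7)
            lo = rng.normal(30 + 2 * k, 6, size=(48, 48))
            hi = rng.normal(170 + 3 * k % 60, 12, size=(48, 48))
            pick = rng.random((48, 48)) < frac
            plane = np.where(pick, hi, lo)
        elif kind == 1:  # spike at low level with geometric tail
            plane = np.full((48, 48), 10.0 + k)
            tail_n = 300 + 10 * k
            tail = 10.0 + k + rng.geometric(0.08, size=tail_n) * 2.0
            idx = rng.choice(48 * 48, size=tail_n, replace=False)
            plane.ravel()[idx] = tail
        else:  # flat background plus a bright square blob
            plane = rng.normal(25, 4, size=(48, 48))
            j = 4 + (k % 5)
            plane[j:j + 12, j:j + 12] += 140 + 5 * k
        planes.append(np.clip(np.rint(plane), 0, 255).astype(np.uint8))
    return planes
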