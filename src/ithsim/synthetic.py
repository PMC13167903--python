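"""Programmatic reference shapes and synthetic cell populations.

These generators provide analytically understood inputs for the metric
pipelines: filled disks and Sierpinski carpets with known box-counting
dimensions, quadratic Koch islands with fractal boundaries, complete
spatial randomness point patterns, and spatially segregated multi-clone
cell tables for sampling studies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import GENOME_SIZE, default_driver_map


def disk_mask(radius: int, pad: int = 4) -> np.ndarray:
    """Filled disk; a plane-filling set with box-counting dimension 2."""
    n = 2 * (radius + pad) + 1
    yy, xx = np.mgrid[:n, :n]
    c = radius + pad
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


def sierpinski_carpet(depth: int) -> np.ndarray:
    """Sierpinski carpet of side 3**depth; dimension log 8 / log 3."""
    mask = np.ones((1, 1), dtype=bool)
    for _ in range(depth):
        n = mask.shape[0]
        out = np.zeros((3 * n, 3 * n), dtype=bool)
        for i in range(3):
            for j in range(3):
                if i == 1 and j == 1:
                    continue
                out[i * n:(i + 1) * n, j * n:(j + 1) * n] = mask
        mask = out
    return mask


def quadratic_koch_island(depth: int, seg: int | None = None) -> np.ndarray:
    """Filled region bounded by a quadratic Koch (Minkowski) curve.

    Each square side is recursively replaced by the 8-segment generator
    (scale 1/4), giving a boundary of similarity dimension log 8 / log 4
    = 1.5.  Returns a filled binary mask whose boundary approximates the
    curve at the given depth.
    """
    from skimage.draw import polygon

    n = seg or 4 ** depth

    def expand(pts: list[tuple[float, float]]) -> list[tuple[float, float]]:
        out = [pts[0]]
        for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
            dx, dy = (x1 - x0) / 4.0, (y1 - y0) / 4.0
            px, py = -dy, dx  # left normal
            path = [
                (x0 + dx, y0 + dy),
                (x0 + dx + px, y0 + dy + py),
                (x0 + 2 * dx + px, y0 + 2 * dy + py),
                (x0 + 2 * dx, y0 + 2 * dy),
                (x0 + 2 * dx - px, y0 + 2 * dy - py),
                (x0 + 3 * dx - px, y0 + 3 * dy - py),
                (x0 + 3 * dx, y0 + 3 * dy),
                (x1, y1),
            ]
            out.extend(path)
        return out

    s = float(n)
    square = [(0.0, 0.0), (s, 0.0), (s, s), (0.0, s), (0.0, 0.0)]
    pts = square
    for _ in range(depth):
        pts = expand(pts)
    arr = np.asarray(pts)
    arr -= arr.min(axis=0) - 2
    size = int(np.ceil(arr.max())) + 3
    mask = np.zeros((size, size), dtype=bool)
    rr, cc = polygon(arr[:, 1], arr[:, 0], shape=mask.shape)
    mask[rr, cc] = True
    return mask


def csr_pattern(
    n: int, window: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """n points uniformly distributed over the window (CSR)."""
    w, h = window
    return rng.random((n, 2)) * np.array([w, h])


def segregated_clones(
    n_cells: int = 4000,
    n_clones: int = 8,
    grid_size: int = 200,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Spatially segregated multi-clone population (snapshot cell table).

    Each clone fills a compact, densely packed lattice patch in its own
    region of the grid (Eden-like randomized growth from a seed site) and
    carries a distinct genome: BRAF plus a private block of 2-6 passenger
    mutations, so both clone identity and mutation burden vary spatially.
    Clone sizes come from a Dirichlet prior (unbalanced population); birth
    steps are uniform and independent of clone, reflecting the weak link
    between birth order and genotype that stochastic death and mutation
    produce in grown tumors.
    """
    rng = rng or np.random.default_rng(0)
    dm = default_driver_map()
    braf = dm.index_of("BRAF")
    weights = rng.dirichlet(np.full(n_clones, 4.0))
    sizes = np.maximum(1, np.round(weights * n_cells).astype(int))
    # clone seed sites on a jittered ring so patches stay segregated
    angles = 2 * np.pi * (np.arange(n_clones) + rng.random(n_clones) * 0.3) / n_clones
    R = grid_size * 0.33
    centers = np.stack([
        grid_size / 2 + R * np.cos(angles),
        grid_size / 2 + R * np.sin(angles),
    ], axis=1)
    rows, cols, genomes, births = [], [], [], []
    occupied: set[tuple[int, int]] = set()
    n_drv = len(dm.driver_indices)
    n_private = rng.integers(2, 7, size=n_clones)
    nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1), (-1, -1), (-1, 1), (1, -1), (1, 1)]
    for ci in range(n_clones):
        g = np.zeros(GENOME_SIZE, dtype=np.uint8)
        g[braf] = 1
        start = n_drv + ci * 5
        g[start: start + int(n_private[ci])] = 1
        gstr = "".join(map(str, g))
        seed = (int(round(centers[ci][0])), int(round(centers[ci][1])))
        frontier = [seed]
        placed = 0
        while placed < sizes[ci] and frontier:
            j = int(rng.integers(len(frontier)))
            r_i, c_i = frontier.pop(j)
            if (r_i, c_i) in occupied:
                continue
            if not (0 <= r_i < grid_size and 0 <= c_i < grid_size):
                continue
            occupied.add((r_i, c_i))
            rows.append(r_i)
            cols.append(c_i)
            genomes.append(gstr)
            placed += 1
            for dr, dc in nbrs:
                nxt = (r_i + dr, c_i + dc)
                if nxt not in occupied:
                    frontier.append(nxt)
        births.extend(rng.integers(0, 500, size=placed).tolist())
    m = len(rows)
    return pd.DataFrame({
        "cell_id": np.arange(m),
        "type": "MTC",
        "row": rows,
        "col": cols,
        "birth_step": births,
        "a0": 1.5,
        "genome": genomes,
    })
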