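"""Tumor morphology metrics and the cross-pair correlation function.

Convexity C = P_H / P compares the marching-squares perimeter P of the
tumor's largest connected component with the perimeter P_H of its convex
hull; C = 1 for convex shapes and falls as the border becomes infiltrative.
The border fractal dimension FD_b applies box counting to the one-pixel
boundary of the mask.  The cross-pair correlation function (cPCF) measures
how a target cell type arranges itself at radial distance r from a
reference type: 1 under complete spatial randomness, > 1 for clustering,
< 1 for anti-clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import simpson
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import cdist
from skimage import measure
from scipy import ndimage

from .genome import DriverMap, default_driver_map
from .ith import box_counting_fd, genome_matrix


class DegenerateShapeError(ValueError):
    pass


@dataclass(frozen=True)
class PointPattern:
    """Planar point pattern inside an axis-aligned rectangular window."""

    points: np.ndarray            # (N, 2) coordinates
    window: tuple[float, float]   # (width, height); window is [0,W] x [0,H]

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (N, 2) array")
        w, h = self.window
        if pts.size and (
            pts[:, 0].min() < 0 or pts[:, 0].max() > w
            or pts[:, 1].min() < 0 or pts[:, 1].max() > h
        ):
            raise ValueError("all points must lie inside the window")


@dataclass(frozen=True)
class MorphologyReport:
    C: float
    P: float
    P_H: float
    FD_b: float
    n_satellites: int = 0


# ---------------------------------------------------------------------------
# masks and morphology


def tumor_mask(snapshot: pd.DataFrame, grid_size: int | None = None) -> np.ndarray:
    """Binary occupancy grid of MTC sites (NCs and CTLs excluded)."""
    mtc = snapshot[snapshot["type"] == "MTC"]
    if grid_size is None:
        grid_size = int(snapshot[["row", "col"]].to_numpy().max()) + 1 if len(snapshot) else 1
    mask = np.zeros((grid_size, grid_size), dtype=bool)
    if len(mtc):
        mask[mtc["row"].to_numpy(), mtc["col"].to_numpy()] = True
    return mask


def largest_component(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """Largest Moore-connected component and the number of components."""
    labels, n = measure.label(mask, connectivity=2, return_num=True)
    if n == 0:
        raise DegenerateShapeError("empty mask")
    sizes = np.bincount(labels.ravel())[1:]
    comp = labels == (int(np.argmax(sizes)) + 1)
    return comp, n


def convexity(mask: np.ndarray) -> tuple[float, float, float]:
    """(C, P, P_H) of the mask's largest connected component.

    P is the sub-pixel marching-squares contour length (the longest
    contour, i.e. the outer boundary); P_H the convex hull perimeter of
    the occupied site centers.  C = P_H / P is clipped to 1.
    """
    comp, _ = largest_component(np.asarray(mask).astype(bool))
    pts = np.argwhere(comp).astype(np.float64)
    if len(pts) < 3:
        raise DegenerateShapeError("need at least 3 occupied sites")
    padded = np.pad(comp, 1).astype(np.float64)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise DegenerateShapeError("no contour found")
    P = max(float(np.linalg.norm(np.diff(c, axis=0), axis=1).sum()) for c in contours)
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:  # collinear sites
        raise DegenerateShapeError("degenerate (collinear) component") from exc
    P_H = float(hull.area)  # scipy 2D hull: .area is the perimeter
    return min(1.0, P_H / P), P, P_H


def boundary_mask(mask: np.ndarray) -> np.ndarray:
    """One-pixel boundary of the largest component (Moore erosion residue)."""
    comp, _ = largest_component(np.asarray(mask).astype(bool))
    eroded = ndimage.binary_erosion(comp, structure=np.ones((3, 3)), border_value=0)
    return comp & ~eroded


def border_fd(mask: np.ndarray) -> float:
    """Box-counting dimension of the tumor boundary."""
    return box_counting_fd(boundary_mask(mask))


def morphology_report(mask: np.ndarray) -> MorphologyReport:
    C, P, P_H = convexity(mask)
    _, n = largest_component(np.asarray(mask).astype(bool))
    return MorphologyReport(C=C, P=P, P_H=P_H, FD_b=border_fd(mask), n_satellites=n - 1)


# ---------------------------------------------------------------------------
# cross-pair correlation function


def circle_window_area(
    cx: np.ndarray, cy: np.ndarray, radii: np.ndarray, window: tuple[float, float],
    n_nodes: int = 257,
) -> np.ndarray:
    """Area of circle(center, r) intersected with [0,W] x [0,H].

    Evaluated by Simpson integration of the clipped vertical chord length;
    accurate to a relative error far below the Monte-Carlo noise of the
    pair-correlation estimator.  Returns shape (n_points, n_radii).
    """
    W, H = window
    cx = np.asarray(cx, dtype=np.float64)[:, None, None]
    cy = np.asarray(cy, dtype=np.float64)[:, None, None]
    r = np.asarray(radii, dtype=np.float64)[None, :, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        # angular substitution x = cx - r cos(theta): the chord length
        # r sin(theta) appears as the Jacobian, removing the sqrt endpoint
        # singularity so Simpson converges fast
        th0 = np.arccos(np.clip(np.divide(cx - 0.0, r), -1.0, 1.0))
        th1 = np.arccos(np.clip(np.divide(cx - W, r), -1.0, 1.0))
    t = np.linspace(0.0, 1.0, n_nodes)[None, None, :]
    theta = th0 + (th1 - th0) * t
    sin_t = np.sin(theta)
    h = r * sin_t
    ylen = np.maximum(np.minimum(cy + h, H) - np.maximum(cy - h, 0.0), 0.0)
    area = simpson(ylen * r * sin_t, x=theta, axis=-1)
    return np.maximum(area, 0.0)


def cross_pcf(
    reference: np.ndarray | PointPattern,
    target: np.ndarray | PointPattern,
    radii: np.ndarray,
    window: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """cPCF per annulus between a reference and a target point pattern.

    For annulus (r1, r2]:

        cPCF = mean over reference points of
               count(targets in annulus) / (lambda_t * area(annulus & window))

    with lambda_t the target intensity over the window.  The annulus area
    is intersected with the window per reference point (edge correction);
    annuli with no window overlap for any reference are reported as NaN.
    """
    if isinstance(reference, PointPattern):
        window = window or reference.window
        reference = reference.points
    if isinstance(target, PointPattern):
        window = window or target.window
        target = target.points
    ref = np.asarray(reference, dtype=np.float64)
    tgt = np.asarray(target, dtype=np.float64)
    if ref.size == 0 or tgt.size == 0:
        raise ValueError("reference and target patterns must be nonempty")
    if window is None:
        raise ValueError("a window (W, H) is required")
    edges = np.asarray(radii, dtype=np.float64)
    if edges.ndim != 1 or len(edges) < 1 or np.any(np.diff(edges) <= 0) or edges[0] <= 0:
        raise ValueError("radii must be positive and strictly increasing")
    edges = np.concatenate([[0.0], edges])
    W, H = window
    lam = len(tgt) / (W * H)

    d = cdist(ref, tgt)
    # per-reference counts in (edges[j], edges[j+1]]
    bins = np.searchsorted(edges, d, side="left")  # d in (e[b-1], e[b]] -> b
    n_ann = len(edges) - 1
    counts = np.zeros((len(ref), n_ann))
    for j in range(1, n_ann + 1):
        counts[:, j - 1] = (bins == j).sum(axis=1)

    disc = circle_window_area(ref[:, 0], ref[:, 1], edges, window)
    areas = np.diff(disc, axis=1)  # (n_ref, n_ann)

    vals = np.full(n_ann, np.nan)
    for j in range(n_ann):
        ok = areas[:, j] > 1e-9
        if ok.any():
            vals[j] = float(np.mean(counts[ok, j] / (lam * areas[ok, j])))
    return pd.DataFrame({
        "r_inner": edges[:-1], "r_outer": edges[1:], "cpcf": vals,
    })


def aggressiveness_rank_pcf(
    snapshot: pd.DataFrame,
    radii: np.ndarray,
    window: tuple[float, float] | None = None,
    driver_map: DriverMap | None = None,
) -> dict[str, pd.DataFrame]:
    """cPCF curves of each aggressiveness group against the most aggressive.

    Cells are grouped by their driver mutation count; the group with the
    highest count is the reference.  Remaining groups are ranked by
    decreasing driver count and labeled "2", "3", ...; normal cells (zero
    drivers) are labeled "NC" and come last.
    """
    dm = driver_map or default_driver_map()
    melan = snapshot[snapshot["type"] != "CTL"]
    M = genome_matrix(melan)
    ndrv = M[:, dm.driver_indices].sum(axis=1).astype(int)
    counts = np.unique(ndrv)
    if len(counts) < 2:
        raise DegenerateShapeError("need at least two distinct driver counts")
    if window is None:
        g = int(melan[["row", "col"]].to_numpy().max()) + 1
        window = (float(g), float(g))
    pos = melan[["row", "col"]].to_numpy(dtype=np.float64)
    ref_pts = pos[ndrv == counts[-1]]
    out: dict[str, pd.DataFrame] = {}
    rank = 2
    for cval in counts[:-1][::-1]:  # decreasing driver count
        label = "NC" if cval == 0 else str(rank)
        out[label] = cross_pcf(ref_pts, pos[ndrv == cval], radii, window)
        rank += 1
    return out
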