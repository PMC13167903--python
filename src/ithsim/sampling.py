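"""Population sampling strategies and their error against full-population ITH.

Four strategies estimate the heterogeneity entropy (epsilon) and mean
mutation count (beta) from a fraction (default 10%) of the cells:

* SRS -- simple random sampling without replacement;
* TS  -- time systematic: cells sorted by birth step, every k-th taken
         from a random offset;
* SS  -- space systematic: a regular grid of nodes with random offset is
         laid over the tumor and the nearest untaken cell to each node is
         sampled;
* CC  -- stratified sampling via a CLARANS-style randomized k-medoids
         search on (position, driver profile) features, sampling
         proportionally within clusters.

Errors are percentages relative to the metrics computed on the entire
population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .genome import DriverMap, default_driver_map
from .ith import entropy_from_profiles, genome_matrix, mean_mutation_count

METHODS = ("SRS", "CC", "TS", "SS")


@dataclass(frozen=True)
class SamplePlan:
    method: str = "SRS"
    fraction: float = 0.10
    # CLARANS hyperparameters (CC only)
    k: int = 8
    numlocal: int = 2
    maxneighbor: int = 50

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError("fraction must lie in (0, 1]")


class SampleSizeError(ValueError):
    pass


def _melanocytes(snapshot: pd.DataFrame) -> pd.DataFrame:
    return snapshot[snapshot["type"] != "CTL"].reset_index(drop=True)


def draw_sample(
    snapshot: pd.DataFrame,
    plan: SamplePlan,
    rng: np.random.Generator,
    driver_map: DriverMap | None = None,
) -> np.ndarray:
    """Indices (into the melanocyte rows of ``snapshot``) of the sample.

    Every method returns exactly round(fraction * m) distinct cells.
    """
    cells = _melanocytes(snapshot)
    m = len(cells)
    size = int(round(plan.fraction * m))
    if size < 1:
        raise SampleSizeError(f"fraction {plan.fraction} of {m} cells is below 1")
    if size >= m:
        return np.arange(m)
    if plan.method == "SRS":
        return np.sort(rng.choice(m, size=size, replace=False))
    if plan.method == "TS":
        return _time_systematic(cells, size, rng)
    if plan.method == "SS":
        return _space_systematic(cells, size, rng)
    return _clarans_stratified(cells, size, plan, rng, driver_map)


def _time_systematic(cells: pd.DataFrame, size: int, rng: np.random.Generator) -> np.ndarray:
    order = np.argsort(cells["birth_step"].to_numpy(), kind="stable")
    m = len(order)
    # evenly spaced positions from a random fractional offset
    offset = rng.random()
    pos = np.floor((np.arange(size) + offset) * m / size).astype(np.intp) % m
    return np.sort(order[np.unique(pos)[:size]]) if len(np.unique(pos)) >= size \
        else _pad_unique(order, pos, size, rng)


def _pad_unique(order: np.ndarray, pos: np.ndarray, size: int, rng: np.random.Generator) -> np.ndarray:
    chosen = set(np.unique(pos).tolist())
    extra = [i for i in range(len(order)) if i not in chosen]
    rng.shuffle(extra)
    need = size - len(chosen)
    chosen.update(extra[:need])
    return np.sort(order[np.fromiter(chosen, dtype=np.intp)])


def _space_systematic(cells: pd.DataFrame, size: int, rng: np.random.Generator) -> np.ndarray:
    """Nearest cell to each node of a randomly offset regular grid.

    Cells sit on a unit lattice (one per site), so a block of side
    sqrt(1/fraction) holds ~1/fraction cells wherever the tumor is present
    and one sample per block realizes the target fraction.  A node only
    contributes when it lies on tumor tissue (a cell within one lattice
    unit); nodes over empty space would otherwise snap to boundary cells
    and over-represent the tumor rim.  Any shortfall is topped up
    uniformly at random.
    """
    xy = cells[["row", "col"]].to_numpy(dtype=np.float64)
    m = len(xy)
    stride = float(np.sqrt(m / size))
    lo = xy.min(axis=0)
    hi = xy.max(axis=0)
    offs = rng.random(2) * stride
    r_nodes = np.arange(lo[0] - stride + offs[0], hi[0] + stride, stride)
    c_nodes = np.arange(lo[1] - stride + offs[1], hi[1] + stride, stride)
    nodes = np.array(np.meshgrid(r_nodes, c_nodes)).reshape(2, -1).T
    rng.shuffle(nodes)
    dist, idx = cKDTree(xy).query(nodes)
    taken: list[int] = []
    seen: set[int] = set()
    for d, i in zip(dist, idx):
        if d <= 1.0 and int(i) not in seen:
            taken.append(int(i))
            seen.add(int(i))
            if len(taken) == size:
                break
    if len(taken) < size:  # sparse patterns: top up at random
        rest = np.setdiff1d(np.arange(m), np.fromiter(seen, dtype=np.intp))
        extra = rng.choice(rest, size=size - len(taken), replace=False)
        taken.extend(int(i) for i in extra)
    return np.sort(np.asarray(taken, dtype=np.intp))


def _clarans_medoids(
    X: np.ndarray, k: int, numlocal: int, maxneighbor: int, rng: np.random.Generator
) -> np.ndarray:
    """Randomized k-medoids search of the CLARANS type.

    Starting from random medoids, random (medoid, non-medoid) swaps are
    accepted whenever they lower the total distance to the nearest medoid;
    a local search ends after ``maxneighbor`` consecutive failed swaps and
    the best of ``numlocal`` restarts is returned.
    """
    m = len(X)

    def cost(meds: np.ndarray) -> float:
        d = np.linalg.norm(X[:, None, :] - X[meds][None, :, :], axis=2)
        return float(d.min(axis=1).sum())

    best_meds, best_cost = None, np.inf
    for _ in range(numlocal):
        meds = rng.choice(m, size=k, replace=False)
        cur = cost(meds)
        fails = 0
        while fails < maxneighbor:
            j = int(rng.integers(k))
            repl = int(rng.integers(m))
            if repl in meds:
                fails += 1
                continue
            trial = meds.copy()
            trial[j] = repl
            c = cost(trial)
            if c < cur:
                meds, cur = trial, c
                fails = 0
            else:
                fails += 1
        if cur < best_cost:
            best_meds, best_cost = meds, cur
    return best_meds


def _clarans_stratified(
    cells: pd.DataFrame,
    size: int,
    plan: SamplePlan,
    rng: np.random.Generator,
    driver_map: DriverMap | None,
) -> np.ndarray:
    dm = driver_map or default_driver_map()
    M = genome_matrix(cells)
    xy = cells[["row", "col"]].to_numpy(dtype=np.float64)
    span = max(float(np.ptp(xy)), 1.0)
    feats = np.hstack([xy / span, M[:, dm.driver_indices].astype(np.float64)])
    k = min(plan.k, len(cells))
    meds = _clarans_medoids(feats, k, plan.numlocal, plan.maxneighbor, rng)
    d = np.linalg.norm(feats[:, None, :] - feats[meds][None, :, :], axis=2)
    labels = d.argmin(axis=1)
    # proportional allocation with largest-remainder rounding
    sizes = np.bincount(labels, minlength=k)
    quota = sizes * size / len(cells)
    alloc = np.floor(quota).astype(int)
    rem = size - alloc.sum()
    if rem > 0:
        order = np.argsort(-(quota - alloc))
        alloc[order[:rem]] += 1
    alloc = np.minimum(alloc, sizes)
    short = size - alloc.sum()
    taken: list[int] = []
    for lab in range(k):
        members = np.flatnonzero(labels == lab)
        if alloc[lab]:
            taken.extend(rng.choice(members, size=alloc[lab], replace=False).tolist())
    if short > 0:
        rest = np.setdiff1d(np.arange(len(cells)), np.asarray(taken, dtype=np.intp))
        taken.extend(rng.choice(rest, size=short, replace=False).tolist())
    return np.sort(np.asarray(taken, dtype=np.intp))


def sampling_error(
    snapshot: pd.DataFrame,
    plan: SamplePlan,
    replicates: int,
    rng: np.random.Generator,
    driver_map: DriverMap | None = None,
) -> dict[str, float]:
    """Mean +- sd percentage error of (epsilon, beta) estimates vs the truth.

    The true values use the entire melanocyte population.  The entropy
    error falls back to an absolute error when the true entropy is zero.
    """
    cells = _melanocytes(snapshot)
    M = genome_matrix(cells)
    eps_true = entropy_from_profiles(M)
    beta_true = mean_mutation_count(M)
    eps_err, beta_err = [], []
    for _ in range(replicates):
        idx = draw_sample(cells, plan, rng, driver_map)
        Ms = M[idx]
        eps_hat = entropy_from_profiles(Ms)
        beta_hat = mean_mutation_count(Ms)
        if eps_true > 0:
            eps_err.append(100.0 * abs(eps_hat - eps_true) / eps_true)
        else:
            eps_err.append(abs(eps_hat - eps_true))
        if beta_true > 0:
            beta_err.append(100.0 * abs(beta_hat - beta_true) / beta_true)
        else:
            beta_err.append(abs(beta_hat - beta_true))
    return {
        "epsilon_mean_error": float(np.mean(eps_err)),
        "epsilon_sd_error": float(np.std(eps_err)),
        "beta_mean_error": float(np.mean(beta_err)),
        "beta_sd_error": float(np.std(beta_err)),
    }
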