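"""Genetic intratumor heterogeneity metrics.

Heterogeneity entropy follows the similarity-matrix / singular-value
construction: from the cells-by-genes binary mutation profile matrix M the
pairwise similarity is

    S_ij = 1 - Hamming(g_i, g_j) / n          (n = 50 genes)

and with s the vector of singular values of S, p_i = s_i / sum(s),

    epsilon = -sum_i p_i * ln(p_i)

so a completely monoclonal population has epsilon = 0 and b equal,
mutually fully dissimilar clones give epsilon = ln(b).  The natural
logarithm is used throughout; absolute entropy values scale accordingly.

The mean mutation count per cell, beta, proxies tumor mutational burden.
The clustered fractal dimension groups cells into subclones by their
driver-gene mutation combination (k-means), computes a box-counting
dimension for each subclone's occupancy mask, and averages them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.spatial.distance import squareform, pdist
from sklearn.cluster import KMeans

from .genome import GENOME_SIZE, DriverMap, default_driver_map


class EmptyPopulationError(ValueError):
    pass


def genome_matrix(snapshot: pd.DataFrame, include_ctl: bool = False) -> np.ndarray:
    """(m, 50) binary matrix from a snapshot's genome strings (NC + MTC)."""
    cells = snapshot if include_ctl else snapshot[snapshot["type"] != "CTL"]
    strings = cells["genome"].tolist()
    if not strings:
        raise EmptyPopulationError("snapshot contains no melanocytes")
    raw = np.frombuffer("".join(strings).encode(), dtype=np.uint8)
    return (raw - ord("0")).reshape(len(strings), GENOME_SIZE)


def validate_profiles(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M)
    if M.ndim != 2 or M.shape[0] < 1:
        raise EmptyPopulationError("mutation profile matrix must be m x n with m >= 1")
    if not np.isin(M, (0, 1)).all():
        raise ValueError("mutation profile entries must be binary")
    return M.astype(np.float64)


def similarity_matrix(M: np.ndarray) -> np.ndarray:
    """m x m similarity S_ij = 1 - Hamming distance / n."""
    M = validate_profiles(M)
    if M.shape[0] == 1:
        return np.ones((1, 1))
    D = squareform(pdist(M, metric="cityblock")) / M.shape[1]
    return 1.0 - D


def entropy(S: np.ndarray) -> float:
    """Singular-value entropy of a similarity matrix (natural log)."""
    S = np.asarray(S, dtype=np.float64)
    if S.size == 0:
        raise EmptyPopulationError("empty similarity matrix")
    s = np.linalg.svd(S, compute_uv=False)
    return _spectrum_entropy(s)


def _spectrum_entropy(s: np.ndarray) -> float:
    s = np.asarray(s, dtype=np.float64)
    if s.size == 0:
        return 0.0
    s = s[s > s.max() * 1e-12]  # numerical-rank tolerance
    total = s.sum()
    if total <= 0:
        return 0.0
    p = s / total
    p = p[p > 0]
    return max(0.0, float(-(p * np.log(p)).sum()))


def entropy_from_profiles(M: np.ndarray) -> float:
    """Entropy computed by compressing duplicate genomes.

    With U the m x c indicator of the c distinct genomes and K their
    similarity matrix, S = U K U^T shares its nonzero spectrum with
    D^(1/2) K D^(1/2) (D = diag of genome multiplicities), so the entropy
    can be evaluated from a c x c eigenproblem instead of an m x m SVD.
    """
    M = validate_profiles(M)
    uniq, counts = np.unique(M, axis=0, return_counts=True)
    K = similarity_matrix(uniq)
    d = np.sqrt(counts.astype(np.float64))
    core = K * np.outer(d, d)
    eigvals = eigh(core, eigvals_only=True)
    return _spectrum_entropy(np.abs(eigvals))


def mean_mutation_count(M: np.ndarray) -> float:
    """beta: average number of mutated genes per cell."""
    M = validate_profiles(M)
    return float(M.sum() / M.shape[0])


def driver_profiles(M: np.ndarray, driver_map: DriverMap | None = None) -> np.ndarray:
    dm = driver_map or default_driver_map()
    return validate_profiles(M)[:, dm.driver_indices]


def cluster_subclones(
    profiles: np.ndarray,
    k: int | None = None,
    rng: np.random.Generator | None = None,
    min_frac: float = 0.01,
) -> np.ndarray:
    """k-means labels on per-cell binary driver-combination vectors.

    ``k`` defaults to the number of *prevalent* driver combinations --
    those carried by at least ``min_frac`` of the cells -- capped at 8.
    Restricting to prevalent combinations keeps the subclone count stable:
    a driver mutant born a handful of steps before the snapshot is a few
    scattered cells, not a subclone, and k-means simply absorbs such cells
    into the nearest established cluster.  Euclidean k-means on binary
    vectors is equivalent to clustering by Hamming distance.
    """
    P = np.asarray(profiles, dtype=np.float64)
    if P.ndim != 2 or P.shape[0] < 1:
        raise EmptyPopulationError("driver profile matrix must be m x d with m >= 1")
    if k is None:
        _, counts = np.unique(P, axis=0, return_counts=True)
        n_prevalent = int((counts >= max(1, min_frac * P.shape[0])).sum())
        k = min(max(1, n_prevalent), 8)
    if k < 1 or k > P.shape[0]:
        raise ValueError(f"k={k} must lie in [1, m]")
    seed = int(rng.integers(2**31)) if rng is not None else 0
    km = KMeans(n_clusters=k, n_init=4, random_state=seed)
    return km.fit_predict(P)


def box_counting_fd(mask: np.ndarray) -> float:
    """Box-counting fractal dimension of a binary mask.

    Boxes of dyadic side length (2, 4, ..., <= min(bounding box)/2) are
    anchored at the mask's bounding-box origin; the dimension is the
    least-squares slope of log N(l) against log(1/l).  Masks too small to
    supply two box sizes (bounding box under 8 pixels) are assigned
    dimension 0 (point-like sets).
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise EmptyPopulationError("empty mask")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    sub = mask[rows[0]: rows[-1] + 1, cols[0]: cols[-1] + 1]
    long_side = max(sub.shape)
    sizes = []
    size = 2
    while size <= long_side // 2:
        sizes.append(size)
        size *= 2
    if len(sizes) < 2:
        return 0.0
    counts = []
    for l in sizes:
        h = -(-sub.shape[0] // l) * l
        w = -(-sub.shape[1] // l) * l
        padded = np.zeros((h, w), dtype=bool)
        padded[: sub.shape[0], : sub.shape[1]] = sub
        blocks = padded.reshape(h // l, l, w // l, l).any(axis=(1, 3))
        counts.append(int(blocks.sum()))
    slope = np.polyfit(np.log(1.0 / np.asarray(sizes)), np.log(counts), 1)[0]
    return float(slope)


def clustered_fd(
    snapshot: pd.DataFrame,
    k: int | None = None,
    rng: np.random.Generator | None = None,
    driver_map: DriverMap | None = None,
    grid_size: int | None = None,
) -> float:
    """Mean box-counting FD over driver-combination subclone masks (MTCs)."""
    mtc = snapshot[snapshot["type"] == "MTC"]
    if len(mtc) == 0:
        raise EmptyPopulationError("snapshot has no melanoma tumor cells")
    M = genome_matrix(mtc)
    P = driver_profiles(M, driver_map)
    labels = cluster_subclones(P, k=k, rng=rng)
    g = grid_size or int(max(mtc["row"].max(), mtc["col"].max())) + 1
    fds = []
    for lab in np.unique(labels):
        sel = mtc.iloc[np.flatnonzero(labels == lab)]
        mask = np.zeros((g, g), dtype=bool)
        mask[sel["row"].to_numpy(), sel["col"].to_numpy()] = True
        fds.append(box_counting_fd(mask))
    return float(np.mean(fds))


def population_metrics(
    snapshot: pd.DataFrame,
    rng: np.random.Generator | None = None,
    sample_fraction: float = 0.10,
    exact_threshold: int = 5_000,
    k: int | None = None,
    driver_map: DriverMap | None = None,
    grid_size: int | None = None,
) -> dict[str, float]:
    """One metrics report row: m, epsilon, beta, clustered FD.

    For populations larger than ``exact_threshold`` the entropy is
    computed on a space-systematic 10% sample (the estimator is otherwise
    exact); beta is always exact.
    """
    from .sampling import SamplePlan, draw_sample

    melan = snapshot[snapshot["type"] != "CTL"]
    M = genome_matrix(snapshot)
    m = M.shape[0]
    beta = mean_mutation_count(M)
    if m > exact_threshold:
        rng = rng or np.random.default_rng(0)
        idx = draw_sample(melan, SamplePlan(method="SS", fraction=sample_fraction), rng)
        eps = entropy_from_profiles(M[idx])
    else:
        eps = entropy_from_profiles(M)
    out = {"m": float(m), "entropy": eps, "beta": beta}
    try:
        out["clustered_fd"] = clustered_fd(
            snapshot, k=k, rng=rng, driver_map=driver_map, grid_size=grid_size
        )
    except EmptyPopulationError:
        out["clustered_fd"] = float("nan")
    return out
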