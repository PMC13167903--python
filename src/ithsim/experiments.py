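"""Experiment drivers: parameter sweeps, Morris screening, immune contrasts.

Everything here is reproducible from a (config, seed) pair: per-run seeds
are derived deterministically from the base seed and the run's position in
the design, and each run uses an independent generator.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, Delaunay, QhullError
from scipy.spatial import cKDTree

from . import engine, ith, morphology
from .config import ImmuneParams, SimulationConfig
from .genome import HallmarkParams


def derive_seed(base: int, *key: int) -> int:
    """Deterministic per-run seed below 2**31."""
    mask = (1 << 64) - 1
    h = (int(base) * 0x9E3779B97F4A7C15) & mask
    for k in key:
        h ^= (int(k) + 0x9E3779B9 + ((h << 6) & mask) + (h >> 2)) & mask
        h = (h * 0xBF58476D1CE4E5B9) & mask
    return h % (2**31 - 1)


@dataclass(frozen=True)
class SweepSpec:
    r0_values: tuple[float, ...] = (1e-6, 1e-5, 1e-4)
    f_values: tuple[float, ...] = (1.6,)
    replicates: int = 5
    seed_base: int = 0
    base_config: SimulationConfig = field(default_factory=SimulationConfig)


def _with_params(cfg: SimulationConfig, r0: float, f: float, seed: int) -> SimulationConfig:
    hp = dataclasses.replace(cfg.hallmarks, r0=r0, f=f)
    return dataclasses.replace(cfg, hallmarks=hp, seed=seed)


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Run the (r0, f) grid; one row of ITH + morphology metrics per run.

    Individual run failures are recorded (``error`` column) and the sweep
    continues.
    """
    rows = []
    for pi, r0 in enumerate(spec.r0_values):
        for fi, f in enumerate(spec.f_values):
            for rep in range(spec.replicates):
                seed = derive_seed(spec.seed_base, pi, fi, rep)
                cfg = _with_params(spec.base_config, r0, f, seed)
                row: dict = {"r0": r0, "f": f, "replicate": rep, "seed": seed}
                try:
                    trace = engine.run(cfg)
                    snap = trace.final
                    mrng = np.random.default_rng(derive_seed(seed, 7))
                    metrics = ith.population_metrics(
                        snap, rng=mrng, driver_map=cfg.driver_map,
                        grid_size=cfg.grid_size,
                    )
                    mask = morphology.tumor_mask(snap, cfg.grid_size)
                    rep_m = morphology.morphology_report(mask)
                    row.update(metrics)
                    row.update({
                        "C": rep_m.C, "FD_b": rep_m.FD_b,
                        "n_satellites": rep_m.n_satellites,
                        "termination": trace.termination,
                        "n_steps": trace.n_steps,
                    })
                except Exception as exc:  # noqa: BLE001 -- record and continue
                    row["error"] = repr(exc)
                rows.append(row)
    return pd.DataFrame(rows)


def classify_ith_mode(
    eps: float,
    clustered_fd: float,
    eps_clonal: float = 0.1,
    eps_fractal: float = 0.5,
    fd_fractal: float = 1.3,
) -> str:
    """Label a tumor clonal / subclonal / fractal from (epsilon, clustered FD).

    The thresholds are conventions of this toolkit (calibrated on the
    default desk-scale sweep), not published cutoffs; every finite input
    maps to exactly one mode.
    """
    if eps < eps_clonal:
        return "clonal"
    if clustered_fd >= fd_fractal and eps >= eps_fractal:
        return "fractal"
    return "subclonal"


# ---------------------------------------------------------------------------
# Morris one-at-a-time (MOAT) elementary-effects screening


@dataclass(frozen=True)
class MorrisSpec:
    names: tuple[str, ...]
    lows: tuple[float, ...]
    highs: tuple[float, ...]
    trajectories: int = 20
    levels: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trajectories < 4:
            raise ValueError("need at least 4 trajectories")
        if self.levels < 2 or self.levels % 2:
            raise ValueError("levels must be even and >= 2")


def morris_sample(spec: MorrisSpec, rng: np.random.Generator) -> np.ndarray:
    """Trajectory design in the unit hypercube; shape (T, d+1, d).

    Each trajectory starts at a random point on the p-level grid and moves
    one randomly ordered coordinate at a time by delta = p / (2(p-1)),
    with the move direction chosen so the point stays inside [0, 1].
    """
    d = len(spec.names)
    p = spec.levels
    delta = p / (2.0 * (p - 1))
    grid = np.arange(p) / (p - 1)
    trajs = np.empty((spec.trajectories, d + 1, d))
    for t in range(spec.trajectories):
        x = grid[rng.integers(p, size=d)].astype(float)
        order = rng.permutation(d)
        pts = [x.copy()]
        for j in order:
            up_ok = x[j] + delta <= 1.0 + 1e-12
            down_ok = x[j] - delta >= -1e-12
            if up_ok and down_ok:
                step = delta if rng.random() < 0.5 else -delta
            else:
                step = delta if up_ok else -delta
            x = x.copy()
            x[j] = min(1.0, max(0.0, x[j] + step))
            pts.append(x)
        trajs[t] = np.asarray(pts)
    return trajs


def morris_analyze(
    spec: MorrisSpec,
    trajs: np.ndarray,
    ys: np.ndarray,
    n_boot: int = 200,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-parameter mu* (mean |EE|) and sigma (sd of EE) with bootstrap CIs.

    Elementary effects are computed in the unit-cube parameterization;
    trajectories containing non-finite outputs are discarded.
    """
    d = len(spec.names)
    ee = np.full((len(trajs), d), np.nan)
    for t, (pts, y) in enumerate(zip(trajs, ys)):
        if not np.all(np.isfinite(y)):
            continue
        for step in range(d):
            dx = pts[step + 1] - pts[step]
            j = int(np.argmax(np.abs(dx)))
            ee[t, j] = (y[step + 1] - y[step]) / dx[j]
    ok = np.all(np.isfinite(ee), axis=1)
    ee = ee[ok]
    if len(ee) == 0:
        raise ValueError("no complete trajectories")
    mu_star = np.abs(ee).mean(axis=0)
    sigma = ee.std(axis=0, ddof=1) if len(ee) > 1 else np.zeros(d)
    rng = rng or np.random.default_rng(0)
    boots_mu = np.empty((n_boot, d))
    boots_sd = np.empty((n_boot, d))
    for b in range(n_boot):
        pick = rng.integers(len(ee), size=len(ee))
        sub = ee[pick]
        boots_mu[b] = np.abs(sub).mean(axis=0)
        boots_sd[b] = sub.std(axis=0, ddof=1) if len(sub) > 1 else 0.0
    lo_mu, hi_mu = np.percentile(boots_mu, [2.5, 97.5], axis=0)
    lo_sd, hi_sd = np.percentile(boots_sd, [2.5, 97.5], axis=0)
    return pd.DataFrame({
        "parameter": spec.names,
        "mu_star": mu_star, "mu_star_lo": lo_mu, "mu_star_hi": hi_mu,
        "sigma": sigma, "sigma_lo": lo_sd, "sigma_hi": hi_sd,
        "n_trajectories": len(ee),
    })


def morris_moat(spec: MorrisSpec, model, n_boot: int = 200) -> pd.DataFrame:
    """Full MOAT screening of ``model`` (callable on a name->value dict)."""
    rng = np.random.default_rng(spec.seed)
    trajs = morris_sample(spec, rng)
    lows = np.asarray(spec.lows)
    highs = np.asarray(spec.highs)
    ys = np.empty(trajs.shape[:2])
    for t in range(trajs.shape[0]):
        for s in range(trajs.shape[1]):
            x = lows + trajs[t, s] * (highs - lows)
            ys[t, s] = model(dict(zip(spec.names, x)))
    return morris_analyze(spec, trajs, ys, n_boot=n_boot, rng=rng)


def entropy_model(base_config: SimulationConfig, seed: int):
    """Reduced-scale simulation returning entropy, for MOAT screening.

    Varies (f, r0, p_i0, s0); all runs share one seed so elementary
    effects reflect parameter changes rather than replicate noise (common
    random numbers).
    """
    def model(params: dict[str, float]) -> float:
        hp = dataclasses.replace(
            base_config.hallmarks,
            f=params.get("f", base_config.hallmarks.f),
            r0=params.get("r0", base_config.hallmarks.r0),
        )
        im = dataclasses.replace(
            base_config.immune,
            p_i0=params.get("p_i0", base_config.immune.p_i0),
            s0=params.get("s0", base_config.immune.s0),
        )
        cfg = dataclasses.replace(base_config, hallmarks=hp, immune=im, seed=seed)
        trace = engine.run(cfg)
        try:
            M = ith.genome_matrix(trace.final)
        except ith.EmptyPopulationError:
            return float("nan")
        return ith.entropy_from_profiles(M)
    return model


# ---------------------------------------------------------------------------
# hot / cold immune contrast and CTL distance profiles


def ctl_density_in_hull(snapshot: pd.DataFrame) -> float:
    """CTLs per unit area inside the convex hull of the MTC positions."""
    mtc = snapshot[snapshot["type"] == "MTC"][["row", "col"]].to_numpy(float)
    ctl = snapshot[snapshot["type"] == "CTL"][["row", "col"]].to_numpy(float)
    if len(mtc) < 3:
        return float("nan")
    try:
        hull = ConvexHull(mtc)
    except QhullError:
        return float("nan")
    area = float(hull.volume)  # 2D hull: .volume is the area
    if area <= 0:
        return float("nan")
    if len(ctl) == 0:
        return 0.0
    tri = Delaunay(mtc[hull.vertices])
    inside = tri.find_simplex(ctl) >= 0
    return float(inside.sum() / area)


def hot_cold_experiment(
    base_config: SimulationConfig,
    seeds: list[int],
    r0_values: tuple[float, ...] = (1e-6,),
    t_fixed: int = 100,
) -> pd.DataFrame:
    """CTL density and mean MTC antigenicity for cold vs hot BRAF variants.

    The cold variant keeps BRAF's immune-evasion tag (low antigenicity);
    the hot variant removes it.  Each (variant, r0, seed) run stops at the
    fixed step ``t_fixed`` (or earlier on c_max) and the CTL density inside
    the MTC convex hull is recorded.
    """
    variants = {
        "cold": base_config.driver_map,
        "hot": base_config.driver_map.without_tag("BRAF", "c"),
    }
    rows = []
    for r0 in r0_values:
        for name, dm in variants.items():
            for seed in seeds:
                hp = dataclasses.replace(base_config.hallmarks, r0=r0)
                cfg = dataclasses.replace(
                    base_config, hallmarks=hp, driver_map=dm,
                    seed=seed, t_max=t_fixed,
                )
                trace = engine.run(cfg)
                snap = trace.final
                ctl_n = int((snap["type"] == "CTL").sum())
                mtc = snap[snap["type"] == "MTC"]
                rows.append({
                    "variant": name, "r0": r0, "seed": seed,
                    "step": trace.n_steps,
                    "n_mtc": len(mtc), "n_ctl": ctl_n,
                    "ctl_density": ctl_density_in_hull(snap),
                    "mean_mtc_a0": float(mtc["a0"].mean()) if len(mtc) else float("nan"),
                })
    return pd.DataFrame(rows)


def ctl_distance_profile(
    trace: engine.SimulationTrace, bins: np.ndarray
) -> pd.DataFrame:
    """CTL counts by distance to the nearest MTC, normalized by MTC count.

    One row per snapshot; bin columns hold (CTLs whose nearest-MTC
    distance falls in the bin) / (MTC count).  Snapshots with no MTC are
    flagged with NaN.
    """
    edges = np.asarray(bins, dtype=float)
    rows = []
    for t, snap in trace.snapshots:
        mtc = snap[snap["type"] == "MTC"][["row", "col"]].to_numpy(float)
        ctl = snap[snap["type"] == "CTL"][["row", "col"]].to_numpy(float)
        row = {"step": t}
        if len(mtc) == 0:
            for j in range(len(edges) - 1):
                row[f"bin_{j}"] = float("nan")
        else:
            if len(ctl):
                d, _ = cKDTree(mtc).query(ctl)
                hist, _ = np.histogram(d, bins=edges)
            else:
                hist = np.zeros(len(edges) - 1, dtype=int)
            for j, h in enumerate(hist):
                row[f"bin_{j}"] = float(h) / len(mtc)
        rows.append(row)
    return pd.DataFrame(rows)
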