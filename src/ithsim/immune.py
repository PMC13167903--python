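"""Immune subsystem: ISF field, Hill recruitment, and CTL actions.

The immune stimulatory factor (ISF) at a grid point is the sum of the
antigenicities of melanoma cells within a Chebyshev radius of that point
(normal cells contribute nothing).  CTLs are recruited to the tumor
periphery as a Poisson process whose rate is a Hill function of the total
ISF carried by border tumor cells; recruited CTLs then kill adjacent
melanoma cells, proliferate, or climb the ISF gradient, each with a
saturating dependence on the local field.
"""

from __future__ import annotations

from typing import TYPE_CHECKING

import numpy as np
from scipy import ndimage

from .config import ImmuneParams
from .engine_types import MOORE

if TYPE_CHECKING:  # pragma: no cover
    from .engine import Simulation


def boxsum(arr: np.ndarray, radius: int) -> np.ndarray:
    """Sum over the (2*radius+1)^2 Chebyshev window, zero outside the array."""
    size = 2 * radius + 1
    return ndimage.uniform_filter(arr.astype(np.float64), size=size,
                                  mode="constant", cval=0.0) * size * size


def isf_field_from_grid(agrid: np.ndarray, radius: int) -> np.ndarray:
    """ISF F(h): additive antigenicity of cells within Chebyshev ``radius``."""
    return boxsum(agrid, radius)


def isf_field(sim: "Simulation", params: ImmuneParams | None = None) -> np.ndarray:
    """ISF field over the padded simulation grid."""
    params = params or sim.cfg.immune
    return isf_field_from_grid(sim.agrid, params.isf_radius)


def recruitment_rate(F_b: float, params: ImmuneParams) -> float:
    """Hill recruitment s_T = s0 + f_T * F_b^n / (gamma_T + F_b^n)."""
    if F_b < 0:
        raise ValueError("border ISF F_b must be nonnegative")
    hill = F_b ** params.n_T
    return params.s0 + params.f_T * hill / (params.gamma_T + hill)


def border_mtc_mask(sim: "Simulation") -> np.ndarray:
    """Padded-grid mask of MTCs with at least one non-MTC Moore neighbor."""
    g = sim._g
    mtc_grid = np.zeros((g + 2, g + 2), dtype=np.float64)
    ids = np.flatnonzero(sim.alive[: sim.n_cells] & sim.mtc[: sim.n_cells])
    mtc_grid[sim.row[ids], sim.col[ids]] = 1.0
    nbr = np.rint(boxsum(mtc_grid, 1))  # MTC count in 3x3 incl. self
    return (mtc_grid > 0) & (nbr < 9)


def _grow_ctl_arrays(sim: "Simulation") -> None:
    cap = len(sim.ctl_row) * 2
    for name in ("ctl_row", "ctl_col", "ctl_birth", "ctl_alive"):
        arr = getattr(sim, name)
        new = np.zeros(cap, dtype=arr.dtype)
        new[: len(arr)] = arr
        setattr(sim, name, new)


def _add_ctl(sim: "Simulation", r: int, c: int) -> None:
    i = sim.n_ctl_total
    if i >= len(sim.ctl_row):
        _grow_ctl_arrays(sim)
    sim.ctl_row[i], sim.ctl_col[i] = r, c
    sim.ctl_birth[i] = sim.t + 1
    sim.ctl_alive[i] = True
    sim.n_ctl_total += 1
    sim.n_ctl += 1
    sim.ctl_occ[r, c] = i + 1


def _remove_ctl(sim: "Simulation", i: int) -> None:
    sim.ctl_occ[sim.ctl_row[i], sim.ctl_col[i]] = 0
    sim.ctl_alive[i] = False
    sim.n_ctl -= 1


def recruit_ctls(sim: "Simulation", s_T: float) -> int:
    """Poisson(s_T) CTLs placed on empty sites in the periphery band.

    The band consists of sites free in both layers within Chebyshev
    distance 2 of a border MTC; fewer CTLs are placed if the band is full.
    """
    if s_T < 0:
        raise ValueError("recruitment rate must be nonnegative")
    if s_T == 0:
        return 0
    n = int(sim.rng.poisson(s_T))
    if n == 0:
        return 0
    border = border_mtc_mask(sim)
    band = (np.rint(boxsum(border.astype(np.float64), 2)) > 0)
    band &= (sim.occ == 0) & (sim.ctl_occ == 0)
    sites = np.flatnonzero(band.ravel())
    if sites.size == 0:
        return 0
    take = min(n, sites.size)
    chosen = sim.rng.choice(sites, size=take, replace=False)
    w = sim.occ.shape[1]
    for s in chosen:
        _add_ctl(sim, int(s) // w, int(s) % w)
    sim.counters["ctl_recruited"] += take
    return take


def ctl_round(sim: "Simulation", F: np.ndarray) -> None:
    """Shuffled sweep over CTLs: apoptosis, kill, proliferate, chemotaxis.

    kill and proliferation probabilities saturate with the local field:
    k = min(1, k0*F/(sat+F)), p_i = min(1, p_i0*F/(sat+F)).  Movement is
    strictly uphill in F among CTL-free Moore neighbors.
    """
    prm = sim.cfg.immune
    rng = sim.rng
    ids = rng.permutation(np.flatnonzero(sim.ctl_alive[: sim.n_ctl_total]))
    for i in ids:
        i = int(i)
        if not sim.ctl_alive[i]:
            continue
        if rng.random() < prm.q_i:
            _remove_ctl(sim, i)
            sim.counters["ctl_deaths"] += 1
            continue
        r, c = int(sim.ctl_row[i]), int(sim.ctl_col[i])
        Fh = float(F[r, c])
        resp = Fh / (prm.isf_sat + Fh) if Fh > 0 else 0.0
        # kill the highest-antigenicity adjacent MTC
        targets = []
        for dr, dc in MOORE:
            v = sim.occ[r + dr, c + dc]
            if v > 0 and sim.mtc[v - 1]:
                targets.append(v - 1)
        if targets and rng.random() < min(1.0, prm.k0 * resp):
            amax = max(sim.a[j] for j in targets)
            best = [j for j in targets if sim.a[j] == amax]
            victim = best[int(rng.integers(len(best)))] if len(best) > 1 else best[0]
            sim._remove_cell(victim)
            sim.counters["immune_kills"] += 1
            continue
        if rng.random() < min(1.0, prm.p_i0 * resp):
            empties = [
                (r + dr, c + dc) for dr, dc in MOORE
                if sim.ctl_occ[r + dr, c + dc] == 0
            ]
            if empties:
                rr, cc = empties[int(rng.integers(len(empties)))]
                _add_ctl(sim, rr, cc)
                sim.counters["ctl_births"] += 1
                continue
        # chemotaxis strictly up the ISF gradient
        best_F = Fh
        best_sites: list[tuple[int, int]] = []
        for dr, dc in MOORE:
            if sim.ctl_occ[r + dr, c + dc] != 0:
                continue  # occupied by CTL or sentinel border
            fv = float(F[r + dr, c + dc])
            if fv > best_F:
                best_F = fv
                best_sites = [(r + dr, c + dc)]
            elif fv == best_F and best_sites:
                best_sites.append((r + dr, c + dc))
        if best_sites:
            rr, cc = best_sites[int(rng.integers(len(best_sites)))] \
                if len(best_sites) > 1 else best_sites[0]
            sim.ctl_occ[r, c] = 0
            sim.ctl_occ[rr, cc] = i + 1
            sim.ctl_row[i], sim.ctl_col[i] = rr, cc


def immune_round(sim: "Simulation") -> None:
    """Recruitment followed by the CTL action sweep.

    When the immune system cannot act at all (zero recruitment and no live
    CTLs) the round is skipped without consuming random numbers, so a run
    with ``s0 = f_T = 0`` is bitwise-identical to one with the immune
    module disabled.
    """
    prm = sim.cfg.immune
    if sim.n_ctl == 0 and prm.s0 == 0.0 and prm.f_T == 0.0:
        return
    if prm.s0 == 0.0 and prm.f_T == 0.0:
        s_T = 0.0
    else:
        border = border_mtc_mask(sim)
        F_b = float(sim.agrid[border].sum())
        s_T = recruitment_rate(F_b, prm)
    recruit_ctls(sim, s_T)
    if sim.n_ctl:
        F = isf_field(sim)
        ctl_round(sim, F)
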