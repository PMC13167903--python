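"""2D lattice tumor growth engine.

Melanocytes live on a square lattice (one per site).  Each step performs a
random-order sweep over the melanocytes alive at the start of the step; a
cell may die (probability q), otherwise attempt division (probability p)
into a uniformly chosen empty Moore site, and -- in the motility extension
-- a BRAF-mutant cell that neither died nor divided may move with
probability m0, pushing a ray of occupied cells outward when no empty
neighbor exists.  After the melanocyte sweep the immune subsystem runs
(recruitment, CTL actions).  The simulation stops when the melanocyte
population reaches ``c_max`` or the step counter reaches ``t_max``.

Internally the occupancy grids are padded with a one-site sentinel border
(-1) so neighbor lookups never go out of bounds; exported coordinates are
0-based interior coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import immune
from .config import SimulationConfig
from .engine_types import MOORE
from .genome import GENOME_SIZE, founder_genome

SNAPSHOT_COLUMNS = ["cell_id", "type", "row", "col", "birth_step", "a0", "genome"]


@dataclass
class SimulationTrace:
    config: SimulationConfig
    snapshots: list[tuple[int, pd.DataFrame]]
    termination: str
    n_steps: int
    counters: dict[str, int] = field(default_factory=dict)

    @property
    def final(self) -> pd.DataFrame:
        return self.snapshots[-1][1]


class Simulation:
    """Stateful tumor--immune lattice simulation.

    All randomness flows through a single ``numpy`` Generator seeded from
    the config, so equal (config, seed) pairs give identical trajectories.
    """

    def __init__(self, config: SimulationConfig):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        g = config.grid_size
        self._g = g
        # padded occupancy grids: 0 empty, -1 sentinel border, i+1 = cell i
        self.occ = np.zeros((g + 2, g + 2), dtype=np.int64)
        self.occ[0, :] = self.occ[-1, :] = self.occ[:, 0] = self.occ[:, -1] = -1
        self.ctl_occ = self.occ.copy()
        self.nngb = np.zeros((g + 2, g + 2), dtype=np.int64)  # occupied Moore neighbors
        self.agrid = np.zeros((g + 2, g + 2), dtype=np.float64)  # antigenicity field src

        cap = 1024
        self.genomes = np.zeros((cap, GENOME_SIZE), dtype=np.uint8)
        self.row = np.zeros(cap, dtype=np.int64)
        self.col = np.zeros(cap, dtype=np.int64)
        self.a0 = np.zeros(cap)
        self.a = np.zeros(cap)
        self.p = np.zeros(cap)
        self.q = np.zeros(cap)
        self.r = np.zeros(cap)
        self.birth = np.zeros(cap, dtype=np.int64)
        self.alive = np.zeros(cap, dtype=bool)
        self.braf = np.zeros(cap, dtype=bool)
        self.mtc = np.zeros(cap, dtype=bool)
        self.n_cells = 0          # total ever created (array high-water mark)
        self.n_alive = 0
        self.n_mtc = 0

        ccap = 256
        self.ctl_row = np.zeros(ccap, dtype=np.int64)
        self.ctl_col = np.zeros(ccap, dtype=np.int64)
        self.ctl_birth = np.zeros(ccap, dtype=np.int64)
        self.ctl_alive = np.zeros(ccap, dtype=bool)
        self.n_ctl_total = 0
        self.n_ctl = 0

        self.t = 0
        self.counters = {
            "births": 0, "deaths": 0, "immune_kills": 0,
            "ctl_recruited": 0, "ctl_births": 0, "ctl_deaths": 0,
        }

        # cached per-genome lookup tables
        self._tag_matrix = config.driver_map.tag_matrix()
        self._driver_idx = config.driver_map.driver_indices
        self._braf_idx = config.driver_map.index_of("BRAF")
        self._init_cells()

    # -- setup ------------------------------------------------------------

    def _init_cells(self) -> None:
        """9 normal cells plus 1 BRAF-mutant founder MTC at the grid center."""
        c = self._g // 2 + 1  # padded coords
        mtc_genome = founder_genome(self.cfg.driver_map)
        wild = np.zeros(GENOME_SIZE, dtype=np.uint8)
        # 3x3 block of normal cells with the founder MTC on its western edge,
        # so the MTC starts with free Moore sites to expand into
        self._add_cell(mtc_genome, c, c - 1, self._draw_a0(), 0)
        for dr in (-1, 0, 1):
            for dc in (0, 1, 2):
                self._add_cell(wild, c + dr, c + dc, self._draw_a0(), 0)
        self.counters["births"] = 0  # initial placement is not a division

    def _draw_a0(self) -> float:
        lo, hi = self.cfg.hallmarks.a0_range
        return lo + (hi - lo) * self.rng.random()

    # -- cell bookkeeping -------------------------------------------------

    def _grow_arrays(self) -> None:
        cap = len(self.row) * 2
        self.genomes = np.resize(self.genomes, (cap, GENOME_SIZE))
        for name in ("row", "col", "a0", "a", "p", "q", "r", "birth", "alive",
                     "braf", "mtc"):
            arr = getattr(self, name)
            new = np.zeros(cap, dtype=arr.dtype)
            new[: len(arr)] = arr
            setattr(self, name, new)

    def _cell_attributes(self, genome: np.ndarray) -> tuple[float, float, float, float, bool, bool]:
        hp = self.cfg.hallmarks
        d = self._tag_matrix @ genome.astype(np.int64)  # (r, p, q, c, c~)
        f = hp.f
        p = min(1.0, hp.p0 * 10.0 ** (f * d[1]))
        q = hp.q0 * 10.0 ** (-f * d[2])
        r = min(1.0, hp.r0 * 10.0 ** (f * d[0]))
        is_mtc = bool(genome[self._driver_idx].any())
        return p, q, r, float(d[4] - d[3]), is_mtc, bool(genome[self._braf_idx])

    def _antigenicity(self, genome: np.ndarray, a0: float, c_shift: float, is_mtc: bool) -> float:
        if not is_mtc:
            return 0.0
        a = a0 * 10.0 ** (self.cfg.hallmarks.f * c_shift)
        if self.cfg.passenger_antigenicity:
            n_pass = int(genome.sum()) - int(genome[self._driver_idx].sum())
            a += self.cfg.passenger_antigenicity * n_pass
        return a

    def _add_cell(self, genome: np.ndarray, r: int, c: int, a0: float, birth: int) -> int:
        i = self.n_cells
        if i >= len(self.row):
            self._grow_arrays()
        p, q, rr, c_shift, is_mtc, braf = self._cell_attributes(genome)
        a = self._antigenicity(genome, a0, c_shift, is_mtc)
        self.genomes[i] = genome
        self.row[i], self.col[i] = r, c
        self.a0[i], self.a[i] = a0, a
        self.p[i], self.q[i], self.r[i] = p, q, rr
        self.birth[i] = birth
        self.alive[i] = True
        self.braf[i] = braf
        self.mtc[i] = is_mtc
        self.n_cells += 1
        self.n_alive += 1
        self.n_mtc += is_mtc
        self.occ[r, c] = i + 1
        self.agrid[r, c] = a
        for dr, dc in MOORE:
            self.nngb[r + dr, c + dc] += 1
        return i

    def _remove_cell(self, i: int) -> None:
        r, c = self.row[i], self.col[i]
        self.occ[r, c] = 0
        self.agrid[r, c] = 0.0
        for dr, dc in MOORE:
            self.nngb[r + dr, c + dc] -= 1
        self.alive[i] = False
        self.n_alive -= 1
        self.n_mtc -= bool(self.mtc[i])

    def _relocate(self, i: int, r2: int, c2: int) -> None:
        r, c = self.row[i], self.col[i]
        self.occ[r, c] = 0
        self.agrid[r, c] = 0.0
        for dr, dc in MOORE:
            self.nngb[r + dr, c + dc] -= 1
        self.occ[r2, c2] = i + 1
        self.agrid[r2, c2] = self.a[i]
        for dr, dc in MOORE:
            self.nngb[r2 + dr, c2 + dc] += 1
        self.row[i], self.col[i] = r2, c2

    # -- per-step dynamics ------------------------------------------------

    def _mutated_daughter_genome(self, i: int) -> np.ndarray:
        """Daughter genome: copy of parent with one mutation pass at rate r."""
        g = self.genomes[i].copy()
        r = self.r[i]
        if r == 0.0:
            return g
        flips = (self.rng.random(GENOME_SIZE) < r) & (g == 0)
        if flips.any():
            excl = sorted(self.cfg.driver_map.exclusive_group)
            taken = any(g[k] for k in excl)
            for k in excl:
                if taken:
                    flips[k] = False
                elif flips[k]:
                    taken = True
            g[flips] = 1
        return g

    def _try_divide(self, i: int) -> bool:
        r, c = self.row[i], self.col[i]
        if self.nngb[r, c] == 8:
            return False  # no empty Moore site: division fails (surface growth)
        occ = self.occ
        empties = [(r + dr, c + dc) for dr, dc in MOORE if occ[r + dr, c + dc] == 0]
        if not empties:
            return False  # neighbors occupied or sentinel border
        rr, cc = empties[int(self.rng.integers(len(empties)))]
        g = self._mutated_daughter_genome(i)
        self._add_cell(g, rr, cc, self.a0[i], self.t + 1)
        self.counters["births"] += 1
        return True

    def attempt_move(self, i: int) -> bool:
        """Motility action: prefer a uniformly chosen empty Moore site;
        otherwise push in a uniformly chosen direction."""
        r, c = self.row[i], self.col[i]
        occ = self.occ
        if self.nngb[r, c] < 8:
            empties = [(r + dr, c + dc) for dr, dc in MOORE if occ[r + dr, c + dc] == 0]
            if empties:
                rr, cc = empties[int(self.rng.integers(len(empties)))]
                self._relocate(i, rr, cc)
                return True
        return self.move_with_push(i, MOORE[int(self.rng.integers(8))])

    def move_with_push(self, i: int, direction: tuple[int, int]) -> bool:
        """Move cell ``i`` one site along ``direction``, pushing occupants.

        If the target site is empty the cell simply moves.  Otherwise every
        contiguous occupied cell along the ray shifts one site outward and
        the mover takes the vacated target; the move is aborted if the ray
        reaches the grid boundary before an empty site.
        """
        r, c = self.row[i], self.col[i]
        occ = self.occ
        dr, dc = direction
        k = 1
        while True:
            v = occ[r + k * dr, c + k * dc]
            if v == -1:
                return False  # push ray hit the boundary: abort
            if v == 0:
                break
            k += 1
        for j in range(k - 1, 0, -1):  # shift the chain outward, far end first
            cell = int(occ[r + j * dr, c + j * dc]) - 1
            self._relocate(cell, r + (j + 1) * dr, c + (j + 1) * dc)
        self._relocate(i, r + dr, c + dc)
        return True

    def step(self) -> None:
        """One synchronous round: melanocyte sweep then immune round."""
        rng = self.rng
        m0 = self.cfg.m0
        ids = np.flatnonzero(self.alive[: self.n_cells])
        order = rng.permutation(ids)
        q, p, alive, braf = self.q, self.p, self.alive, self.braf
        for i in order:
            i = int(i)
            if not alive[i]:
                continue  # died earlier in this sweep
            if rng.random() < q[i]:
                self._remove_cell(i)
                self.counters["deaths"] += 1
                continue
            divided = False
            if rng.random() < p[i]:
                divided = self._try_divide(i)
            if not divided and m0 > 0.0 and braf[i] and rng.random() < m0:
                self.attempt_move(i)
        if self.cfg.immune.enabled:
            immune.immune_round(self)
        self.t += 1

    # -- termination and snapshots ---------------------------------------

    @property
    def population(self) -> int:
        return self.n_mtc if self.cfg.count_mtc_only else self.n_alive

    def termination_reason(self) -> str | None:
        if self.population >= self.cfg.c_max:
            return "c_max"
        if self.t >= self.cfg.t_max:
            return "t_max"
        if self.n_alive == 0:
            return "extinct"
        return None

    def snapshot(self) -> pd.DataFrame:
        """Cell table: melanocytes (NC/MTC) and CTLs, 0-based coordinates."""
        ids = np.flatnonzero(self.alive[: self.n_cells])
        genome_str = [
            "".join("1" if b else "0" for b in self.genomes[i]) for i in ids
        ]
        df_m = pd.DataFrame({
            "cell_id": ids,
            "type": np.where(self.mtc[ids], "MTC", "NC"),
            "row": self.row[ids] - 1,
            "col": self.col[ids] - 1,
            "birth_step": self.birth[ids],
            "a0": self.a0[ids],
            "genome": genome_str,
        })
        cids = np.flatnonzero(self.ctl_alive[: self.n_ctl_total])
        df_c = pd.DataFrame({
            "cell_id": cids + 1_000_000,
            "type": "CTL",
            "row": self.ctl_row[cids] - 1,
            "col": self.ctl_col[cids] - 1,
            "birth_step": self.ctl_birth[cids],
            "a0": 0.0,
            "genome": "",
        })
        df = pd.concat([df_m, df_c], ignore_index=True) if len(df_c) else df_m
        return df[SNAPSHOT_COLUMNS]

    def mtc_mask(self) -> np.ndarray:
        """Binary grid (grid_size x grid_size) of MTC-occupied sites."""
        mask = np.zeros((self._g, self._g), dtype=bool)
        ids = np.flatnonzero(self.alive[: self.n_cells] & self.mtc[: self.n_cells])
        mask[self.row[ids] - 1, self.col[ids] - 1] = True
        return mask


def run(config: SimulationConfig) -> SimulationTrace:
    """Run a simulation to termination, recording snapshots.

    Snapshots are taken at step 0, every ``snapshot_every`` steps (if
    positive), and at termination.
    """
    sim = Simulation(config)
    stride = config.snapshot_every
    snapshots: list[tuple[int, pd.DataFrame]] = []
    reason = sim.termination_reason()
    if stride > 0 or reason is not None:
        snapshots.append((0, sim.snapshot()))
    while reason is None:
        sim.step()
        reason = sim.termination_reason()
        if stride > 0 and reason is None and sim.t % stride == 0:
            snapshots.append((sim.t, sim.snapshot()))
    if not snapshots or snapshots[-1][0] != sim.t:
        snapshots.append((sim.t, sim.snapshot()))
    return SimulationTrace(
        config=config,
        snapshots=snapshots,
        termination=reason,
        n_steps=sim.t,
        counters=dict(sim.counters),
    )
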