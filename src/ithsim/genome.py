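"""Genomes, driver-gene hallmark maps, and per-cell action probabilities.

Each melanocyte carries a binary genome of ``GENOME_SIZE`` genes (0 wild,
1 mutated).  Seven loci are melanoma driver genes; each driver is tagged
with one or more cancer hallmarks:

* ``p`` -- increased proliferation
* ``q`` -- increased survival (reduced apoptosis)
* ``r`` -- genetic instability (increased mutation rate)
* ``c`` -- decreased antigenicity (immune evasion)
* ``c~`` -- increased antigenicity

The number of mutated drivers per hallmark, scaled by the driver-gene
strength ``f``, sets each cell's per-step action probabilities

    p = p0 * 10 ** (f * d_p)        (clipped to 1)
    q = q0 * 10 ** (-f * d_q)
    r = r0 * 10 ** (f * d_r)        (clipped to 1)

and its antigenicity

    a = a0 * 10 ** (f * (d_c~ - d_c))

A melanocyte is a melanoma tumor cell (MTC) as soon as any driver locus is
mutated; otherwise it is a normal cell (NC) with antigenicity 0 for the
purposes of the immune stimulatory field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GENOME_SIZE = 50

HALLMARKS = ("r", "p", "q", "c", "c~")


class GenomeError(ValueError):
    """Raised for structurally invalid genomes or driver maps."""


@dataclass(frozen=True)
class DriverGene:
    index: int
    name: str
    tags: frozenset[str]


@dataclass(frozen=True)
class DriverMap:
    """Driver loci, their hallmark tags, and the mutually exclusive group.

    BRAF, NRAS and KIT are foundational melanoma mutations that rarely
    co-occur in one cell; the exclusivity group enforces that at most one
    of them is ever mutated in a genome.
    """

    drivers: tuple[DriverGene, ...]
    exclusive_group: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(self.drivers) != 7:
            raise GenomeError(f"expected 7 driver genes, got {len(self.drivers)}")
        idx = [d.index for d in self.drivers]
        if len(set(idx)) != len(idx):
            raise GenomeError("driver indices must be unique")
        if any(i < 0 or i >= GENOME_SIZE for i in idx):
            raise GenomeError("driver indices must lie in [0, 50)")
        for d in self.drivers:
            bad = set(d.tags) - set(HALLMARKS)
            if bad:
                raise GenomeError(f"unknown hallmark tags {bad} on {d.name}")
        if not self.exclusive_group <= set(idx):
            raise GenomeError("exclusivity group must be a subset of driver loci")

    @property
    def driver_indices(self) -> np.ndarray:
        return np.array([d.index for d in self.drivers], dtype=np.intp)

    def index_of(self, name: str) -> int:
        for d in self.drivers:
            if d.name == name:
                return d.index
        raise KeyError(name)

    def tag_matrix(self) -> np.ndarray:
        """(5, 50) 0/1 matrix; row h marks loci tagged with HALLMARKS[h]."""
        m = np.zeros((len(HALLMARKS), GENOME_SIZE), dtype=np.int64)
        for d in self.drivers:
            for t in d.tags:
                m[HALLMARKS.index(t), d.index] = 1
        return m

    def without_tag(self, gene: str, tag: str) -> "DriverMap":
        """Copy of the map with ``tag`` removed from ``gene``.

        Removing the immune-evasion tag ``c`` from BRAF turns the default
        cold tumor variant into the hot (immune-infiltrated) variant.
        """
        new = []
        for d in self.drivers:
            if d.name == gene:
                new.append(DriverGene(d.index, d.name, d.tags - {tag}))
            else:
                new.append(d)
        return DriverMap(tuple(new), self.exclusive_group)


def default_driver_map() -> DriverMap:
    """Seven melanoma driver genes with hallmark assignments.

    BRAF activation promotes proliferation, survival and immune evasion;
    NRAS and KIT drive proliferation; TERT and MITF support survival;
    CDKN2A loss releases the cell cycle; PTEN loss aids survival and is
    associated with genomic instability.  The assignments are editable via
    the YAML driver-map config so alternative annotations can be dropped in.
    """
    genes = (
        DriverGene(0, "BRAF", frozenset({"p", "q", "c"})),
        DriverGene(1, "NRAS", frozenset({"p"})),
        DriverGene(2, "KIT", frozenset({"p"})),
        DriverGene(3, "TERT", frozenset({"q"})),
        DriverGene(4, "CDKN2A", frozenset({"p"})),
        DriverGene(5, "MITF", frozenset({"q"})),
        DriverGene(6, "PTEN", frozenset({"q", "r"})),
    )
    return DriverMap(genes, frozenset({0, 1, 2}))


@dataclass(frozen=True)
class HallmarkParams:
    """Base action probabilities and the driver-gene strength ``f``.

    ``p0``/``q0`` are per-step proliferation/apoptosis probabilities of an
    unmutated melanocyte; ``r0`` is the per-gene mutation probability per
    division; ``f`` scales the decade shift each mutated driver applies to
    its hallmark; ``a0_range`` is the interval base antigenicities are
    drawn from at cell creation.
    """

    p0: float = 0.01
    q0: float = 0.002
    r0: float = 1e-5
    f: float = 1.6
    a0_range: tuple[float, float] = (1.0, 2.0)

    def __post_init__(self) -> None:
        for name in ("p0", "q0", "r0"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.f < 0:
            raise ValueError("f must be nonnegative")
        lo, hi = self.a0_range
        if not (1.0 <= lo <= hi <= 2.0):
            raise ValueError("a0_range must be within [1, 2]")


def validate_genome(genome: np.ndarray, driver_map: DriverMap | None = None) -> np.ndarray:
    g = np.asarray(genome)
    if g.shape != (GENOME_SIZE,):
        raise GenomeError(f"genome must have length {GENOME_SIZE}, got shape {g.shape}")
    if not np.isin(g, (0, 1)).all():
        raise GenomeError("genome entries must be 0 or 1")
    if driver_map is not None and driver_map.exclusive_group:
        excl = np.fromiter(driver_map.exclusive_group, dtype=np.intp)
        if int(g[excl].sum()) > 1:
            raise GenomeError("more than one mutually exclusive driver mutated")
    return g.astype(np.uint8)


def count_hallmark_drivers(genome: np.ndarray, driver_map: DriverMap) -> dict[str, int]:
    """Per-hallmark counts of mutated driver loci (d_r, d_p, d_q, d_c, d_c~).

    A driver tagged with several hallmarks contributes to each of them.
    """
    g = validate_genome(genome)
    counts = driver_map.tag_matrix() @ g.astype(np.int64)
    return dict(zip(HALLMARKS, (int(v) for v in counts)))


def action_probabilities(
    counts: dict[str, int], params: HallmarkParams
) -> tuple[float, float, float]:
    """(p, q, r) for a cell with the given hallmark driver counts.

    p and r are clipped to 1 after the decade scaling, which can exceed 1
    for f >~ 1.4 with two or more drivers; clipping keeps probabilities
    valid and preserves monotonicity in the counts.
    """
    for k in ("p", "q", "r"):
        if counts.get(k, 0) < 0:
            raise ValueError("hallmark counts must be nonnegative")
    f = params.f
    p = min(1.0, params.p0 * 10.0 ** (f * counts.get("p", 0)))
    q = params.q0 * 10.0 ** (-f * counts.get("q", 0))
    r = min(1.0, params.r0 * 10.0 ** (f * counts.get("r", 0)))
    return p, q, r


def antigenicity(a0: float, counts: dict[str, int], f: float) -> float:
    """a = a0 * 10 ** (f * (d_c~ - d_c)); zero for cells with no driver.

    Callers are expected to pass the antigenicity of normal cells as 0 to
    the immune field; this function computes the melanoma-cell value.
    """
    return a0 * 10.0 ** (f * (counts.get("c~", 0) - counts.get("c", 0)))


def is_mtc(genome: np.ndarray, driver_map: DriverMap) -> bool:
    """True iff at least one driver locus is mutated."""
    g = validate_genome(genome)
    return bool(g[driver_map.driver_indices].any())


def mutate_genome(
    genome: np.ndarray,
    r: float,
    rng: np.random.Generator,
    driver_map: DriverMap,
) -> np.ndarray:
    """One mutation pass: each wild gene flips 0->1 independently w.p. ``r``.

    Mutated genes never revert.  Within the mutually exclusive group
    (BRAF/NRAS/KIT) at most one gene may ever be mutated: if one is already
    mutated the others cannot flip, and if several are hit in the same pass
    the conflict is resolved in fixed index order (lowest index wins).
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError("mutation probability must lie in [0, 1]")
    g = np.array(genome, dtype=np.uint8, copy=True)
    if r == 0.0:
        return g
    flips = (rng.random(GENOME_SIZE) < r) & (g == 0)
    if driver_map.exclusive_group:
        excl = sorted(driver_map.exclusive_group)
        taken = any(g[i] for i in excl)
        for i in excl:
            if taken:
                flips[i] = False
            elif flips[i]:
                taken = True  # first hit in index order wins
    g[flips] = 1
    return g


def founder_genome(driver_map: DriverMap, founder: str = "BRAF") -> np.ndarray:
    """Genome with only the founder driver mutated (default BRAF)."""
    g = np.zeros(GENOME_SIZE, dtype=np.uint8)
    g[driver_map.index_of(founder)] = 1
    return g
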