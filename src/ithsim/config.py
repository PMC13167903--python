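"""Simulation configuration: dataclasses plus YAML load/save.

The driver map and all numeric parameters are read from plain-text YAML so
alternative hallmark annotations or parameter tables can be dropped in
without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import yaml

from .genome import DriverGene, DriverMap, HallmarkParams, default_driver_map


@dataclass(frozen=True)
class ImmuneParams:
    """Cytotoxic T lymphocyte (CTL) subsystem parameters.

    Recruitment follows a Hill function of the total immune stimulatory
    factor (ISF) carried by border tumor cells,

        s_T = s0 + f_T * F_b**n_T / (gamma_T + F_b**n_T),

    and CTLs are recruited as a Poisson process with mean ``s_T`` per step.
    CTL proliferation and killing depend on the local ISF F(h) through a
    saturating response F/(isf_sat + F); apoptosis is constant at ``q_i``.
    ``isf_radius`` is the Chebyshev radius within which a melanoma cell's
    antigenicity contributes to the field.
    """

    enabled: bool = True
    s0: float = 0.5
    f_T: float = 5.0
    n_T: float = 2.0
    gamma_T: float = 3.0e4
    p_i0: float = 0.2
    k0: float = 0.5
    q_i: float = 0.05
    isf_radius: int = 5
    isf_sat: float = 10.0

    def __post_init__(self) -> None:
        for name in ("p_i0", "k0", "q_i"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.s0 < 0 or self.f_T < 0:
            raise ValueError("recruitment rates must be nonnegative")
        if self.n_T < 1:
            raise ValueError("Hill exponent n_T must be >= 1")
        if self.gamma_T <= 0:
            raise ValueError("gamma_T must be positive")
        if self.isf_radius < 1:
            raise ValueError("isf_radius must be >= 1")


@dataclass(frozen=True)
class SimulationConfig:
    hallmarks: HallmarkParams = field(default_factory=HallmarkParams)
    immune: ImmuneParams = field(default_factory=ImmuneParams)
    driver_map: DriverMap = field(default_factory=default_driver_map)
    m0: float = 0.0              # BRAF-mutant motility probability per step
    grid_size: int = 300
    c_max: int = 10_000
    t_max: int = 2_000
    count_mtc_only: bool = False  # if True, c_max counts MTCs, not all melanocytes
    passenger_antigenicity: float = 0.0  # additive a increment per passenger mutation
    snapshot_every: int = 0      # 0 -> final snapshot only
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.m0 <= 1.0:
            raise ValueError("m0 must lie in [0, 1]")
        if self.c_max <= 0 or self.t_max < 0:
            raise ValueError("c_max must be positive and t_max nonnegative")
        if self.grid_size < 4:
            raise ValueError("grid too small for the initial 10-cell cluster")


# ---------------------------------------------------------------------------
# YAML serialization


def driver_map_to_dict(dm: DriverMap) -> dict:
    return {
        "drivers": [
            {"index": d.index, "name": d.name, "tags": sorted(d.tags)}
            for d in dm.drivers
        ],
        "exclusive_group": sorted(dm.exclusive_group),
    }


def driver_map_from_dict(d: dict) -> DriverMap:
    drivers = tuple(
        DriverGene(int(e["index"]), str(e["name"]), frozenset(e.get("tags", [])))
        for e in d["drivers"]
    )
    return DriverMap(drivers, frozenset(int(i) for i in d.get("exclusive_group", [])))


def config_to_dict(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    d["hallmarks"]["a0_range"] = list(cfg.hallmarks.a0_range)
    d["driver_map"] = driver_map_to_dict(cfg.driver_map)
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    hp = dict(d.pop("hallmarks", {}))
    if "a0_range" in hp:
        hp["a0_range"] = tuple(hp["a0_range"])
    im = dict(d.pop("immune", {}))
    dm = d.pop("driver_map", None)
    return SimulationConfig(
        hallmarks=HallmarkParams(**hp),
        immune=ImmuneParams(**im),
        driver_map=driver_map_from_dict(dm) if dm else default_driver_map(),
        **d,
    )


def load_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def save_config(cfg: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)


def load_default_driver_map() -> DriverMap:
    """Driver map shipped with the package (data/driver_map.yaml)."""
    text = resources.files("ithsim.data").joinpath("driver_map.yaml").read_text()
    return driver_map_from_dict(yaml.safe_load(text))
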