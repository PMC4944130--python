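"""The 2-D lattice: occupancy, bone-matrix mask, and placement primitives.

The canonical state is a set of per-site numpy arrays on a ``(nx, ny)`` grid
(``y = 0`` is the bottom edge; the mineralized bone slab sits there, marrow
above).  :class:`CellAgent` is a lightweight record view of one occupied
site; the id -> position registry is kept consistent with the per-site maps
by :func:`place_agent` / :func:`remove_agent` / :func:`move_agent`, which are
the only mutation paths.

Neighborhoods: Moore (8-connected) for movement and daughter placement,
von Neumann (4-connected) for bone-surface adjacency.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .fields import FieldSet, make_fields
from .params import ParamSet

__all__ = [
    "Phenotype", "CellAgent", "GridState", "make_initial_bmu", "neighbors",
    "place_agent", "remove_agent", "move_agent", "CANCER_PHENOTYPES",
    "bone_adjacent_mask", "audit",
]


class Phenotype(enum.IntEnum):
    MSC = 1   # mesenchymal stromal cell
    POB = 2   # precursor osteoblast
    AOB = 3   # adult (bone-forming) osteoblast
    POC = 4   # precursor osteoclast
    AOC = 5   # adult multinucleated osteoclast
    TRP = 6   # cancer: TGFβ ligand + receptor producing
    TR = 7    # cancer: receptor only
    TP = 8    # cancer: ligand only
    TN = 9    # cancer: neither


CANCER_PHENOTYPES = (Phenotype.TRP, Phenotype.TR, Phenotype.TP, Phenotype.TN)
EMPTY = 0

_MOORE = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_VON_NEUMANN = [(-1, 0), (1, 0), (0, -1), (0, 1)]


@dataclass
class CellAgent:
    """One lattice-resident cell."""

    id: int
    phenotype: Phenotype
    position: tuple[int, int]
    age_hours: float = 0.0
    starvation_hours: float = 0.0   # advances only for cancer phenotypes
    nuclei: int = 1                 # > 1 only for aOC
    alive: bool = True

    def __post_init__(self) -> None:
        if self.nuclei > 1 and self.phenotype is not Phenotype.AOC:
            raise ValueError("nuclei > 1 is only valid for aOC agents")
        if self.starvation_hours < 0:
            raise ValueError("starvation_hours must be >= 0")


@dataclass
class GridState:
    """Lattice occupancy, bone mask, fields and the agent registry."""

    params: ParamSet
    bone: np.ndarray                 # bool (nx, ny)
    phen: np.ndarray                 # int8, 0 = empty
    agent_id: np.ndarray             # int32, -1 = empty
    age_h: np.ndarray                # float32
    starv_h: np.ndarray              # float32
    nuclei: np.ndarray               # int16
    clock_h: np.ndarray              # float32 action clock (resorb/deposit)
    idle_h: np.ndarray               # float32 aOC time without bone contact
    fields: FieldSet
    day: float = 0.0
    next_id: int = 0
    registry: dict[int, tuple[int, int]] = field(default_factory=dict)

    @property
    def nx(self) -> int:
        return self.bone.shape[0]

    @property
    def ny(self) -> int:
        return self.bone.shape[1]

    @property
    def bone_area_um2(self) -> float:
        return float(self.bone.sum()) * self.params.site_area_um2

    # -- queries -----------------------------------------------------------
    def agent_at(self, pos: tuple[int, int]) -> CellAgent | None:
        x, y = pos
        if self.phen[x, y] == EMPTY:
            return None
        return CellAgent(
            id=int(self.agent_id[x, y]),
            phenotype=Phenotype(int(self.phen[x, y])),
            position=(x, y),
            age_hours=float(self.age_h[x, y]),
            starvation_hours=float(self.starv_h[x, y]),
            nuclei=int(self.nuclei[x, y]),
        )

    def agents(self) -> list[CellAgent]:
        out = []
        for x, y in np.argwhere(self.phen != EMPTY):
            out.append(self.agent_at((int(x), int(y))))
        return out

    def positions_of(self, phenotype: Phenotype) -> np.ndarray:
        """``(n, 2)`` integer array of sites holding the given phenotype."""
        return np.argwhere(self.phen == int(phenotype))

    def count(self, phenotype: Phenotype) -> int:
        return int((self.phen == int(phenotype)).sum())

    def cancer_mask(self) -> np.ndarray:
        return self.phen >= int(Phenotype.TRP)

    def empty_marrow_mask(self) -> np.ndarray:
        return (self.phen == EMPTY) & ~self.bone


def neighbors(grid: GridState, position: tuple[int, int],
              connectivity: str = "moore") -> list[tuple[int, int]]:
    """Neighbor coordinates, clipped at the closed boundary."""
    x, y = position
    if not (0 <= x < grid.nx and 0 <= y < grid.ny):
        raise IndexError(f"position {position} out of bounds")
    offs = _MOORE if connectivity == "moore" else _VON_NEUMANN
    return [(x + dx, y + dy) for dx, dy in offs
            if 0 <= x + dx < grid.nx and 0 <= y + dy < grid.ny]


def place_agent(grid: GridState, agent: CellAgent) -> int:
    """Place an agent; returns its id (assigned if ``agent.id < 0``)."""
    x, y = agent.position
    if not (0 <= x < grid.nx and 0 <= y < grid.ny):
        raise IndexError(f"position {agent.position} out of bounds")
    if grid.bone[x, y]:
        raise ValueError(f"cannot place agent on bone site {agent.position}")
    if grid.phen[x, y] != EMPTY:
        raise ValueError(f"site {agent.position} already occupied")
    aid = agent.id if agent.id >= 0 else grid.next_id
    grid.next_id = max(grid.next_id, aid + 1)
    grid.phen[x, y] = int(agent.phenotype)
    grid.agent_id[x, y] = aid
    grid.age_h[x, y] = agent.age_hours
    grid.starv_h[x, y] = agent.starvation_hours
    grid.nuclei[x, y] = agent.nuclei
    grid.clock_h[x, y] = 0.0
    grid.idle_h[x, y] = 0.0
    grid.registry[aid] = (x, y)
    return aid


def remove_agent(grid: GridState, agent_id: int) -> None:
    if agent_id not in grid.registry:
        raise KeyError(f"unknown agent id {agent_id}")
    x, y = grid.registry.pop(agent_id)
    grid.phen[x, y] = EMPTY
    grid.agent_id[x, y] = -1
    grid.age_h[x, y] = 0.0
    grid.starv_h[x, y] = 0.0
    grid.nuclei[x, y] = 0
    grid.clock_h[x, y] = 0.0
    grid.idle_h[x, y] = 0.0


def move_agent(grid: GridState, agent_id: int,
               to: tuple[int, int]) -> None:
    """Move an agent to an empty non-bone site, preserving its state."""
    x0, y0 = grid.registry[agent_id]
    x1, y1 = to
    if grid.bone[x1, y1] or grid.phen[x1, y1] != EMPTY:
        raise ValueError(f"target site {to} not free")
    for arr in (grid.phen, grid.agent_id, grid.age_h, grid.starv_h,
                grid.nuclei, grid.clock_h, grid.idle_h):
        arr[x1, y1] = arr[x0, y0]
    grid.phen[x0, y0] = EMPTY
    grid.agent_id[x0, y0] = -1
    grid.age_h[x0, y0] = 0.0
    grid.starv_h[x0, y0] = 0.0
    grid.nuclei[x0, y0] = 0
    grid.clock_h[x0, y0] = 0.0
    grid.idle_h[x0, y0] = 0.0
    grid.registry[agent_id] = (x1, y1)


def bone_adjacent_mask(bone: np.ndarray) -> np.ndarray:
    """Sites with at least one von Neumann bone neighbor (not bone itself)."""
    adj = np.zeros_like(bone)
    adj[:-1, :] |= bone[1:, :]
    adj[1:, :] |= bone[:-1, :]
    adj[:, :-1] |= bone[:, 1:]
    adj[:, 1:] |= bone[:, :-1]
    return adj & ~bone


def make_initial_bmu(params: ParamSet, rng: np.random.Generator) -> GridState:
    """Build the homeostatic BMU: bone slab, MSC and precursor pools.

    The bone slab fills ``bone_fraction`` of the grid height along the bottom
    edge (the trabecular surface). MSCs scatter through the marrow; initial
    pOB and pOC pools sit within 10 sites of the surface so remodeling can
    start without a long recruitment transient. No cancer cells are placed;
    tumors are seeded separately.
    """
    nx, ny = params.nx, params.ny
    n_bone_rows = int(round(params.bone_fraction * ny))
    bone = np.zeros((nx, ny), dtype=bool)
    bone[:, :n_bone_rows] = True

    grid = GridState(
        params=params,
        bone=bone,
        phen=np.zeros((nx, ny), dtype=np.int8),
        agent_id=np.full((nx, ny), -1, dtype=np.int32),
        age_h=np.zeros((nx, ny), dtype=np.float32),
        starv_h=np.zeros((nx, ny), dtype=np.float32),
        nuclei=np.zeros((nx, ny), dtype=np.int16),
        clock_h=np.zeros((nx, ny), dtype=np.float32),
        idle_h=np.zeros((nx, ny), dtype=np.float32),
        fields=make_fields((nx, ny), params),
    )

    def scatter(phen: Phenotype, n: int, y_lo: int, y_hi: int) -> None:
        free = np.argwhere(grid.empty_marrow_mask()[:, y_lo:y_hi])
        if len(free) < n:
            raise ValueError(
                f"grid too small to hold {n} initial {phen.name} cells")
        pick = rng.choice(len(free), size=n, replace=False)
        for x, y in free[pick]:
            place_agent(grid, CellAgent(
                id=-1, phenotype=phen, position=(int(x), int(y) + y_lo)))

    band = min(10, ny - n_bone_rows)
    scatter(Phenotype.MSC, params.msc_count, n_bone_rows, ny)
    scatter(Phenotype.POB, params.init_pob, n_bone_rows, n_bone_rows + band)
    scatter(Phenotype.POC, params.init_poc, n_bone_rows, n_bone_rows + band)
    return grid


def audit(grid: GridState) -> None:
    """Consistency check of registry vs per-site maps (test mode)."""
    occ = np.argwhere(grid.phen != EMPTY)
    assert len(occ) == len(grid.registry), "registry size mismatch"
    for x, y in occ:
        aid = int(grid.agent_id[x, y])
        assert grid.registry.get(aid) == (int(x), int(y)), (
            f"registry inconsistent at {(x, y)}")
        assert not grid.bone[x, y], f"agent standing on bone at {(x, y)}"
    assert (grid.nuclei[(grid.phen > 0) & (grid.phen != int(Phenotype.AOC))]
            <= 1).all(), "nuclei > 1 outside aOC"
    assert (grid.starv_h[(grid.phen > 0)
                         & (grid.phen < int(Phenotype.TRP))] == 0).all(), (
        "starvation clock advanced for a non-cancer agent")
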