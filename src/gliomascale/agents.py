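"""Tumour-cell agents on the lattice: seeding, chemotaxis, proliferation.

Each agent occupies one grid site (volume exclusion: at most one cell per
site).  Migration and proliferation are chemotactic -- a cell moves, or
places its daughter, on the empty Moore neighbour with the highest glucose,
ties broken uniformly at random.  Proliferation is slower than migration:
a proliferating cell divides only when its division clock (reset to
``T_DIV`` steps after every division) reaches zero.  The model has no cell
death, so the population is non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np

from .microenv import GlucoseField
from .network import Phenotype

#: Division delay in macro steps.  With one macro step per hour and one site
#: (15 um) of migration per step (~15 um/h, glioma-typical), a 24-step delay
#: gives the day-scale cell cycle that makes proliferation the slow mode.
T_DIV = 24

#: Moore neighbourhood offsets in fixed clockwise order starting north.
_MOORE = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))


@dataclass
class Agent:
    """One tumour cell: lattice position, phenotype, molecular state, clock."""

    pos: tuple
    phenotype: Phenotype = Phenotype.QUIESCENT
    mol: np.ndarray = None
    division_clock: int = T_DIV


@dataclass
class WorldState:
    """Lattice occupancy, the agents on it, the glucose field and the clock."""

    agents: list
    occupancy: np.ndarray
    glucose: GlucoseField
    step: int = 0

    def check_consistent(self) -> None:
        occ = np.zeros_like(self.occupancy, dtype=int)
        for a in self.agents:
            occ[a.pos] += 1
        if occ.max(initial=0) > 1:
            raise RuntimeError("volume exclusion violated: site hosts two agents")
        if not np.array_equal(occ.astype(bool), self.occupancy):
            raise RuntimeError("occupancy mask inconsistent with agent positions")

    def counts(self) -> dict:
        c = {p: 0 for p in Phenotype}
        for a in self.agents:
            c[a.phenotype] += 1
        return c


def seed_positions(n_side: int, radius: int) -> list:
    """Sites of the closed lattice disc of ``radius`` centred on the grid.

    Every site whose integer offset (i, j) from the central site satisfies
    i^2 + j^2 <= radius^2 receives one cell; radius 16 on a 200-lattice
    yields the 797-cell circular seed.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if 2 * radius >= n_side:
        raise ValueError(f"radius {radius} too large for an n_side={n_side} lattice")
    ci = cj = n_side // 2
    r2 = radius * radius
    out = []
    for di in range(-radius, radius + 1):
        for dj in range(-radius, radius + 1):
            if di * di + dj * dj <= r2:
                out.append((ci + di, cj + dj))
    return out


def seed_tumour(n_side: int, radius: int) -> tuple:
    """Circular tumour seed: (agents, occupancy mask)."""
    positions = seed_positions(n_side, radius)
    occupancy = np.zeros((n_side, n_side), dtype=bool)
    agents = []
    for pos in positions:
        occupancy[pos] = True
        agents.append(Agent(pos=pos))
    return agents, occupancy


def neighbor_sites(pos: tuple, n_side: int) -> list:
    """Moore 8-neighbourhood clipped at the lattice edges, clockwise from
    north (deterministic order so tie-breaking is the only randomness)."""
    i, j = pos
    if not (0 <= i < n_side and 0 <= j < n_side):
        raise ValueError(f"position {pos} outside the {n_side}x{n_side} lattice")
    out = []
    for di, dj in _MOORE:
        ni, nj = i + di, j + dj
        if 0 <= ni < n_side and 0 <= nj < n_side:
            out.append((ni, nj))
    return out


def _best_empty_neighbor(pos, world: WorldState, rng: np.random.Generator):
    """Empty neighbour with maximal glucose; ties uniform via rng; None if
    the cell is fully enclosed."""
    n_side = world.occupancy.shape[0]
    empties = [s for s in neighbor_sites(pos, n_side) if not world.occupancy[s]]
    if not empties:
        return None
    levels = np.array([world.glucose.values[s] for s in empties])
    best = np.flatnonzero(levels == levels.max())
    pick = best[0] if len(best) == 1 else rng.choice(best)
    return empties[int(pick)]


def act(agent: Agent, world: WorldState, rng: np.random.Generator) -> None:
    """Realize one agent's phenotype on the grid (in place).

    MIGRATING: move up the local glucose gradient (stay when enclosed).
    PROLIFERATING: when the division clock has run out and an empty
    neighbour exists, place a daughter (copy of the molecular state, fresh
    clock) there and reset the clock; otherwise just count the clock down.
    QUIESCENT: no action.
    """
    if not world.occupancy[agent.pos]:
        raise RuntimeError(f"inconsistent occupancy at {agent.pos}")
    if agent.phenotype is Phenotype.MIGRATING:
        target = _best_empty_neighbor(agent.pos, world, rng)
        if target is not None:
            world.occupancy[agent.pos] = False
            world.occupancy[target] = True
            agent.pos = target
    elif agent.phenotype is Phenotype.PROLIFERATING:
        if agent.division_clock > 0:
            agent.division_clock -= 1
            return
        target = _best_empty_neighbor(agent.pos, world, rng)
        if target is None:
            return
        daughter = Agent(
            pos=target,
            phenotype=agent.phenotype,
            mol=None if agent.mol is None else agent.mol.copy(),
            division_clock=T_DIV,
        )
        world.occupancy[target] = True
        world.agents.append(daughter)
        agent.division_clock = T_DIV


def snapshot_rows(world: WorldState) -> list:
    """Trajectory snapshot: one (step, row, col, phenotype-letter) record per
    agent, phenotype encoded Q/M/P."""
    return [
        {"step": world.step, "row": a.pos[0], "col": a.pos[1],
         "phenotype": a.phenotype.value}
        for a in world.agents
    ]


def boundary_reached(world: WorldState) -> bool:
    """True once any cell sits on the outermost row or column."""
    n = world.occupancy.shape[0]
    return bool(
        world.occupancy[0, :].any()
        or world.occupancy[n - 1, :].any()
        or world.occupancy[:, 0].any()
        or world.occupancy[:, n - 1].any()
    )
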