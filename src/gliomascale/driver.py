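"""Cross-scale simulation driver.

One macro step (default 3600 s) couples the three layers in a fixed order:

1. each cell reads the glucose at its site and updates its molecular
   network and phenotype,
2. cells consume glucose at their sites,
3. glucose diffuses (explicit substeps covering the macro step),
4. cells act (migrate / divide / rest) in a freshly shuffled order.

A run starts from the circular seed with every cell's network at the
steady state for its local glucose, and ends when the first cell touches
the lattice boundary (or at a step cap for degenerate configurations).
The four endpoints recorded are the step count M_time (expansion
velocity), the final cell count M_total (tumour volume), and the final
migrating/proliferating counts M_mig and M_prolif (tumour build-up).

The published reaction constants make the molecular network far faster
(relaxation within minutes) than the hourly macro step, so by default the
driver sets each cell's network to its steady state at the local glucose
level -- a quasi-steady-state coupling served from a memoized solver on a
quantized glucose grid.  Explicit within-step integration
(``molecular_update="rk4"``) is available for small problems.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .agents import Agent, WorldState, act, boundary_reached, seed_tumour
from .microenv import DiffusionConfig, GlucoseField, consume, diffusion_step, init_field
from .network import (
    NetworkConstants,
    Phenotype,
    PhenotypeThresholds,
    ReactionParameters,
    calibrate_thresholds,
    decide_phenotype,
    integrate_cell,
    steady_state,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Complete specification of one growth simulation."""

    n_side: int = 200
    radius: int = 16
    glucose0: float = 4.5
    glucose_mode: str = "constant"
    params: ReactionParameters = field(default_factory=ReactionParameters)
    consts: NetworkConstants = field(default_factory=NetworkConstants)
    diffusion: DiffusionConfig = field(default_factory=DiffusionConfig)
    thresholds: PhenotypeThresholds | None = None
    max_steps: int = 5000
    seed: int = 0
    dt_macro: float = 3600.0
    molecular_update: str = "qss"
    n_sub_rk4: int = 200
    glucose_quantum: float = 1e-3
    dx: float = 1.5e-5
    #: seconds of nominal uptake applied per macro step.  The published
    #: uptake rate r is large: a full hour's draw (3600 s) would empty even
    #: the richest site within a single step, flip every phenotype to
    #: starvation-driven migration and void the proliferative regime the
    #: model is meant to exhibit at high glucose.  Sixty seconds of nominal
    #: draw per step lets a proliferating cell deplete its site over tens
    #: of steps: deep enough to carve the chemotactic depression, shallow
    #: enough that well-fed regions stay proliferative.
    uptake_dt: float = 60.0

    def __post_init__(self) -> None:
        if self.max_steps <= 0:
            raise ValueError("max_steps must be > 0")
        if self.glucose0 < 0:
            raise ValueError("glucose0 must be >= 0")
        if self.molecular_update not in ("qss", "rk4"):
            raise ValueError("molecular_update must be 'qss' or 'rk4'")

    def resolved_thresholds(self) -> PhenotypeThresholds:
        """Explicit thresholds if given, else calibrated from this config's
        parameters.  Perturbation sweeps must pass the baseline thresholds
        explicitly so the decision criterion stays fixed."""
        if self.thresholds is not None:
            return self.thresholds
        return calibrate_thresholds(self.params, self.consts)


@dataclass(frozen=True)
class Endpoints:
    """The four cellular-scale outputs of one run."""

    M_time: int
    M_total: int
    M_mig: int
    M_prolif: int
    terminated_by: str

    def __post_init__(self) -> None:
        if min(self.M_time, self.M_total, self.M_mig, self.M_prolif) < 0:
            raise ValueError("endpoints must be >= 0")
        if self.M_mig + self.M_prolif > self.M_total:
            raise ValueError("M_mig + M_prolif cannot exceed M_total")

    def as_dict(self) -> dict:
        return {
            "M_time": self.M_time,
            "M_total": self.M_total,
            "M_mig": self.M_mig,
            "M_prolif": self.M_prolif,
            "terminated_by": self.terminated_by,
        }


class SteadyStateCache:
    """Memoized network steady states on a quantized glucose grid.

    Quantization (default 1e-3 g/L) bounds the cache while keeping the
    phenotype decision far below the calibrated threshold separations.
    """

    def __init__(
        self,
        params: ReactionParameters,
        consts: NetworkConstants,
        quantum: float = 1e-3,
    ) -> None:
        self.params = params
        self.consts = consts
        self.quantum = quantum
        self._cache: dict = {}

    def state_at(self, glucose: float) -> np.ndarray:
        key = int(round(glucose / self.quantum))
        hit = self._cache.get(key)
        if hit is None:
            hit = steady_state(
                key * self.quantum, self.params, self.consts, method="cascade"
            )
            self._cache[key] = hit
        return hit


def init_world(config: SimulationConfig, rng: np.random.Generator) -> WorldState:
    """Seed the tumour disc on a fresh glucose field; every cell's network
    starts at the steady state for its local glucose."""
    fld = init_field(
        config.glucose_mode,
        config.glucose0,
        (config.n_side, config.n_side),
        seed=rng.integers(2**31),
        dx=config.dx,
    )
    agents, occupancy = seed_tumour(config.n_side, config.radius)
    cache = SteadyStateCache(config.params, config.consts, config.glucose_quantum)
    thresholds = config.resolved_thresholds()
    for a in agents:
        a.mol = cache.state_at(fld.values[a.pos]).copy()
        a.phenotype = decide_phenotype(a.mol, thresholds)
    return WorldState(agents=agents, occupancy=occupancy, glucose=fld, step=0)


def step(
    world: WorldState,
    config: SimulationConfig,
    rng: np.random.Generator,
    cache: SteadyStateCache | None = None,
    thresholds: PhenotypeThresholds | None = None,
) -> WorldState:
    """Advance the world by one macro step (in place; returns the world)."""
    if cache is None:
        cache = SteadyStateCache(config.params, config.consts, config.glucose_quantum)
    if thresholds is None:
        thresholds = config.resolved_thresholds()
    try:
        # molecular layer + phenotype decision
        for a in world.agents:
            g_local = float(world.glucose.values[a.pos])
            if config.molecular_update == "qss":
                a.mol = cache.state_at(g_local).copy()
            else:
                a.mol = integrate_cell(
                    a.mol, g_local, config.params, config.consts,
                    config.dt_macro, config.n_sub_rk4,
                )
            a.phenotype = decide_phenotype(a.mol, thresholds)
        # microenvironment: consumption then diffusion over the macro step
        world.glucose = consume(world.glucose, world.agents, config.params,
                                config.uptake_dt)
        n_diff = math.ceil(config.dt_macro / config.diffusion.dt_diff)
        world.glucose = diffusion_step(world.glucose, world.occupancy,
                                       config.diffusion, n_steps=n_diff)
        # cellular layer: shuffled order prevents directional artefacts
        order = rng.permutation(len(world.agents))
        snapshot = list(world.agents)
        for idx in order:
            act(snapshot[idx], world, rng)
        world.step += 1
    except Exception as exc:
        raise RuntimeError(f"macro step {world.step} failed") from exc
    return world


def run(config: SimulationConfig) -> Endpoints:
    """Run a complete simulation and return the four endpoints.

    Fully determined by (config, seed).  Termination by the boundary rule
    is the regular outcome; hitting ``max_steps`` is flagged, not an error.
    """
    rng = np.random.default_rng(config.seed)
    cache = SteadyStateCache(config.params, config.consts, config.glucose_quantum)
    thresholds = config.resolved_thresholds()
    world = init_world(config, rng)
    terminated_by = "cap"
    while world.step < config.max_steps:
        if boundary_reached(world):
            terminated_by = "boundary"
            break
        step(world, config, rng, cache=cache, thresholds=thresholds)
    else:
        if boundary_reached(world):
            terminated_by = "boundary"
    counts = world.counts()
    return Endpoints(
        M_time=world.step,
        M_total=len(world.agents),
        M_mig=counts[Phenotype.MIGRATING],
        M_prolif=counts[Phenotype.PROLIFERATING],
        terminated_by=terminated_by,
    )


def config_to_text(config: SimulationConfig) -> str:
    """Serialize a config as a plain-text key -> value document (nested
    structures flattened with dotted keys)."""
    import dataclasses

    lines = []

    def emit(prefix, obj):
        for f in dataclasses.fields(obj):
            v = getattr(obj, f.name)
            if dataclasses.is_dataclass(v):
                emit(f"{prefix}{f.name}.", v)
            elif v is not None:
                lines.append(f"{prefix}{f.name} = {v!r}")

    emit("", config)
    return "\n".join(lines) + "\n"


def run_record(config: SimulationConfig, endpoints: Endpoints) -> dict:
    """One-line run record: config hash, seed, glucose and the endpoints."""
    import hashlib

    digest = hashlib.sha256(config_to_text(config).encode()).hexdigest()[:12]
    return {
        "config": digest,
        "seed": config.seed,
        "glucose0": config.glucose0,
        **endpoints.as_dict(),
    }


def make_sim(config: SimulationConfig):
    """Adapt a config into the ``sim(params, glucose0, seed) -> Endpoints``
    callable the sensitivity pipeline drives.

    The phenotype thresholds are calibrated once from the config's (baseline)
    parameters and pinned: perturbed sweeps must change the network response,
    never the decision criterion itself.
    """
    thresholds = config.resolved_thresholds()

    def sim(params: ReactionParameters, glucose0: float, seed: int) -> Endpoints:
        return run(
            replace(config, params=params, glucose0=glucose0, seed=seed,
                    thresholds=thresholds)
        )

    return sim
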