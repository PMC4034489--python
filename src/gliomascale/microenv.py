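"""Glucose field on the lattice: diffusion, consumption, initialization.

The nutrient (glucose, g/L) lives on the same regular grid as the cell
agents.  It diffuses by an occupancy-modulated heat equation

    du/dt = alpha * D * laplacian(u),

where ``alpha`` slows diffusion at sites occupied by a tumour cell (cells
crowd the extracellular space), integrated with an explicit forward-time
centred-space (FTCS) scheme under the usual 2-D stability bound
``dt <= dx^2 / (4 D)``.  The grid boundary is a no-flux (reflecting) wall:
nutrient cannot leave the dish.  Tumour cells act as point sinks whose
demand depends on phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import Phenotype, ReactionParameters

try:  # optional JIT acceleration for the diffusion inner loop
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

#: g per mmol of glucose (molar mass 180.16 g/mol).
GLUCOSE_G_PER_MMOL = 0.18016


@dataclass
class GlucoseField:
    """2-D glucose concentration field (g/L) with grid spacing dx (m)."""

    values: np.ndarray
    dx: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("glucose field must be 2-D")
        if self.dx <= 0:
            raise ValueError("grid spacing dx must be > 0")
        if np.any(self.values < 0):
            raise ValueError("glucose concentrations must be >= 0")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def total_mass(self) -> float:
        """Sum of concentrations over sites (proportional to dissolved mass)."""
        return float(self.values.sum())

    def copy(self) -> "GlucoseField":
        return GlucoseField(self.values.copy(), self.dx)


@dataclass(frozen=True)
class DiffusionConfig:
    """Diffusion coefficient, occupancy slow-down and substep length.

    Defaults: effective D = 6.7e-13 m^2/s, alpha_occ = 0.5 halving
    diffusion through occupied sites, and a substep of 0.8x the FTCS
    stability limit for dx = 1.5e-5 m.  The effective diffusivity is
    deliberately far below the free-solution value for glucose: it folds in
    tissue tortuosity and matrix binding, and keeps the per-coupling-step
    diffusion length at a few cell diameters.  Nutrient heterogeneity at
    the cell scale is what glucose-directed chemotaxis reads; with a
    free-solution diffusivity the closed dish re-equilibrates completely
    within every one-hour step, no cell-scale gradients survive, and
    directed migration degenerates into a tie-broken random walk.
    """

    D: float = 6.7e-13
    alpha_occ: float = 0.5
    dt_diff: float = 0.8 * (1.5e-5) ** 2 / (4 * 6.7e-13)

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError("diffusion coefficient D must be > 0")
        if not (0 < self.alpha_occ <= 1):
            raise ValueError("alpha_occ must lie in (0, 1]")
        if self.dt_diff <= 0:
            raise ValueError("dt_diff must be > 0")

    def check_stability(self, dx: float) -> None:
        limit = dx * dx / (4.0 * self.D)
        if self.dt_diff > limit * (1 + 1e-12):
            raise ValueError(
                f"diffusion substep {self.dt_diff:.4g} s violates the FTCS "
                f"stability bound dx^2/(4D) = {limit:.4g} s"
            )


def init_field(
    mode: str, level: float, shape: tuple, seed=None, dx: float = 1.5e-5
) -> GlucoseField:
    """Initial glucose field: uniform at ``level`` or i.i.d. uniform on
    [0, 2*level] (mean ``level``), seeded for reproducibility."""
    if level < 0:
        raise ValueError(f"glucose level must be >= 0, got {level}")
    if mode == "constant":
        values = np.full(shape, float(level))
    elif mode == "random":
        rng = np.random.default_rng(seed)
        values = rng.uniform(0.0, 2.0 * level, size=shape)
    else:
        raise ValueError(f"unknown init mode {mode!r} (use 'constant' or 'random')")
    return GlucoseField(values, dx)


def _diffusion_kernel_numpy(
    u: np.ndarray, alpha: np.ndarray, lam: float, n_steps: int
) -> np.ndarray:
    for _ in range(n_steps):
        # ghost-cell mirroring realizes the zero-flux boundary
        up = np.pad(u, 1, mode="edge")
        lap = (
            up[:-2, 1:-1] + up[2:, 1:-1] + up[1:-1, :-2] + up[1:-1, 2:] - 4.0 * u
        )
        u = u + lam * alpha * lap
    return u


if _HAVE_NUMBA:

    @njit(cache=True)
    def _diffusion_kernel_numba(u, alpha, lam, n_steps):  # pragma: no cover
        n, m = u.shape
        v = u.copy()
        w = np.empty_like(u)
        for _ in range(n_steps):
            for i in range(n):
                im = i - 1 if i > 0 else 0
                ip = i + 1 if i < n - 1 else n - 1
                for j in range(m):
                    jm = j - 1 if j > 0 else 0
                    jp = j + 1 if j < m - 1 else m - 1
                    lap = v[im, j] + v[ip, j] + v[i, jm] + v[i, jp] - 4.0 * v[i, j]
                    w[i, j] = v[i, j] + lam * alpha[i, j] * lap
            v, w = w, v
        return v.copy()


def diffusion_step(
    field: GlucoseField,
    occupancy: np.ndarray,
    cfg: DiffusionConfig,
    n_steps: int = 1,
) -> GlucoseField:
    """Advance the field by ``n_steps`` explicit FTCS substeps.

    The occupancy factor multiplies the site-wise update (occupied sites
    update with ``alpha_occ``, free sites with 1).  With uniform alpha the
    scheme conserves total glucose exactly and obeys the discrete maximum
    principle under the stability bound.
    """
    cfg.check_stability(field.dx)
    occupancy = np.asarray(occupancy, dtype=bool)
    if occupancy.shape != field.shape:
        raise ValueError("occupancy mask shape must match the field")
    lam = cfg.D * cfg.dt_diff / (field.dx * field.dx)
    alpha = np.where(occupancy, cfg.alpha_occ, 1.0)
    if _HAVE_NUMBA:
        values = _diffusion_kernel_numba(
            np.ascontiguousarray(field.values), np.ascontiguousarray(alpha),
            lam, n_steps,
        )
    else:
        values = _diffusion_kernel_numpy(field.values, alpha, lam, n_steps)
    return GlucoseField(values, field.dx)


def save_field(field: GlucoseField, path, time: float = 0.0) -> None:
    """Write a field snapshot as a delimited numeric grid with a one-line
    header (shape, dx, time); %.17g preserves doubles bit-exactly."""
    n, m = field.shape
    header = f"shape={n}x{m} dx={field.dx:.17g} time={time:.17g}"
    np.savetxt(path, field.values, fmt="%.17g", header=header)


def load_field(path) -> tuple:
    """Read a snapshot written by :func:`save_field`; returns (field, time)."""
    with open(path) as fh:
        header = fh.readline().lstrip("# ").split()
    meta = dict(tok.split("=", 1) for tok in header)
    values = np.loadtxt(path)
    n, m = (int(v) for v in meta["shape"].split("x"))
    if values.shape != (n, m):
        raise ValueError(f"snapshot shape {values.shape} disagrees with header {n}x{m}")
    return GlucoseField(values, float(meta["dx"])), float(meta["time"])


def phenotype_weight(phenotype: Phenotype, params: ReactionParameters) -> float:
    """Consumption weight: proliferating cells draw the larger share C1;
    migrating and quiescent cells the smaller share C2."""
    return params.C1 if phenotype is Phenotype.PROLIFERATING else params.C2


def consume(
    field: GlucoseField, agents, params: ReactionParameters, dt: float
) -> GlucoseField:
    """Subtract phenotype-weighted glucose demand at each occupied site.

    Demand per cell is ``r`` (mmol L^-1 s^-1, converted to g L^-1 s^-1 via
    the molar mass) times the phenotype weight times ``dt``; sites clamp
    at zero when demand exceeds supply.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    values = field.values.copy()
    base = params.r * GLUCOSE_G_PER_MMOL * dt
    for agent in agents:
        i, j = agent.pos
        demand = base * phenotype_weight(agent.phenotype, params)
        values[i, j] = max(0.0, values[i, j] - demand)
    return GlucoseField(values, field.dx)
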