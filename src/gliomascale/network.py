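"""Per-cell molecular interaction network: glucose → miR-451 → AMPK/mTORC1.

Each tumour-cell agent carries a nine-species reaction network that converts
the extracellular glucose level into a migrate-or-proliferate decision (the
"Go or Grow" switch).  Glucose drives synthesis of the microRNA miR-451,
which represses translation of the scaffold protein MO25.  MO25 assembles the
active LKB1-STRAD complex, which phosphorylates the energy-stress kinase AMPK.
Active AMPK phosphorylates TSC2, TSC2 inactivates Rheb, and Rheb activity is
required for mTORC1 activation; AMPK additionally inhibits mTORC1 directly.
The net effect is a switch: low glucose → AMPK high / mTORC1 low → migration;
high glucose → AMPK low / mTORC1 high → proliferation.

State vector (concentrations, pmol/L):

    x1  miR-451             x4  MO25                x7  TSC2 (phosphorylated)
    x2  MO25 mRNA           x5  LKB1-STRAD complex  x8  Rheb (active)
    x3  MO25 mRNA:miR-451   x6  AMPK (phosphorylated)  x9  mTORC1 (active)

The kinetics combine mass-action binding/decay steps with Michaelis-Menten
phosphorylation/dephosphorylation cycles over conserved pools (Goldbeter-
Koshland form).  The right-hand side implemented here is this package's
documented canonical reconstruction of that interaction scheme; it is kept
behind the narrow :func:`rhs` interface so an alternative system can be
substituted without touching any other module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields, replace
from enum import Enum
from functools import lru_cache

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root

logger = logging.getLogger(__name__)

#: Species names, index i corresponds to x_{i+1}.
SPECIES = (
    "miR451",
    "MO25_mRNA",
    "MO25_mRNA_miR451",
    "MO25",
    "LKB1_STRAD",
    "AMPK_P",
    "TSC2_P",
    "Rheb_active",
    "mTORC1_active",
)
N_SPECIES = len(SPECIES)

#: The 31 reaction constants subject to perturbation in the sensitivity sweep.
#: The consumption parameters r, C1, C2 belong to the microenvironment and are
#: not perturbed.
PERTURBABLE = (
    "k1", "k1_i", "k2", "k3", "k4", "k5", "k6", "k7", "k8", "k9", "k10",
    "k11_m1", "k11_c1", "k11_m2", "k11_c2", "k12_i", "k12",
    "k13_m1", "k13_c1", "k13_m2", "k13_c2", "k14", "k15_i", "k15", "k16",
    "k17_m1", "k17_c1", "k17_m2", "k17_c2", "k18_m", "k18_c",
)


@dataclass(frozen=True)
class ReactionParameters:
    """The 31 perturbable reaction constants plus the consumption triple.

    Defaults are the published baseline values.  Units: second-order rate
    constants (k1, k2, k9) in pmol^-1 L s^-1; first-order rates in s^-1;
    Michaelis constants (the ``*_m*`` entries, k1_i, k15_i, k18_m) in pmol/L
    except the dimensionless k12_i; catalytic velocities (the ``*_c*``
    entries, k18_c) in pmol L^-1 s^-1; r in mmol L^-1 s^-1; C1, C2
    dimensionless.
    """

    k1: float = 1.2e-9
    k1_i: float = 1.0
    k2: float = 3e-2
    k3: float = 3e1
    k4: float = 1.4583e-2
    k5: float = 3.6e2
    k6: float = 1.0467e-2
    k7: float = 5.626e-3
    k8: float = 6.4167e-3
    k9: float = 6e-2
    k10: float = 3.6e2
    k11_m1: float = 5e2
    k11_c1: float = 1.8e5
    k11_m2: float = 5e2
    k11_c2: float = 1.8e6
    k12_i: float = 6e-1
    k12: float = 6e2
    k13_m1: float = 1e2
    k13_c1: float = 6e2
    k13_m2: float = 1e2
    k13_c2: float = 6e4
    k14: float = 3.6e2
    k15_i: float = 5.0
    k15: float = 3.6e2
    k16: float = 3.6e2
    k17_m1: float = 1e2
    k17_c1: float = 3.6e3
    k17_m2: float = 1e2
    k17_c2: float = 3.6e5
    k18_m: float = 1.5104e3
    k18_c: float = 4.86e3
    r: float = 1.17e-2
    C1: float = 8.571e-1
    C2: float = 1.429e-1

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"parameter {f.name} must be finite and > 0, got {v!r}")
        if abs(self.C1 + self.C2 - 1.0) > 1e-3:
            raise ValueError(f"C1 + C2 must equal 1 within 1e-3, got {self.C1 + self.C2}")

    def perturbed(self, name: str, factor: float) -> "ReactionParameters":
        """Return a copy with ``name`` multiplied by ``factor``.

        Only the 31 perturbable constants may be scaled.
        """
        if name not in PERTURBABLE:
            raise KeyError(f"{name!r} is not a perturbable reaction parameter")
        if factor <= 0:
            raise ValueError(f"perturbation factor must be > 0, got {factor}")
        return replace(self, **{name: getattr(self, name) * factor})

    def perturbed_many(self, perturbations) -> "ReactionParameters":
        """Apply a sequence of (name, factor) perturbations (distinct names)."""
        out = self
        seen = set()
        for name, factor in perturbations:
            if name in seen:
                raise ValueError(f"parameter {name!r} perturbed twice")
            seen.add(name)
            out = out.perturbed(name, factor)
        return out


@dataclass(frozen=True)
class NetworkConstants:
    """Conserved pool totals and unit-conversion constants.

    These are structural constants of the reconstruction, not published
    reaction parameters, and are never perturbed by the sensitivity sweep.

    Attributes
    ----------
    A_tot, T_tot, R_tot, M_tot, S_tot:
        Conserved totals of AMPK, TSC2, Rheb, mTORC1 and LKB1-STRAD
        (pmol/L).  The phosphorylated/active forms x5-x9 are bounded above
        by these pools.
    kappa:
        Glucose mass-to-molar conversion, pmol per g (molar mass
        180.16 g/mol → 5.551e9 pmol/g).
    g_ref:
        Glucose normalisation for the dimensionless AMPK-inhibition input,
        g/L (the highest glucose level used in the growth experiments).
    d4:
        First-order MO25 protein turnover rate, s^-1.  Without protein
        turnover MO25 would accumulate without bound (translation has no
        counterweight because scaffold binding conserves MO25+complex), and
        the network would have no steady state to calibrate against; 1e-4
        s^-1 corresponds to a ~2 h half-life, typical for a signalling
        scaffold.
    """

    A_tot: float = 1e3
    T_tot: float = 1e3
    R_tot: float = 1e3
    M_tot: float = 1e3
    S_tot: float = 5e2
    kappa: float = 5.551e9
    g_ref: float = 4.5
    d4: float = 1e-4

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"constant {f.name} must be finite and > 0, got {v!r}")

    def pool_bounds(self) -> np.ndarray:
        """Upper bound per species (inf where no conservation applies)."""
        b = np.full(N_SPECIES, np.inf)
        b[4] = self.S_tot
        b[5] = self.A_tot
        b[6] = self.T_tot
        b[7] = self.R_tot
        b[8] = self.M_tot
        return b


class Phenotype(Enum):
    """Cellular phenotype realized on the lattice each macro step."""

    MIGRATING = "M"
    PROLIFERATING = "P"
    QUIESCENT = "Q"


@dataclass(frozen=True)
class PhenotypeThresholds:
    """AMPK (theta_A) and mTORC1 (theta_M) decision thresholds, pmol/L."""

    theta_A: float
    theta_M: float

    def __post_init__(self) -> None:
        if not (self.theta_A > 0 and self.theta_M > 0):
            raise ValueError("phenotype thresholds must be > 0")


def _check_state(x: np.ndarray, glucose: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape != (N_SPECIES,):
        raise ValueError(f"state must have shape ({N_SPECIES},), got {x.shape}")
    bad = ~np.isfinite(x)
    if bad.any():
        i = int(np.argmax(bad))
        raise ValueError(f"non-finite concentration for species {SPECIES[i]} (x{i + 1})")
    if not np.isfinite(glucose) or glucose < 0:
        raise ValueError(f"glucose must be finite and >= 0, got {glucose!r}")
    return x


def rhs(
    state: np.ndarray,
    glucose: float,
    params: ReactionParameters,
    consts: NetworkConstants,
) -> np.ndarray:
    """Time derivatives of the nine species, pmol L^-1 s^-1.

    ``glucose`` is the local extracellular level in g/L; it enters twice,
    as a molar substrate for miR-451 synthesis (via ``kappa``) and as the
    dimensionless saturating input to the direct glucose inhibition of AMPK
    (via ``g_ref``).  Every perturbable constant appears in exactly one
    reaction term, so a single-parameter perturbation touches exactly one
    arrow of the network.
    """
    x = _check_state(state, glucose)
    p, c = params, consts
    x1, x2, x3, x4, x5, x6, x7, x8, x9 = x
    g_mol = glucose * c.kappa        # pmol/L
    g_hat = glucose / c.g_ref        # dimensionless

    bind = p.k2 * x1 * x2            # miR-451 : MO25-mRNA association
    unbind = p.k3 * x3

    dx = np.empty(N_SPECIES)
    # miR-451: glucose-driven synthesis with product inhibition, recycling
    # from the complex, first-order decay.
    dx[0] = p.k1 * g_mol / (1.0 + x1 / p.k1_i) - bind + unbind - p.k6 * x1
    # MO25 mRNA: constitutive transcription, sequestration, decay.
    dx[1] = p.k4 - bind + unbind - p.k7 * x2
    # bound complex: complex-mediated mRNA degradation at rate k5.
    dx[2] = bind - unbind - p.k5 * x3
    # MO25 protein: translation, reversible scaffold assembly, turnover.
    assemble = p.k9 * x4 * (c.S_tot - x5)
    disassemble = p.k10 * x5
    dx[3] = p.k8 * x2 - assemble + disassemble - c.d4 * x4
    dx[4] = assemble - disassemble
    # AMPK phosphorylation cycle, driven by LKB1-STRAD, opposed by a
    # phosphatase and by direct glucose inhibition.
    dx[5] = (
        p.k11_c1 * x5 * (c.A_tot - x6) / (p.k11_m1 + c.A_tot - x6)
        - p.k11_c2 * x6 / (p.k11_m2 + x6)
        - p.k12 * x6 * g_hat / (p.k12_i + g_hat)
    )
    # TSC2 phosphorylation cycle driven by active AMPK.
    dx[6] = (
        p.k13_c1 * x6 * (c.T_tot - x7) / (p.k13_m1 + c.T_tot - x7)
        - p.k13_c2 * x7 / (p.k13_m2 + x7)
    )
    # Rheb: constitutive reactivation, TSC2-mediated inactivation.
    dx[7] = p.k14 * (c.R_tot - x8) - p.k15 * x8 * x7 / (p.k15_i + x7)
    # mTORC1: Rheb-driven activation cycle, AMPK-mediated and basal loss.
    dx[8] = (
        p.k17_c1 * x8 * (c.M_tot - x9) / (p.k17_m1 + c.M_tot - x9)
        - p.k17_c2 * x9 / (p.k17_m2 + x9)
        - p.k18_c * x6 * x9 / (p.k18_m + x9)
        - p.k16 * x9
    )
    return dx


def integrate_cell(
    state: np.ndarray,
    glucose: float,
    params: ReactionParameters,
    consts: NetworkConstants,
    dt_macro: float,
    n_sub: int,
) -> np.ndarray:
    """Advance one cell's network by ``dt_macro`` seconds.

    Classical fixed-step 4th-order Runge-Kutta with ``n_sub`` equal substeps.
    After each substep the state is clamped to [0, pool bound]; clamping is
    counted and logged (it indicates the substep is too coarse for the
    stiffness of the current parameter set).
    """
    if dt_macro <= 0:
        raise ValueError(f"dt_macro must be > 0, got {dt_macro}")
    if n_sub < 1:
        raise ValueError(f"n_sub must be >= 1, got {n_sub}")
    x = _check_state(state, glucose).copy()
    h = dt_macro / n_sub
    lo = np.zeros(N_SPECIES)
    hi = consts.pool_bounds()
    n_clamped = 0
    for step in range(n_sub):
        k1v = rhs(x, glucose, params, consts)
        k2v = rhs(x + 0.5 * h * k1v, glucose, params, consts)
        k3v = rhs(x + 0.5 * h * k2v, glucose, params, consts)
        k4v = rhs(x + h * k3v, glucose, params, consts)
        x_new = x + (h / 6.0) * (k1v + 2.0 * k2v + 2.0 * k3v + k4v)
        bad = ~np.isfinite(x_new)
        if bad.any():
            i = int(np.argmax(bad))
            raise FloatingPointError(
                f"integration produced a non-finite value at substep {step} "
                f"for species {SPECIES[i]} (x{i + 1})"
            )
        clamped = np.clip(x_new, lo, hi)
        n_clamped += int(np.sum(clamped != x_new))
        x = clamped
    if n_clamped:
        logger.warning(
            "integrate_cell clamped %d component updates to [0, pool] "
            "(dt=%.3g s, n_sub=%d)", n_clamped, dt_macro, n_sub,
        )
    return x


def _cascade_steady_state(
    glucose: float, params: ReactionParameters, consts: NetworkConstants
) -> np.ndarray:
    """Equilibrium by exploiting the feed-forward structure of the network.

    At fixed glucose the network is a cascade: (x1,x2,x3) close among
    themselves, then x4, x5, x6, x7, x8, x9 each depend only on upstream
    species.  Each stage reduces to a scalar equation that is strictly
    decreasing in its own variable, so every root is unique and bracketed.
    """
    p, c = params, consts
    g_mol = glucose * c.kappa
    g_hat = glucose / c.g_ref
    beta = p.k2 * p.k5 / (p.k3 + p.k5)  # net sequestration rate constant

    def x2_of(x1: float) -> float:
        return p.k4 / (p.k7 + beta * x1)

    def f1(x1: float) -> float:
        return p.k1 * g_mol / (1.0 + x1 / p.k1_i) - beta * x1 * x2_of(x1) - p.k6 * x1

    if g_mol == 0.0:
        x1 = 0.0
    else:
        hi = p.k1 * g_mol / p.k6 + 1.0
        x1 = brentq(f1, 0.0, hi, xtol=1e-15, rtol=8.9e-16, maxiter=200)
    x2 = x2_of(x1)
    x3 = p.k2 * x1 * x2 / (p.k3 + p.k5)
    x4 = p.k8 * x2 / c.d4
    x5 = c.S_tot * p.k9 * x4 / (p.k10 + p.k9 * x4)

    def solve_decreasing(f, hi: float) -> float:
        f0 = f(0.0)
        if f0 <= 0.0:
            return 0.0
        return brentq(f, 0.0, hi, xtol=1e-15, rtol=8.9e-16, maxiter=200)

    def f6(x6: float) -> float:
        return (
            p.k11_c1 * x5 * (c.A_tot - x6) / (p.k11_m1 + c.A_tot - x6)
            - p.k11_c2 * x6 / (p.k11_m2 + x6)
            - p.k12 * x6 * g_hat / (p.k12_i + g_hat)
        )

    x6 = solve_decreasing(f6, c.A_tot)

    def f7(x7: float) -> float:
        return (
            p.k13_c1 * x6 * (c.T_tot - x7) / (p.k13_m1 + c.T_tot - x7)
            - p.k13_c2 * x7 / (p.k13_m2 + x7)
        )

    x7 = solve_decreasing(f7, c.T_tot)
    x8 = p.k14 * c.R_tot / (p.k14 + p.k15 * x7 / (p.k15_i + x7))

    def f9(x9: float) -> float:
        return (
            p.k17_c1 * x8 * (c.M_tot - x9) / (p.k17_m1 + c.M_tot - x9)
            - p.k17_c2 * x9 / (p.k17_m2 + x9)
            - p.k18_c * x6 * x9 / (p.k18_m + x9)
            - p.k16 * x9
        )

    x9 = solve_decreasing(f9, c.M_tot)
    return np.array([x1, x2, x3, x4, x5, x6, x7, x8, x9])


def steady_state(
    glucose: float,
    params: ReactionParameters,
    consts: NetworkConstants,
    tol: float = 1e-6,
    t_max: float = 1e7,
    method: str = "relax",
) -> np.ndarray:
    """Network equilibrium at fixed glucose, from the all-zero state.

    ``method="relax"`` integrates the stiff system from zero with an implicit
    solver over growing horizons and polishes the endpoint with a Newton
    solve; ``method="cascade"`` solves the feed-forward stage equations
    directly (identical fixed point, orders of magnitude faster).  Both are
    deterministic.  The returned state satisfies ``max|rhs| < tol``.
    """
    if not np.isfinite(glucose) or glucose < 0:
        raise ValueError(f"glucose must be finite and >= 0, got {glucose!r}")
    if method == "cascade":
        x = _cascade_steady_state(glucose, params, consts)
    elif method == "relax":
        x = np.zeros(N_SPECIES)
        t = 1e2
        while True:
            sol = solve_ivp(
                lambda _t, y: rhs(y, glucose, params, consts),
                (0.0, t),
                x,
                method="LSODA",
                rtol=1e-8,
                atol=1e-10,
            )
            if not sol.success:
                raise RuntimeError(f"relaxation failed at horizon {t:.3g} s: {sol.message}")
            x = np.clip(sol.y[:, -1], 0.0, consts.pool_bounds())
            if np.max(np.abs(rhs(x, glucose, params, consts))) < tol or t >= t_max:
                break
            t *= 10.0
    else:
        raise ValueError(f"unknown method {method!r}")
    # Newton polish removes the residual the relaxation horizon leaves behind.
    sol = root(lambda y: rhs(y, glucose, params, consts), x, method="hybr", tol=1e-12)
    if sol.success and np.all(sol.x >= -1e-9):
        x = np.clip(sol.x, 0.0, consts.pool_bounds())
    resid = float(np.max(np.abs(rhs(x, glucose, params, consts))))
    if resid >= tol:
        raise RuntimeError(
            f"no steady state within tolerance: residual {resid:.3g} >= {tol:.3g} "
            f"at glucose {glucose} g/L"
        )
    return x


@lru_cache(maxsize=128)
def _calibrate_cached(
    params: ReactionParameters,
    consts: NetworkConstants,
    glucose_low: float,
    glucose_high: float,
) -> PhenotypeThresholds:
    ss_low = steady_state(glucose_low, params, consts, method="cascade")
    ss_high = steady_state(glucose_high, params, consts, method="cascade")
    x6_lo, x9_lo = ss_low[5], ss_low[8]
    x6_hi, x9_hi = ss_high[5], ss_high[8]
    if np.isclose(x6_lo, x6_hi, rtol=1e-6) or np.isclose(x9_lo, x9_hi, rtol=1e-6):
        raise RuntimeError(
            "degenerate steady states: AMPK/mTORC1 do not separate between "
            f"{glucose_low} and {glucose_high} g/L; the switch cannot be calibrated"
        )
    return PhenotypeThresholds(
        theta_A=0.5 * (x6_lo + x6_hi), theta_M=0.5 * (x9_lo + x9_hi)
    )


def calibrate_thresholds(
    params: ReactionParameters,
    consts: NetworkConstants,
    glucose_low: float = 0.3,
    glucose_high: float = 4.5,
) -> PhenotypeThresholds:
    """Midpoint phenotype thresholds from the two extreme glucose levels.

    theta_A (theta_M) is the midpoint of the steady-state AMPK (mTORC1)
    level at ``glucose_low`` and ``glucose_high``.  By construction the
    steady state at the low level classifies as MIGRATING and the one at the
    high level as PROLIFERATING.  Results are cached per parameter set;
    perturbed sweeps must keep using the baseline thresholds so that the
    perturbation changes the network response, not the decision criterion.
    """
    lo, hi = sorted((glucose_low, glucose_high))
    return _calibrate_cached(params, consts, lo, hi)


def decide_phenotype(state: np.ndarray, thresholds: PhenotypeThresholds) -> Phenotype:
    """Map AMPK (x6) and mTORC1 (x9) levels to a phenotype.

    AMPK above threshold with mTORC1 at-or-below threshold → MIGRATING;
    mTORC1 above threshold with AMPK at-or-below → PROLIFERATING; any other
    combination (both high, both low, both at threshold) → QUIESCENT.
    """
    x6, x9 = float(state[5]), float(state[8])
    a_high = x6 > thresholds.theta_A
    m_high = x9 > thresholds.theta_M
    if a_high and not m_high:
        return Phenotype.MIGRATING
    if m_high and not a_high:
        return Phenotype.PROLIFERATING
    return Phenotype.QUIESCENT
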