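"""Surrogate endpoint generator for exercising the sensitivity pipeline.

Full lattice simulations are expensive; the pipeline logic (sweep,
coefficients, selection, pairing, screening) is independent of where the
endpoint numbers come from.  The surrogate emulates the simulator's
input→output statistical structure with a log-linear response:

    M_e(perturbations, glucose) =
        baseline_e(glucose) * exp( sum_p w_e(p) * ln(factor_p) ) * noise,

with multiplicative lognormal replicate noise (exp(sigma * z), z standard
normal; noise = 1 when sigma = 0) and integer rounding of the count-valued
endpoints.  Under this response a single perturbation (p, b) has the exact
closed-form sensitivity coefficient

    S_e = (b**w_e(p) - 1) / (b - 1),

which makes the surrogate the analytic oracle for the pipeline: whatever
the sweep code computes must match this expression at zero noise.  The
surrogate is a test harness, not a quantitative emulator of the simulator.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np

from .network import PERTURBABLE, ReactionParameters
from .sensitivity import DEFAULT_FACTORS, DEFAULT_GLUCOSE_LEVELS, ENDPOINTS, SelectionRule

from .driver import Endpoints

#: Baseline endpoints per glucose level for the default surrogate: low
#: glucose → fast loose tumours (few steps, few cells, migration-heavy),
#: high glucose → slow dense tumours (many steps, many cells,
#: proliferation-heavy), mirroring the simulator's qualitative behaviour.
DEFAULT_BASELINES = {
    0.3: {"time": 100.0, "total": 1500.0, "mig": 1200.0, "prolif": 200.0},
    1.125: {"time": 250.0, "total": 4000.0, "mig": 2200.0, "prolif": 1500.0},
    2.25: {"time": 420.0, "total": 8000.0, "mig": 2600.0, "prolif": 4800.0},
    4.5: {"time": 600.0, "total": 12000.0, "mig": 2000.0, "prolif": 9200.0},
}


@dataclass(frozen=True)
class SurrogateSpec:
    """Log-response weights, per-glucose baselines, noise scale and seed."""

    weights: dict        # param -> {endpoint: w}
    baselines: dict      # glucose -> {endpoint: baseline > 0}
    sigma: float = 0.0
    seed: int = 0
    #: round endpoints to integers (counts/steps); disable for exact
    #: closed-form coefficient checks.
    round_counts: bool = True

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        for g, b in self.baselines.items():
            for e in ENDPOINTS:
                if b.get(e, 0) <= 0:
                    raise ValueError(f"baseline {e} at glucose {g} must be > 0")

    def weight(self, param: str, endpoint: str) -> float:
        if param not in self.weights:
            raise KeyError(f"unknown parameter {param!r} in surrogate spec")
        return float(self.weights[param].get(endpoint, 0.0))


def _noise_rng(spec: SurrogateSpec, replicate_index: int, perturbations, glucose0):
    """Deterministic rng per (spec seed, replicate, setting)."""
    tag = ";".join(f"{p}*{b:.12g}" for p, b in sorted(perturbations))
    h = zlib.crc32(f"{tag}|{glucose0:.12g}".encode())
    return np.random.default_rng(
        np.random.SeedSequence([int(spec.seed), int(replicate_index), int(h)])
    )


def surrogate_run(
    perturbations, glucose0: float, spec: SurrogateSpec, replicate_index: int = 0
) -> Endpoints:
    """Synthetic endpoints for a (possibly multi-parameter) perturbation.

    ``perturbations`` is a list of (parameter name, factor); factors must be
    positive and parameters known to the spec.
    """
    perturbations = list(perturbations)
    for p, b in perturbations:
        if p not in spec.weights:
            raise KeyError(f"unknown parameter {p!r} in surrogate spec")
        if b <= 0:
            raise ValueError(f"factor for {p!r} must be > 0, got {b}")
    if glucose0 not in spec.baselines:
        raise KeyError(f"no surrogate baseline for glucose {glucose0!r}")
    rng = _noise_rng(spec, replicate_index, perturbations, glucose0)
    values = {}
    for e in ENDPOINTS:
        log_resp = sum(spec.weight(p, e) * math.log(b) for p, b in perturbations)
        noise = math.exp(spec.sigma * rng.standard_normal()) if spec.sigma > 0 else 1.0
        values[e] = spec.baselines[glucose0][e] * math.exp(log_resp) * noise
    _cast = (lambda v: int(round(v))) if spec.round_counts else (lambda v: v)
    m_total = _cast(values["total"])
    m_mig = min(_cast(values["mig"]), m_total)
    m_prolif = min(_cast(values["prolif"]), m_total - m_mig)
    return Endpoints(
        M_time=_cast(values["time"]),
        M_total=m_total,
        M_mig=m_mig,
        M_prolif=m_prolif,
        terminated_by="boundary",
    )


def make_surrogate_sim(spec: SurrogateSpec, base_params: ReactionParameters):
    """Adapt the surrogate to the ``sim(params, glucose0, seed)`` interface
    of the sweep: perturbations are recovered as the component-wise ratio
    to the baseline parameter set, and the seed doubles as the replicate
    index."""

    def sim(params: ReactionParameters, glucose0: float, seed: int) -> Endpoints:
        perturbations = []
        for name in PERTURBABLE:
            ratio = getattr(params, name) / getattr(base_params, name)
            if not math.isclose(ratio, 1.0, rel_tol=1e-12):
                perturbations.append((name, ratio))
        return surrogate_run(perturbations, glucose0, spec, replicate_index=seed)

    return sim


def default_spec(
    seed: int = 0,
    sigma: float = 0.0,
    dominant: str | None = None,
    baselines: dict | None = None,
    round_counts: bool = True,
) -> SurrogateSpec:
    """Generic surrogate: small random log-weights per parameter, optionally
    with one planted dominant parameter (|w| = 1.5 on every endpoint).

    The three count endpoints (total, mig, prolif) share one weight per
    parameter -- in the simulator they co-move, and equal weights keep the
    mig + prolif <= total consistency clamp from ever binding at zero
    noise, so the closed-form coefficient holds exactly on every endpoint.
    """
    rng = np.random.default_rng(seed)
    weights = {}
    for p in PERTURBABLE:
        w_time = float(rng.uniform(-0.3, 0.3))
        w_count = float(rng.uniform(-0.3, 0.3))
        weights[p] = {"time": w_time, "total": w_count, "mig": w_count, "prolif": w_count}
    if dominant is not None:
        if dominant not in weights:
            raise KeyError(f"unknown parameter {dominant!r}")
        weights[dominant] = {e: 1.5 for e in ENDPOINTS}
    return SurrogateSpec(
        weights=weights,
        baselines=baselines or DEFAULT_BASELINES,
        sigma=sigma,
        seed=seed,
        round_counts=round_counts,
    )


def _solve_weight(qualifying, factors, ratio: float) -> float:
    """Weight w with b**w > ratio exactly for b in ``qualifying``.

    Each factor contributes a half-line constraint on w (the response is
    monotone in w for fixed b); the intersection is an interval, and the
    midpoint (nudged inward when a side is unbounded) is returned.  A
    qualifying set incompatible with a monotone log-linear response raises.
    """
    if ratio <= 1:
        raise ValueError("ratio must exceed 1")
    lo, hi = -math.inf, math.inf
    for b in factors:
        if b == 1:
            continue
        c = math.log(ratio) / math.log(b)
        inq = b in qualifying
        if (b > 1) == inq:       # w must exceed c
            lo = max(lo, c)
        else:                    # w must not exceed c
            hi = min(hi, c)
    if lo >= hi:
        raise ValueError("qualifying factor set is not realizable by a monotone response")
    if math.isinf(lo) and math.isinf(hi):
        return 0.0
    if math.isinf(lo):
        return hi - max(0.1, 0.1 * abs(hi))
    if math.isinf(hi):
        return lo + max(0.1, 0.1 * abs(lo))
    return 0.5 * (lo + hi)


def spec_from_factor_groups(
    groups,
    factors=DEFAULT_FACTORS,
    plus_rule: SelectionRule | None = None,
    minus_rule: SelectionRule | None = None,
    baselines: dict | None = None,
    sigma: float = 0.0,
    seed: int = 0,
) -> SurrogateSpec:
    """Surrogate whose selection stage reproduces a given Factor+/Factor-
    table exactly (at zero noise).

    The time-endpoint weight of each parameter is solved so that exactly
    the Factor+ factors push dM_time beyond the + threshold, and the
    total-endpoint weight so that exactly the Factor- factors push
    dM_total below the - threshold; parameters absent from the table get
    zero weight.
    """
    from .sensitivity import MINUS_RULE, PLUS_RULE  # defaults

    plus_rule = plus_rule or PLUS_RULE
    minus_rule = minus_rule or MINUS_RULE
    ratio_plus = plus_rule.threshold + 1.0           # b**w > ratio_plus
    ratio_minus = 1.0 / (minus_rule.threshold + 1.0)  # b**-w > 1/(thr+1)
    weights = {}
    for p in PERTURBABLE:
        w_time = _solve_weight(set(groups.factor_plus.get(p, [])), factors, ratio_plus)
        w_total = -_solve_weight(set(groups.factor_minus.get(p, [])), factors, ratio_minus)
        weights[p] = {"time": w_time, "total": w_total, "mig": w_total, "prolif": w_total}
    return SurrogateSpec(
        weights=weights,
        baselines=baselines or DEFAULT_BASELINES,
        sigma=sigma,
        seed=seed,
    )
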