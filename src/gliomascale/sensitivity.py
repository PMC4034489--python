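"""Cross-scale sensitivity analysis of the growth model.

Molecular-scale reaction constants are perturbed one at a time
(multiplication by a factor b) and the effect is read out on the cellular
scale through four endpoints: the number of macro steps to the boundary
(M_time, expansion velocity), the final cell count (M_total, tumour
volume), and the final migrating / proliferating counts (M_mig, M_prolif).

The normalized local sensitivity coefficient for endpoint e is

    S = (M_pert / M_base - 1) / (b - 1),

the relative endpoint change per relative parameter change, and the raw
relative endpoint change is

    dM = M_pert / M_base - 1.

The pipeline stages after the one-at-a-time sweep:

* ``summarize_max``   -- per parameter, the maximal |S| over all factors and
  glucose levels (with the argmax glucose level),
* ``select_groups``   -- Factor+ (strong slow-down at low glucose,
  dM_time > 9 at 0.3 g/L) and Factor- (strong shrinkage at high glucose,
  dM_total < -0.8 at 4.5 g/L) parameter-factor sets,
* ``enumerate_pairs`` -- all cross combinations of one Factor+ and one
  Factor- scaling on distinct parameters,
* ``screen_pairs``    -- pairs that simultaneously slow expansion
  (dM_time > margin) and shrink the tumour (dM_total < -margin), per
  glucose level and across a level set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import PERTURBABLE, ReactionParameters

#: The 20 perturbation factors of the standard sweep design.
DEFAULT_FACTORS = (
    0.01, 0.1, 0.5, 0.8, 0.9, 0.95, 0.98, 0.99, 1.01, 1.02,
    1.05, 1.1, 1.2, 1.5, 1.9, 1.99, 5.0, 10.0, 50.0, 100.0,
)

#: Initial glucose levels of the standard sweep design, g/L.
DEFAULT_GLUCOSE_LEVELS = (0.3, 1.125, 2.25, 4.5)

ENDPOINTS = ("time", "total", "mig", "prolif")


def sensitivity_coefficient(M_pert: float, M_base: float, b: float) -> float:
    """Normalized sensitivity coefficient (M_pert/M_base - 1)/(b - 1).

    Algebraically identical to the quotient of relative changes
    (ΔM/M)/(Δk/k) for a parameter scaled by b.
    """
    if b <= 0:
        raise ValueError(f"factor must be > 0, got {b}")
    if b == 1:
        raise ValueError("sensitivity coefficient undefined for factor b = 1")
    if M_base == 0:
        raise ValueError("sensitivity coefficient undefined for zero baseline output")
    return (M_pert / M_base - 1.0) / (b - 1.0)


def delta_M(M_pert: float, M_base: float) -> float:
    """Relative endpoint change M_pert/M_base - 1 (so dM = a means the
    perturbed output is (a+1) times the baseline)."""
    if M_base == 0:
        raise ValueError("relative change undefined for zero baseline output")
    return M_pert / M_base - 1.0


@dataclass
class SensitivityRecord:
    """One (parameter, factor, glucose) cell of the sweep."""

    param: str
    factor: float
    glucose0: float
    M_time: float
    M_total: float
    M_mig: float
    M_prolif: float
    S_time: float = np.nan
    S_total: float = np.nan
    S_mig: float = np.nan
    S_prolif: float = np.nan
    dM_time: float = np.nan
    dM_total: float = np.nan
    error: str | None = None


@dataclass
class SummaryRow:
    """Per-parameter maxima of |S| with the glucose level attaining them."""

    param: str
    m: dict = field(default_factory=dict)        # endpoint -> max |S|
    glucose: dict = field(default_factory=dict)  # endpoint -> argmax glucose


@dataclass
class FactorGroups:
    """Factor+ / Factor- scaling sets per parameter (lists may be empty)."""

    factor_plus: dict = field(default_factory=dict)   # param -> list of factors
    factor_minus: dict = field(default_factory=dict)  # param -> list of factors

    def params_listed(self) -> list:
        both = set(self.factor_plus) | set(self.factor_minus)
        return sorted(p for p in both if self.factor_plus.get(p) or self.factor_minus.get(p))

    def params_with_both(self) -> list:
        return sorted(
            p for p in self.params_listed()
            if self.factor_plus.get(p) and self.factor_minus.get(p)
        )


@dataclass(frozen=True, order=True)
class PairSpec:
    """One Factor+ scaling combined with one Factor- scaling on a
    different parameter."""

    param1: str
    factor1: float
    param2: str
    factor2: float

    def __post_init__(self) -> None:
        if self.param1 == self.param2:
            raise ValueError("a combined perturbation needs two distinct parameters")


@dataclass
class PairRecord:
    """Replicate-mean endpoint changes for one combined perturbation at one
    glucose level."""

    pair: PairSpec
    glucose0: float
    dM_time: float
    dM_total: float
    error: str | None = None


def _mean_endpoints(sim, params, glucose0, replicates, base_seed):
    """Replicate-mean of the four endpoints; seeds are base + replicate index
    (common random numbers across parameter settings)."""
    acc = np.zeros(4)
    for i in range(replicates):
        ep = sim(params, glucose0, base_seed + i)
        acc += (ep.M_time, ep.M_total, ep.M_mig, ep.M_prolif)
    return acc / replicates


def run_lsa(
    sim,
    params: ReactionParameters,
    factors=DEFAULT_FACTORS,
    glucose_levels=DEFAULT_GLUCOSE_LEVELS,
    replicates: int = 3,
    base_seed: int = 0,
    param_names=PERTURBABLE,
) -> list:
    """One-at-a-time sweep: every (parameter, factor, glucose) cell.

    ``sim(params, glucose0, seed) -> Endpoints`` is the engine (full
    simulator or surrogate).  One baseline mean is computed per glucose
    level and shared by all parameters.  Engine failures are recorded on
    the affected rows, never silently dropped.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    factors = tuple(factors)
    if any(f == 1 for f in factors):
        raise ValueError("factor 1 carries no perturbation; exclude it")
    baselines = {
        g: _mean_endpoints(sim, params, g, replicates, base_seed)
        for g in glucose_levels
    }
    records = []
    for name in param_names:
        for b in factors:
            perturbed = params.perturbed(name, b)
            for g in glucose_levels:
                rec = SensitivityRecord(
                    param=name, factor=b, glucose0=g,
                    M_time=np.nan, M_total=np.nan, M_mig=np.nan, M_prolif=np.nan,
                )
                try:
                    m = _mean_endpoints(sim, perturbed, g, replicates, base_seed)
                    base = baselines[g]
                    rec.M_time, rec.M_total, rec.M_mig, rec.M_prolif = m
                    # endpoints with a zero baseline (e.g. no proliferating
                    # cells at all under starvation) have no defined relative
                    # change; they degrade to NaN without failing the record
                    S = [
                        sensitivity_coefficient(m[i], base[i], b)
                        if base[i] != 0 else np.nan
                        for i in range(4)
                    ]
                    rec.S_time, rec.S_total, rec.S_mig, rec.S_prolif = S
                    rec.dM_time = delta_M(m[0], base[0]) if base[0] else np.nan
                    rec.dM_total = delta_M(m[1], base[1]) if base[1] else np.nan
                except Exception as exc:  # noqa: BLE001 - flagged, not dropped
                    rec.error = f"{type(exc).__name__}: {exc}"
                records.append(rec)
    return records


def records_to_frame(records) -> pd.DataFrame:
    """Sweep records as a tidy table (one row per record)."""
    return pd.DataFrame([vars(r) for r in records])


def summarize_max(records) -> list:
    """Per parameter and endpoint, max |S| over factors and glucose levels,
    with the glucose level attaining the maximum."""
    if not records:
        raise ValueError("cannot summarize an empty record set")
    rows: dict = {}
    for rec in records:
        if rec.error is not None:
            continue
        row = rows.setdefault(rec.param, SummaryRow(param=rec.param))
        for e in ENDPOINTS:
            s = abs(getattr(rec, f"S_{e}"))
            if np.isfinite(s) and s > row.m.get(e, -np.inf):
                row.m[e] = s
                row.glucose[e] = rec.glucose0
    if not rows:
        raise ValueError("no valid records to summarize")
    return [rows[p] for p in sorted(rows)]


def summary_to_frame(rows) -> pd.DataFrame:
    """Summary rows as a table: param + (m_e, argmax glucose) per endpoint."""
    out = []
    for r in rows:
        d = {"param": r.param}
        for e in ENDPOINTS:
            d[f"m_{e}"] = r.m.get(e, np.nan)
            d[f"glucose_{e}"] = r.glucose.get(e, np.nan)
        out.append(d)
    return pd.DataFrame(out)


@dataclass(frozen=True)
class SelectionRule:
    """Threshold rule: endpoint change at one glucose level beyond a bound."""

    endpoint: str          # "time" or "total"
    glucose0: float
    threshold: float
    direction: str         # "above" or "below"

    def passes(self, value: float) -> bool:
        if not np.isfinite(value):
            return False
        return value > self.threshold if self.direction == "above" else value < self.threshold


#: Factor+ rule: expansion slowed more than tenfold at the lowest glucose.
PLUS_RULE = SelectionRule("time", 0.3, 9.0, "above")
#: Factor- rule: final cell count reduced by >80% at the highest glucose.
MINUS_RULE = SelectionRule("total", 4.5, -0.8, "below")


def select_groups(
    records, plus_rule: SelectionRule = PLUS_RULE, minus_rule: SelectionRule = MINUS_RULE
) -> FactorGroups:
    """Split the sweep into Factor+ and Factor- parameter-factor sets."""
    levels = {rec.glucose0 for rec in records}
    for rule in (plus_rule, minus_rule):
        if rule.glucose0 not in levels:
            raise ValueError(
                f"records contain no rows at {rule.glucose0} g/L required by the "
                f"{rule.endpoint} selection rule"
            )
    groups = FactorGroups()
    for rec in sorted(records, key=lambda r: (r.param, r.factor)):
        if rec.error is not None:
            continue
        if rec.glucose0 == plus_rule.glucose0 and plus_rule.passes(
            getattr(rec, f"dM_{plus_rule.endpoint}")
        ):
            groups.factor_plus.setdefault(rec.param, []).append(rec.factor)
        if rec.glucose0 == minus_rule.glucose0 and minus_rule.passes(
            getattr(rec, f"dM_{minus_rule.endpoint}")
        ):
            groups.factor_minus.setdefault(rec.param, []).append(rec.factor)
    return groups


def enumerate_pairs(groups: FactorGroups) -> list:
    """All (Factor+ scaling) x (Factor- scaling) combinations on distinct
    parameters, in lexicographic order.

    The same-parameter exclusion reflects that one parameter cannot carry
    two different scalings simultaneously.
    """
    pairs = []
    for p1 in sorted(groups.factor_plus):
        for f1 in sorted(groups.factor_plus[p1]):
            for p2 in sorted(groups.factor_minus):
                if p2 == p1:
                    continue
                for f2 in sorted(groups.factor_minus[p2]):
                    pairs.append(PairSpec(p1, f1, p2, f2))
    return pairs


def run_pairs(
    sim,
    params: ReactionParameters,
    pairs,
    glucose_levels=DEFAULT_GLUCOSE_LEVELS,
    replicates: int = 3,
    base_seed: int = 0,
) -> list:
    """Combined two-parameter perturbation runs, replicate-averaged dM per
    glucose level (baselines shared, same seeds as the one-at-a-time sweep)."""
    baselines = {
        g: _mean_endpoints(sim, params, g, replicates, base_seed)
        for g in glucose_levels
    }
    out = []
    for pair in pairs:
        perturbed = params.perturbed_many(
            [(pair.param1, pair.factor1), (pair.param2, pair.factor2)]
        )
        for g in glucose_levels:
            rec = PairRecord(pair=pair, glucose0=g, dM_time=np.nan, dM_total=np.nan)
            try:
                m = _mean_endpoints(sim, perturbed, g, replicates, base_seed)
                base = baselines[g]
                rec.dM_time = delta_M(m[0], base[0]) if base[0] else np.nan
                rec.dM_total = delta_M(m[1], base[1]) if base[1] else np.nan
            except Exception as exc:  # noqa: BLE001
                rec.error = f"{type(exc).__name__}: {exc}"
            out.append(rec)
    return out


def screen_pairs(pair_records, margin: float = 0.01, all_of=None) -> dict:
    """Beneficial pairs: slower expansion (dM_time > margin) together with a
    smaller tumour (dM_total < -margin).

    Returns ``{"per_level": {glucose: [PairSpec...]}, "all_levels":
    [PairSpec...]}`` where ``all_levels`` lists pairs passing at every
    glucose level in ``all_of`` (default: every level present).
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    per_level: dict = {}
    for rec in pair_records:
        if rec.error is not None:
            continue
        keep = (
            np.isfinite(rec.dM_time) and np.isfinite(rec.dM_total)
            and rec.dM_time > margin and rec.dM_total < -margin
        )
        if keep:
            per_level.setdefault(rec.glucose0, []).append(rec.pair)
    for g in per_level:
        per_level[g] = sorted(set(per_level[g]))
    levels = sorted(per_level) if all_of is None else list(all_of)
    if levels:
        common = set(per_level.get(levels[0], []))
        for g in levels[1:]:
            common &= set(per_level.get(g, []))
        all_levels = sorted(common)
    else:
        all_levels = []
    return {"per_level": per_level, "all_levels": all_levels}
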