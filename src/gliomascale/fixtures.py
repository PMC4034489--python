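"""Packaged machine-readable transcriptions of the published tables.

Four delimited text fixtures ship with the package:

* ``reaction_parameters.tsv`` -- the 34 baseline constants (31 perturbable
  reaction constants + the consumption triple r, C1, C2),
* ``factor_groups.tsv``       -- the Factor+/Factor- selection,
* ``beneficial_pairs.tsv``    -- the combined scalings that slow expansion
  while shrinking the tumour, per glucose level,
* ``max_sensitivity.tsv``     -- the per-parameter maximal |S| summary
  (reference transcription for plot comparison only; never a test oracle
  for simulated values, which are stochastic).

Loaders validate structure loudly: missing/extra parameter names, malformed
rows and out-of-design factors are errors, not warnings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .network import PERTURBABLE, ReactionParameters
from .sensitivity import DEFAULT_FACTORS, DEFAULT_GLUCOSE_LEVELS, FactorGroups, PairSpec

_PARAM_NAMES = tuple(f.name for f in __import__("dataclasses").fields(ReactionParameters))


def _read_fixture(name: str) -> pd.DataFrame:
    with resources.files("gliomascale.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t", comment="#", keep_default_na=False)


def fixture_text(name: str) -> str:
    """Raw fixture text (used by the checksum-pinning tests)."""
    return resources.files("gliomascale.data").joinpath(name).read_text()


def load_parameters() -> tuple[ReactionParameters, tuple]:
    """Baseline constants from the packaged table.

    Returns (parameters, perturbable names); errors list any missing or
    extra keys and any disagreement on which constants are perturbable.
    """
    df = _read_fixture("reaction_parameters.tsv")
    names = tuple(df["name"])
    missing = [n for n in _PARAM_NAMES if n not in names]
    extra = [n for n in names if n not in _PARAM_NAMES]
    if missing or extra:
        raise ValueError(
            f"parameter fixture mismatch: missing {missing or 'none'}, "
            f"extra {extra or 'none'}"
        )
    values = {row["name"]: float(row["value"]) for _, row in df.iterrows()}
    perturbable = tuple(df.loc[df["perturbable"] == 1, "name"])
    if set(perturbable) != set(PERTURBABLE):
        raise ValueError("perturbable flags disagree with the sweep design")
    return ReactionParameters(**values), perturbable


def _parse_factor_list(cell: str) -> list:
    if not str(cell).strip():
        return []
    return [float(tok) for tok in str(cell).split(";")]


def load_table2() -> FactorGroups:
    """The published Factor+/Factor- selection as a FactorGroups structure."""
    df = _read_fixture("factor_groups.tsv")
    groups = FactorGroups()
    design = set(DEFAULT_FACTORS)
    for idx, row in df.iterrows():
        param = row["param"]
        if param not in PERTURBABLE:
            raise ValueError(f"factor_groups row {idx}: unknown parameter {param!r}")
        plus = _parse_factor_list(row["factor_plus"])
        minus = _parse_factor_list(row.get("factor_minus", ""))
        if not plus and not minus:
            raise ValueError(f"factor_groups row {idx}: empty row for {param!r}")
        for f in plus + minus:
            if f not in design:
                raise ValueError(
                    f"factor_groups row {idx}: factor {f} outside the sweep design"
                )
        if plus:
            groups.factor_plus[param] = plus
        if minus:
            groups.factor_minus[param] = minus
    return groups


@dataclass
class Table3Fixture:
    """Beneficial combined scalings per glucose level."""

    rows: pd.DataFrame = field(repr=False)

    def partners(self, param1: str, factor1: float, glucose: float) -> set:
        sel = self.rows[
            (self.rows.param1 == param1)
            & (self.rows.factor1 == factor1)
            & (self.rows.glucose == glucose)
        ]
        return {(r.param2, r.factor2) for r in sel.itertuples()}

    def pairs_at(self, glucose: float) -> set:
        sel = self.rows[self.rows.glucose == glucose]
        return {
            PairSpec(r.param1, r.factor1, r.param2, r.factor2) for r in sel.itertuples()
        }

    def pairs_at_all_levels(self, levels=(1.125, 2.25, 4.5)) -> list:
        """Pairs beneficial at every glucose level in ``levels``."""
        common = None
        for g in levels:
            s = self.pairs_at(g)
            common = s if common is None else common & s
        return sorted(common or set())

    def scalings_with_min_partners(self, n_min: int = 5) -> list:
        """First-position scalings with at least ``n_min`` beneficial
        (partner, glucose level) combinations across all glucose levels."""
        counts: dict = {}
        for r in self.rows.itertuples():
            counts.setdefault((r.param1, r.factor1), []).append((r.param2, r.factor2))
        return sorted(k for k, v in counts.items() if len(v) >= n_min)


def load_table3() -> Table3Fixture:
    """The published beneficial-pair table."""
    df = _read_fixture("beneficial_pairs.tsv")
    levels = set(DEFAULT_GLUCOSE_LEVELS[1:])  # no beneficial pairs at 0.3
    for idx, row in df.iterrows():
        for col in ("param1", "param2"):
            if row[col] not in PERTURBABLE:
                raise ValueError(
                    f"beneficial_pairs row {idx}: unknown parameter {row[col]!r}"
                )
        if float(row["glucose"]) not in levels:
            raise ValueError(
                f"beneficial_pairs row {idx}: glucose {row['glucose']} outside "
                f"the medium/high level set"
            )
        if float(row["factor1"]) <= 0 or float(row["factor2"]) <= 0:
            raise ValueError(f"beneficial_pairs row {idx}: factors must be positive")
    df = df.astype(
        {"factor1": float, "glucose": float, "factor2": float}
    )
    return Table3Fixture(rows=df)


def load_max_sensitivity() -> pd.DataFrame:
    """Reference per-parameter maximal |S| table (plot comparison only)."""
    df = _read_fixture("max_sensitivity.tsv")
    if list(df["param"]) != list(PERTURBABLE):
        raise ValueError("max_sensitivity fixture must list all 31 parameters in order")
    return df
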