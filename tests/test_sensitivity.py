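"""Sensitivity pipeline: coefficient algebra, sweep mechanics, selection,
pairing and screening."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gliomascale.sensitivity import (
    DEFAULT_FACTORS,
    DEFAULT_GLUCOSE_LEVELS,
    FactorGroups,
    PairRecord,
    PairSpec,
    SensitivityRecord,
    delta_M,
    enumerate_pairs,
    run_lsa,
    screen_pairs,
    select_groups,
    sensitivity_coefficient,
    summarize_max,
)

positive = st.floats(1e-3, 1e6, allow_nan=False, allow_infinity=False)
factors_st = st.floats(1e-3, 1e3).filter(lambda b: abs(b - 1) > 1e-6)


class TestCoefficientAlgebra:
    @pytest.mark.parametrize(
        "m_pert, m_base, b, expected",
        [(100, 100, 1.5, 0.0), (150, 100, 1.5, 1.0), (50, 100, 0.5, 1.0)],
    )
    def test_direct_substitution(self, m_pert, m_base, b, expected):
        assert sensitivity_coefficient(m_pert, m_base, b) == pytest.approx(expected)

    def test_undefined_inputs_raise(self):
        with pytest.raises(ValueError):
            sensitivity_coefficient(10, 10, 1.0)
        with pytest.raises(ValueError):
            sensitivity_coefficient(10, 0, 2.0)
        with pytest.raises(ValueError):
            delta_M(10, 0)

    @given(m_pert=positive, m_base=positive, b=factors_st)
    @settings(max_examples=500)
    def test_closed_form_equals_quotient_of_relative_changes(self, m_pert, m_base, b):
        lhs = sensitivity_coefficient(m_pert, m_base, b)
        k = 0.37  # any baseline parameter value cancels
        rhs = ((m_pert - m_base) / m_base) / ((k * b - k) / k)
        assert lhs == pytest.approx(rhs, rel=1e-9)

    @given(m_base=positive, b=factors_st, shift=st.floats(0.01, 10))
    @settings(max_examples=500)
    def test_sign_rule(self, m_base, b, shift):
        # co-directed change of parameter and output -> positive coefficient
        m_up, m_down = m_base * (1 + shift), m_base / (1 + shift)
        if b > 1:
            assert sensitivity_coefficient(m_up, m_base, b) > 0
            assert sensitivity_coefficient(m_down, m_base, b) < 0
        else:
            assert sensitivity_coefficient(m_down, m_base, b) > 0
            assert sensitivity_coefficient(m_up, m_base, b) < 0

    @given(m_pert=positive, m_base=positive, d=st.floats(0.01, 0.98))
    @settings(max_examples=500)
    def test_antisymmetry_for_mirrored_factors(self, m_pert, m_base, d):
        # b1 - 1 = 1 - b2 with equal outputs flips only the sign
        s1 = sensitivity_coefficient(m_pert, m_base, 1 + d)
        s2 = sensitivity_coefficient(m_pert, m_base, 1 - d)
        assert s1 == pytest.approx(-s2, rel=1e-9)

    @given(m_base=positive, gain=st.floats(1.01, 100),
           b1=st.floats(1.01, 50), extra=st.floats(0.01, 50))
    @settings(max_examples=500)
    def test_magnitude_rule_for_increased_outputs(self, m_base, gain, b1, extra):
        # equal *increased* outputs: the smaller factor gets the larger S
        b2 = b1 + extra
        m_pert = m_base * gain
        assert sensitivity_coefficient(m_pert, m_base, b1) > sensitivity_coefficient(
            m_pert, m_base, b2
        )

    @pytest.mark.parametrize(
        "m_pert, m_base, expected",
        [(100, 100, 0.0), (50, 100, -0.5), (1000, 100, 9.0)],
    )
    def test_relative_change(self, m_pert, m_base, expected):
        assert delta_M(m_pert, m_base) == pytest.approx(expected)


def constant_sim(M=100.0):
    from gliomascale.driver import Endpoints

    def sim(params, glucose0, seed):
        return Endpoints(int(M), int(M), int(M // 2), int(M // 4), "boundary")

    return sim


class TestRunLsa:
    def test_cardinality_small_design(self, params):
        recs = run_lsa(constant_sim(), params, factors=(0.5, 2.0, 5.0),
                       glucose_levels=(0.3,), replicates=1, base_seed=0,
                       param_names=("k2", "k9"))
        assert len(recs) == 6

    def test_full_design_cardinality(self, params):
        recs = run_lsa(constant_sim(), params, replicates=1, base_seed=0)
        assert len(recs) == 31 * 20 * 4 == 2480

    def test_factor_one_rejected(self, params):
        with pytest.raises(ValueError):
            run_lsa(constant_sim(), params, factors=(1.0, 2.0), replicates=1)

    def test_constant_simulator_gives_zero_coefficients(self, params):
        recs = run_lsa(constant_sim(), params, factors=(0.5, 2.0),
                       glucose_levels=(0.3, 4.5), replicates=2,
                       param_names=("k2",))
        for r in recs:
            assert r.S_time == 0 and r.S_total == 0 and r.dM_time == 0

    def test_engine_failures_are_flagged_not_dropped(self, params):
        def flaky(p, glucose0, seed):
            if p.k2 != params.k2:
                raise RuntimeError("engine exploded")
            return constant_sim()(p, glucose0, seed)

        recs = run_lsa(flaky, params, factors=(2.0,), glucose_levels=(0.3,),
                       replicates=1, param_names=("k2", "k9"))
        assert len(recs) == 2
        flagged = [r for r in recs if r.error is not None]
        assert len(flagged) == 1 and flagged[0].param == "k2"


def make_record(param, factor, glucose0, **kw):
    base = dict(M_time=1, M_total=1, M_mig=0, M_prolif=0,
                S_time=0.0, S_total=0.0, S_mig=0.0, S_prolif=0.0,
                dM_time=0.0, dM_total=0.0)
    base.update(kw)
    return SensitivityRecord(param=param, factor=factor, glucose0=glucose0, **base)


class TestSummarize:
    def test_single_record_absolute_value(self):
        rows = summarize_max([make_record("k2", 2.0, 0.3, S_time=-3.0)])
        assert rows[0].m["time"] == 3.0 and rows[0].glucose["time"] == 0.3

    def test_maximum_and_argmax_glucose(self):
        recs = [
            make_record("k2", 2.0, 0.3, S_time=2.0),
            make_record("k2", 2.0, 4.5, S_time=-5.0),
        ]
        rows = summarize_max(recs)
        assert rows[0].m["time"] == 5.0 and rows[0].glucose["time"] == 4.5

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            summarize_max([])


class TestSelection:
    def test_thresholds_split_plus_and_minus(self):
        recs = [
            make_record("k2", 50.0, 0.3, dM_time=9.5),
            make_record("k2", 50.0, 4.5, dM_total=-0.85),
            make_record("k2", 0.5, 0.3, dM_time=3.0),
            make_record("k9", 0.01, 0.3, dM_time=12.0),
            make_record("k9", 0.01, 4.5, dM_total=-0.5),
        ]
        groups = select_groups(recs)
        assert groups.factor_plus == {"k2": [50.0], "k9": [0.01]}
        assert groups.factor_minus == {"k2": [50.0]}
        assert groups.params_with_both() == ["k2"]

    def test_all_zero_changes_give_empty_groups(self):
        recs = [make_record("k2", 2.0, g) for g in DEFAULT_GLUCOSE_LEVELS]
        groups = select_groups(recs)
        assert groups.factor_plus == {} and groups.factor_minus == {}

    def test_missing_required_level_rejected(self):
        with pytest.raises(ValueError):
            select_groups([make_record("k2", 2.0, 0.3)])


class TestPairs:
    def test_same_parameter_excluded(self):
        groups = FactorGroups(factor_plus={"k2": [2.0]}, factor_minus={"k2": [0.5]})
        assert enumerate_pairs(groups) == []

    def test_disjoint_parameters_cross_product(self):
        groups = FactorGroups(
            factor_plus={"k2": [2.0, 5.0]},
            factor_minus={"k9": [0.5, 0.1, 0.01]},
        )
        assert len(enumerate_pairs(groups)) == 6

    @given(
        st.dictionaries(
            st.sampled_from(["k1", "k2", "k4", "k9", "k10"]),
            st.lists(st.sampled_from(list(DEFAULT_FACTORS)), min_size=1,
                     max_size=4, unique=True),
            max_size=5,
        ),
        st.dictionaries(
            st.sampled_from(["k1", "k2", "k4", "k9", "k10"]),
            st.lists(st.sampled_from(list(DEFAULT_FACTORS)), min_size=1,
                     max_size=4, unique=True),
            max_size=5,
        ),
    )
    @settings(max_examples=200)
    def test_count_matches_brute_force(self, plus, minus):
        groups = FactorGroups(factor_plus=plus, factor_minus=minus)
        got = enumerate_pairs(groups)
        brute = [
            (p1, f1, p2, f2)
            for p1, fs1 in plus.items()
            for f1 in fs1
            for p2, fs2 in minus.items()
            for f2 in fs2
            if p1 != p2
        ]
        assert len(got) == len(brute)
        assert len(set(got)) == len(got)

    def test_pair_needs_distinct_parameters(self):
        with pytest.raises(ValueError):
            PairSpec("k2", 2.0, "k2", 0.5)


class TestScreen:
    def pair(self, p1="k2", f1=50.0, p2="k9", f2=100.0):
        return PairSpec(p1, f1, p2, f2)

    def test_margin_keeps_and_rejects(self):
        kept = PairRecord(self.pair(), 4.5, dM_time=0.02, dM_total=-0.02)
        tiny = PairRecord(self.pair(p2="k10"), 4.5, dM_time=0.005, dM_total=-0.5)
        out = screen_pairs([kept, tiny], margin=0.01)
        assert out["per_level"][4.5] == [kept.pair]

    def test_all_level_intersection(self):
        p1, p2 = self.pair(), self.pair(p2="k10", f2=0.01)
        recs = []
        for g in (1.125, 2.25, 4.5):
            recs.append(PairRecord(p1, g, 0.1, -0.1))
        recs.append(PairRecord(p2, 4.5, 0.1, -0.1))  # only one level
        out = screen_pairs(recs, margin=0.01, all_of=(1.125, 2.25, 4.5))
        assert out["all_levels"] == [p1]

    def test_negative_margin_rejected(self):
        with pytest.raises(ValueError):
            screen_pairs([], margin=-0.1)
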