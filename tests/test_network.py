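"""Molecular network: right-hand side structure, integration, steady states,
phenotype calibration."""

import dataclasses

import numpy as np
import pytest

from gliomascale.network import (
    N_SPECIES,
    PERTURBABLE,
    NetworkConstants,
    Phenotype,
    PhenotypeThresholds,
    ReactionParameters,
    calibrate_thresholds,
    decide_phenotype,
    integrate_cell,
    rhs,
    steady_state,
)

GLUCOSE_GRID = (0.3, 1.125, 2.25, 4.5)


def random_states(consts, n, seed=0):
    gen = np.random.default_rng(seed)
    bounds = np.where(np.isfinite(consts.pool_bounds()), consts.pool_bounds(), 50.0)
    return gen.uniform(0.0, 1.0, size=(n, N_SPECIES)) * bounds


class TestRhs:
    def test_zero_state_zero_glucose_only_constitutive_terms(self, params, consts):
        # two terms survive at the empty state: constitutive MO25
        # transcription (k4) and constitutive Rheb reactivation (k14*R_tot)
        dx = rhs(np.zeros(N_SPECIES), 0.0, params, consts)
        assert dx[1] == pytest.approx(params.k4)
        assert dx[7] == pytest.approx(params.k14 * consts.R_tot)
        others = np.delete(dx, [1, 7])
        assert np.all(others == 0.0)

    def test_saturated_ampk_without_drive_only_decays(self, params, consts):
        x = np.zeros(N_SPECIES)
        x[5] = consts.A_tot  # AMPK pool fully phosphorylated, no LKB1-STRAD
        dx = rhs(x, 0.0, params, consts)
        assert dx[5] <= 0.0

    def test_perturbing_binding_constant_touches_only_the_binding_reaction(
        self, params, consts
    ):
        # k2 drives miR-451:mRNA association; only x1, x2, x3 terms carry it
        doubled = params.perturbed("k2", 2.0)
        for x in random_states(consts, 100, seed=7):
            diff = rhs(x, 2.0, doubled, consts) - rhs(x, 2.0, params, consts)
            assert np.all(diff[3:] == 0.0)

    @pytest.mark.parametrize("name", PERTURBABLE)
    def test_every_perturbable_parameter_acts_somewhere(self, params, consts, name):
        scaled = params.perturbed(name, 3.0)
        moved = False
        for x in random_states(consts, 20, seed=11):
            if np.any(rhs(x, 1.7, scaled, consts) != rhs(x, 1.7, params, consts)):
                moved = True
                break
        assert moved, f"{name} has no effect on the right-hand side"

    def test_non_finite_state_rejected_with_species_name(self, params, consts):
        x = np.zeros(N_SPECIES)
        x[4] = np.nan
        with pytest.raises(ValueError, match="LKB1_STRAD"):
            rhs(x, 1.0, params, consts)

    def test_no_negative_outflow_at_depleted_species(self, params, consts):
        # at x_i = 0 every loss term (proportional to x_i) vanishes, so the
        # derivative cannot push the concentration negative
        gen = np.random.default_rng(42)
        states = random_states(consts, 1000, seed=3)
        for x in states:
            i = gen.integers(N_SPECIES)
            x[i] = 0.0
            dx = rhs(x, float(gen.uniform(0, 4.5)), params, consts)
            assert dx[i] >= -1e-12


class TestIntegrateCell:
    def test_single_active_constitutive_term_grows_linearly(self, params, consts):
        tiny = {f.name: 1e-300 for f in dataclasses.fields(ReactionParameters)
                if f.name not in ("k4", "C1", "C2", "k1_i", "k12_i", "k11_m1",
                                  "k11_m2", "k13_m1", "k13_m2", "k15_i",
                                  "k17_m1", "k17_m2", "k18_m", "r")}
        p = dataclasses.replace(params, **tiny)
        out = integrate_cell(np.zeros(N_SPECIES), 0.0, p, consts, dt_macro=50.0, n_sub=10)
        assert out[1] == pytest.approx(p.k4 * 50.0, rel=1e-12)
        assert np.allclose(np.delete(out, 1), 0.0, atol=1e-250)

    def test_richardson_convergence_at_baseline(self, params, consts):
        x0 = steady_state(2.25, params, consts, method="cascade")
        coarse = integrate_cell(x0, 4.5, params, consts, dt_macro=0.05, n_sub=2000)
        fine = integrate_cell(x0, 4.5, params, consts, dt_macro=0.05, n_sub=4000)
        rel = np.max(np.abs(coarse - fine) / (1.0 + np.abs(fine)))
        assert rel < 1e-6

    def test_long_integration_reaches_the_cascade_fixed_point(
        self, gentle_params, gentle_consts
    ):
        target = steady_state(2.25, gentle_params, gentle_consts, method="cascade")
        x = np.zeros(N_SPECIES)
        for _ in range(10):
            x = integrate_cell(x, 2.25, gentle_params, gentle_consts,
                               dt_macro=200.0, n_sub=4000)
        assert np.allclose(x, target, rtol=1e-5, atol=1e-8)

    def test_pool_bounds_hold_along_trajectories(self, gentle_params, gentle_consts):
        x = np.zeros(N_SPECIES)
        bounds = gentle_consts.pool_bounds()
        for _ in range(20):
            x = integrate_cell(x, 4.5, gentle_params, gentle_consts,
                               dt_macro=50.0, n_sub=500)
            assert np.all(x >= 0.0) and np.all(x <= bounds + 1e-12)

    def test_invalid_steps_rejected(self, params, consts):
        with pytest.raises(ValueError):
            integrate_cell(np.zeros(N_SPECIES), 1.0, params, consts, -1.0, 10)
        with pytest.raises(ValueError):
            integrate_cell(np.zeros(N_SPECIES), 1.0, params, consts, 1.0, 0)


class TestSteadyState:
    def test_no_glucose_means_no_mir451(self, params, consts):
        ss = steady_state(0.0, params, consts, method="cascade")
        assert ss[0] == 0.0

    def test_relaxation_and_cascade_agree(self, params, consts):
        for g in (0.3, 4.5):
            relax = steady_state(g, params, consts, method="relax")
            casc = steady_state(g, params, consts, method="cascade")
            # the scaffold assembly/disassembly fluxes are ~1e5 times the
            # MO25 turnover flux, so a residual-norm stopping rule leaves
            # x4 a few 1e-5 relative off the exact fixed point
            assert np.allclose(relax, casc, rtol=1e-3, atol=1e-6)

    def test_glucose_raises_mir451_and_flips_the_kinase_balance(self, params, consts):
        lo = steady_state(0.3, params, consts, method="cascade")
        hi = steady_state(4.5, params, consts, method="cascade")
        assert hi[0] > lo[0]          # miR-451 rises with glucose
        assert lo[5] > hi[5]          # AMPK active under starvation
        assert hi[8] > lo[8]          # mTORC1 active under plenty

    def test_switch_monotone_across_the_glucose_grid(self, params, consts):
        ss = [steady_state(g, params, consts, method="cascade") for g in GLUCOSE_GRID]
        x1 = [s[0] for s in ss]
        x6 = [s[5] for s in ss]
        assert all(a <= b for a, b in zip(x1, x1[1:]))
        assert all(a >= b for a, b in zip(x6, x6[1:]))

    def test_deterministic(self, params, consts):
        a = steady_state(1.125, params, consts, method="relax")
        b = steady_state(1.125, params, consts, method="relax")
        assert np.array_equal(a, b)

    def test_respects_pool_bounds(self, params, consts):
        for g in GLUCOSE_GRID:
            ss = steady_state(g, params, consts, method="cascade")
            assert np.all(ss >= 0.0)
            assert np.all(ss <= consts.pool_bounds() + 1e-9)


class TestPhenotype:
    def test_thresholds_are_midpoints_of_the_extreme_steady_states(self, params, consts):
        thr = calibrate_thresholds(params, consts)
        lo = steady_state(0.3, params, consts, method="cascade")
        hi = steady_state(4.5, params, consts, method="cascade")
        assert thr.theta_A == pytest.approx(0.5 * (lo[5] + hi[5]))
        assert thr.theta_M == pytest.approx(0.5 * (lo[8] + hi[8]))

    def test_calibration_order_invariant(self, params, consts):
        a = calibrate_thresholds(params, consts, 0.3, 4.5)
        b = calibrate_thresholds(params, consts, 4.5, 0.3)
        assert a == b

    def test_extreme_steady_states_classify_as_designed(self, params, consts):
        thr = calibrate_thresholds(params, consts)
        lo = steady_state(0.3, params, consts, method="cascade")
        hi = steady_state(4.5, params, consts, method="cascade")
        assert decide_phenotype(lo, thr) is Phenotype.MIGRATING
        assert decide_phenotype(hi, thr) is Phenotype.PROLIFERATING

    def test_degenerate_network_cannot_calibrate(self, params, consts):
        # with both glucose inputs switched off (miR-451 synthesis and the
        # direct AMPK inhibition), the extreme steady states coincide
        p = params.perturbed("k1", 1e-12).perturbed("k12", 1e-12)
        with pytest.raises(RuntimeError, match="degenerate"):
            calibrate_thresholds(p, consts)

    @pytest.mark.parametrize(
        "x6_mult, x9_mult, expected",
        [
            (1.0, 1.0, Phenotype.QUIESCENT),   # both exactly at threshold
            (2.0, 0.0, Phenotype.MIGRATING),
            (0.0, 2.0, Phenotype.PROLIFERATING),
            (2.0, 2.0, Phenotype.QUIESCENT),   # conflicting signals
            (0.5, 0.5, Phenotype.QUIESCENT),   # both low
        ],
    )
    def test_decision_rule(self, x6_mult, x9_mult, expected):
        thr = PhenotypeThresholds(theta_A=10.0, theta_M=100.0)
        x = np.zeros(N_SPECIES)
        x[5] = x6_mult * thr.theta_A
        x[8] = x9_mult * thr.theta_M
        assert decide_phenotype(x, thr) is expected


def test_parameter_perturbation_rules(params):
    assert params.perturbed("k2", 2.0).k2 == pytest.approx(2 * params.k2)
    with pytest.raises(KeyError):
        params.perturbed("r", 2.0)  # consumption triple is not perturbable
    with pytest.raises(ValueError):
        params.perturbed("k2", 0.0)


def test_consumption_weights_partition(params):
    assert params.C1 + params.C2 == pytest.approx(1.0, abs=1e-3)


def test_constants_must_be_positive():
    with pytest.raises(ValueError):
        NetworkConstants(A_tot=-1.0)
    with pytest.raises(ValueError):
        ReactionParameters(k4=0.0)
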