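"""Equilibrium relation, knees, region classification, knee placement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tonegap import (
    InputParams,
    ModelConfig,
    NoKneesError,
    Pathways,
    PopulationParams,
    classify_region,
    equilibrium_IT,
    find_equilibria,
    knee_IT,
    knee_x,
    solve_knee_placement,
)


class TestEquilibriumIT:
    def test_midpoint_value(self):
        pop = PopulationParams(a_E=5.9, m=3.6)
        # logit(0.5) = 0, so I_T(0.5) = m - a_E/2
        assert equilibrium_IT(0.5, 0.0, pop, InputParams()) == pytest.approx(
            3.6 - 5.9 / 2
        )

    def test_printed_params_miss_the_knee_slightly(self):
        # printed one-decimal roundings land near but not exactly on I_T = 1
        pop = PopulationParams(a_E=5.9, m=3.6)
        _, x_R = knee_x(5.9)
        val = equilibrium_IT(x_R, 0.0, pop, InputParams())
        assert val == pytest.approx(1.04, abs=0.02)
        assert val != pytest.approx(1.0, abs=1e-3)

    def test_exact_knee_placement_hits_target(self):
        a_E, m = solve_knee_placement(0.2, 1.0)
        pop = PopulationParams(a_E=a_E, m=m)
        _, x_R = knee_x(a_E)
        assert equilibrium_IT(x_R, 0.0, pop, InputParams()) == pytest.approx(1.0, abs=1e-9)

    def test_rejects_boundary_x(self):
        pop = PopulationParams(a_E=5.0, m=3.0)
        for x in (0.0, 1.0):
            with pytest.raises(ValueError):
                equilibrium_IT(x, 0.0, pop, InputParams())

    @given(st.floats(0.01, 0.99), st.floats(0, 10))
    @settings(max_examples=100, derandomize=True)
    def test_inverse_consistency(self, x, I_N):
        """f(a_E x + I_T(x, I_N) + alpha I_N - a_I I_N (1-x)) == x."""
        from tonegap import sigmoid

        pop = PopulationParams(a_E=5.9475, m=3.5737)
        inp = InputParams(alpha=0.168, a_I=1.124)
        it = equilibrium_IT(x, I_N, pop, inp)
        u = pop.a_E * x + it + inp.alpha * I_N - inp.a_I * I_N * (1 - x)
        assert float(sigmoid(u, pop)) == pytest.approx(x, abs=1e-10)


class TestKneeX:
    def test_degenerate_fold(self):
        assert knee_x(4.0) == (0.5, 0.5)

    def test_tone_only_values(self):
        x_L, x_R = knee_x(5.9)
        assert x_L == pytest.approx(0.7837, abs=2e-4)
        assert x_R == pytest.approx(0.2163, abs=2e-4)

    def test_noise_widens_the_fold(self):
        x_L, _ = knee_x(5.9, a_I=1.124, I_N=8.0)
        assert x_L == pytest.approx(0.928, abs=2e-3)

    def test_no_knees_below_gain_four(self):
        with pytest.raises(NoKneesError):
            knee_x(3.9)

    @given(st.floats(4.0, 50.0), st.floats(0, 5), st.floats(0, 10))
    @settings(max_examples=100, derandomize=True)
    def test_knee_rates_sum_to_one(self, a_E, a_I, I_N):
        x_L, x_R = knee_x(a_E, a_I, I_N)
        assert x_L + x_R == pytest.approx(1.0, abs=1e-12)
        assert x_R <= 0.5 <= x_L


class TestKneeIT:
    def test_model1_preset_knees(self, m1):
        knees = knee_IT(m1.population, m1.inputs)
        assert knees.IT_L == pytest.approx(0.2, abs=1e-9)
        assert knees.IT_R == pytest.approx(1.0, abs=1e-9)

    def test_model2_preset_knees(self, m2):
        knees = knee_IT(m2.population, m2.inputs, include_inhib=False)
        assert knees.IT_L == pytest.approx(-2.0, abs=1e-9)
        assert knees.IT_R == pytest.approx(2.0, abs=1e-9)

    def test_noise_shifts_knees_apart(self, m1):
        # strong gap noise (the continuity demonstration level) drags the
        # deactivation knee below zero while raising the activation knee
        base = knee_IT(m1.population, m1.inputs, I_N=0.0)
        noisy = knee_IT(m1.population, m1.inputs, I_N=8.0)
        assert noisy.IT_R > base.IT_R  # activation harder with noise
        assert noisy.IT_L < 0 < base.IT_L  # active state survives silence-level tones

    def test_hysteresis_ordering(self, m1, m2, m3):
        for cfg in (m1, m2, m3):
            knees = knee_IT(cfg.population, cfg.inputs, include_inhib=False)
            assert knees.IT_L < knees.IT_R


class TestClassifyRegion:
    @pytest.mark.parametrize(
        "a_E, m, label",
        [
            (5.9, 3.6, "IIIa"),
            (10.5, 5.2, "IV"),
            (12.7, 9.5, "IIIb"),
            (3.0, 2.0, "I"),
            (5.0, 11.0, "II"),
            (8.0, 1.0, "V"),
        ],
    )
    def test_examples(self, a_E, m, label):
        assert classify_region(a_E, m) == label


class TestSolveKneePlacement:
    @pytest.mark.parametrize(
        "targets, printed",
        [
            ((0.2, 1.0), (5.9, 3.6)),
            ((-2.0, 2.0), (10.5, 5.2)),
            ((0.2, 6.0), (12.7, 9.5)),
        ],
    )
    def test_printed_roundings(self, targets, printed):
        a_E, m = solve_knee_placement(*targets)
        assert round(a_E, 1) == printed[0]
        assert round(m, 1) == printed[1]
        assert a_E > 4

    def test_symmetric_targets_give_m_half_aE(self):
        a_E, m = solve_knee_placement(-2.0, 2.0)
        assert m == pytest.approx(a_E / 2, abs=1e-12)

    def test_rejects_unordered_targets(self):
        with pytest.raises(ValueError):
            solve_knee_placement(0.2, 0.2)

    @pytest.mark.parametrize("IT_L", [-3.0, -1.0, 0.5, 2.0])
    @pytest.mark.parametrize("span", [0.5, 2.0, 5.0])
    def test_round_trip(self, IT_L, span):
        IT_R = IT_L + span
        a_E, m = solve_knee_placement(IT_L, IT_R)
        pop = PopulationParams(a_E=a_E, m=m)
        knees = knee_IT(pop, InputParams())
        assert knees.IT_L == pytest.approx(IT_L, abs=1e-8)
        assert knees.IT_R == pytest.approx(IT_R, abs=1e-8)


class TestFindEquilibria:
    def test_model2_rest_is_bistable(self, m2):
        fps = find_equilibria(m2)
        assert [fp.stability for fp in fps] == ["stable", "unstable", "stable"]
        assert fps[0].x < fps[1].x < fps[2].x

    def test_model1_strong_tone_single_active_state(self, m1):
        fps = find_equilibria(m1, tone_on=True, I_T=1.5)
        assert len(fps) == 1
        assert fps[0].stability == "stable"
        assert fps[0].x > 0.8

    def test_model1_rest_single_inactive_state(self, m1):
        fps = find_equilibria(m1)
        assert len(fps) == 1
        assert fps[0].x < 0.1

    def test_symmetry_oracle(self, m2):
        """m = a_E/2 without sustained inputs: fixed points mirror x -> 1-x."""
        x_I, x_S, x_A = (fp.x for fp in find_equilibria(m2))
        assert x_S == pytest.approx(0.5, abs=1e-9)
        assert x_I + x_A == pytest.approx(1.0, abs=1e-9)

    def test_matches_closed_form_crossings(self, m1):
        """Fixed points agree with crossings of the equilibrium relation."""
        pop, inp = m1.population, m1.inputs
        I_T = 0.6  # inside the bistable window (0.2, 1.0)
        fps = find_equilibria(m1, tone_on=True, I_T=I_T)
        assert len(fps) == 3
        for fp in fps:
            assert equilibrium_IT(fp.x, 0.0, pop, inp) == pytest.approx(I_T, abs=1e-8)

    def test_deep_inactive_root_found_under_strong_inhibition(self, m3):
        """Strong noise pins x_I extremely close to 0; the search still finds it."""
        fps = find_equilibria(m3, tone_on=True, noise_on=True, I_T=2.0, I_N=1.5)
        assert len(fps) == 3
        assert fps[0].x < 1e-5
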