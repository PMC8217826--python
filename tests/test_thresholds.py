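"""Masking/continuity threshold curves, feasibility checks, parameter sweeps."""

import numpy as np
import pytest

from tonegap import (
    continuity_threshold,
    feasibility_report,
    knee_x,
    masking_threshold,
    model1_masking_slope_approx,
    saddle_and_neighbors,
    sweep_aI_alpha,
    sweep_gamma_off,
    threshold_curve,
)


class TestMasking:
    def test_model2_closed_form(self, m2):
        assert masking_threshold(m2, 3.0) == pytest.approx(3.0)
        assert masking_threshold(m2, 1.0 + 1e-9) == pytest.approx(0.0, abs=1e-8)

    def test_model1_weak_noise_masks_moderate_tone(self, m1):
        # I_N = 1 already masks a 1.5 tone (the reference demonstration level)
        assert masking_threshold(m1, 1.5) < 1.0

    def test_rejects_subthreshold_tone(self, m1):
        with pytest.raises(ValueError):
            masking_threshold(m1, 0.9)

    def test_monotone_in_tone_level(self, m1, m2, m3):
        for cfg in (m1, m2, m3):
            vals = [masking_threshold(cfg, it) for it in (1.5, 2.0, 3.0, 4.0, 5.0)]
            assert all(v is not None for v in vals)
            assert all(b >= a - 1e-9 for a, b in zip(vals, vals[1:]))


class TestContinuity:
    def test_model1_constant_in_tone_level(self, m1):
        vals = {continuity_threshold(m1, it) for it in (1.5, 2.0, 3.0, 5.0)}
        assert len(vals) == 1  # the defining equation contains no I_T
        (v,) = vals
        assert v <= 8.0  # the demonstration noise level lies above threshold

    def test_model2_equals_masking_under_symmetry(self, m2):
        for it in (1.5, 2.0, 3.0, 4.0, 5.0):
            assert continuity_threshold(m2, it) == pytest.approx(
                masking_threshold(m2, it), abs=1e-9
            )

    def test_model3_exceeds_saddle_preservation_level(self, m3):
        """Gap noise must first restore the active state before the offset
        comparison matters."""
        c = continuity_threshold(m3, 2.0)
        # find the noise level at which the gap system becomes bistable
        from tonegap.phase_plane import MonostableError

        def bistable(I_N):
            try:
                saddle_and_neighbors(m3, noise_on=True, I_N=I_N)
                return True
            except MonostableError:
                return False

        lo, hi = 0.0, 5.0
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            lo, hi = (lo, mid) if bistable(mid) else (mid, hi)
        assert c > hi

    def test_model3_continuity_above_masking(self, m3):
        for it in (1.5, 2.0, 3.0):
            assert continuity_threshold(m3, it) > masking_threshold(m3, it)


class TestSlopeApprox:
    def test_value(self):
        _, x_R0 = knee_x(5.9475)
        s = model1_masking_slope_approx(1.124, 0.168, x_R0)
        assert s == pytest.approx(1.40, abs=0.01)

    def test_infeasible_raises(self):
        with pytest.raises(ValueError):
            model1_masking_slope_approx(1.124, 2.0, 0.2163)

    def test_secant_of_numeric_curve_within_ten_percent(self, m1):
        _, x_R0 = knee_x(m1.population.a_E)
        approx = model1_masking_slope_approx(
            m1.inputs.a_I, m1.inputs.alpha, x_R0
        )
        m2v, m4v = masking_threshold(m1, 2.0), masking_threshold(m1, 4.0)
        secant = (m4v - m2v) / 2.0
        # the approximation freezes x_R at its no-noise value; the exact
        # curve is slightly shallower over [2, 4]
        assert secant == pytest.approx(approx, rel=0.15)


class TestFeasibilityReport:
    def test_model_presets_pass(self, m1, m2):
        for cfg in (m1, m2):
            rep = feasibility_report(cfg)
            assert rep["all_passed"], rep

    def test_alpha_violation_detected(self, m1):
        from dataclasses import replace

        bad = m1.with_(inputs=replace(m1.inputs, alpha=2.0))
        rep = feasibility_report(bad, tone_grid=[5.0])
        assert not rep["alpha_constraint"]["passed"]

    def test_gamma_ordering_flagged_for_bistable_rest(self, m2):
        from dataclasses import replace

        bad = m2.with_(inputs=replace(m2.inputs, gamma_off=m2.inputs.gamma_on / 2))
        rep = feasibility_report(bad, tone_grid=[3.0])
        assert rep["gamma_off_at_least_gamma_on"]["applies"]
        assert not rep["gamma_off_at_least_gamma_on"]["passed"]


class TestSweeps:
    def test_aI_alpha_reference_cell(self, m1):
        df = sweep_aI_alpha(m1, [1.124], [0.168])
        row = df.iloc[0]
        assert row.feasible
        assert row.C_at_IT_max >= row.M_at_IT_max

    def test_masking_decreases_with_inhibition(self, m1):
        df = sweep_aI_alpha(m1, [1.0, 1.5, 2.0], [0.168])
        m = df.sort_values("a_I").M_at_IT_max.to_numpy()
        assert np.all(np.diff(m) < 0)

    def test_infeasible_above_alpha_bound(self, m1):
        _, x_R0 = knee_x(m1.population.a_E)
        alpha_bad = m1.inputs.a_I * (1 - x_R0) + 0.1
        df = sweep_aI_alpha(m1, [m1.inputs.a_I], [alpha_bad])
        assert not df.iloc[0].feasible

    def test_gamma_off_family(self, m3):
        # tone levels kept moderate so every cell stays below the noise cap
        # (stronger tones at gamma_off = 2 push the threshold above I_N_max,
        # which the sweep reports as absent)
        tone_grid = [1.5, 2.0, 2.5]
        df = sweep_gamma_off(m3, [0.2, 0.88, 2.0], tone_grid)
        piv = df.pivot(index="I_T", columns="gamma_off", values="C")
        assert piv.notna().all().all()
        # pointwise monotone in gamma_off
        assert (piv[0.88] >= piv[0.2] - 1e-9).all()
        assert (piv[2.0] >= piv[0.88] - 1e-9).all()
        # small gamma_off approaches the flat hysteresis limit
        assert piv[0.2].max() - piv[0.2].min() < piv[2.0].max() - piv[2.0].min()

    def test_gamma_off_sweep_contains_preset_curve(self, m3):
        df = sweep_gamma_off(m3, [0.88], [2.0])
        assert df.iloc[0].C == pytest.approx(continuity_threshold(m3, 2.0), abs=1e-9)


class TestThresholdCurve:
    def test_masking_curve_shape(self, m2):
        curve = threshold_curve(m2, "masking", tone_grid=np.linspace(1.1, 5, 9))
        df = curve.to_frame()
        assert (df.I_N_threshold.diff().dropna() >= 0).all()
        beta = m2.inputs.beta
        np.testing.assert_allclose(
            df.I_N_threshold, (df.I_T - 1) / beta, rtol=1e-9
        )

    def test_bisection_method_tagged(self, m2):
        curve = threshold_curve(
            m2, "masking", tone_grid=[3.0], method="bisection", dt=5e-3
        )
        assert curve.method == "bisection"
        assert curve.noise_thresholds[0] == pytest.approx(3.0, rel=0.02)
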