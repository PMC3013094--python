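"""Quadratic VO2/COT fitting, SMR extrapolation and the U_opt vertex."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from zfswim.errors import InvalidConditionError, NoMinimumError, UnderdeterminedError
from zfswim.metabolic_model import (
    COTCurve,
    MetabolicPoint,
    analyze_fish,
    cot_from_vo2,
    find_uopt,
    fit_cot_curve,
    fit_vo2_curve,
    summarize_group,
)
from zfswim.swim_performance import FishRecord
from zfswim.synthetic import SyntheticTruth, simulate_metabolic_points, simulate_o2_trace
from zfswim.respirometry import TunnelSpec, mo2_from_trace

# the fitted group metabolic curve: VO2 = SMR + a U² + b U on the %U_crit axis
GROUP_SMR, GROUP_A, GROUP_B = 43.79, 0.0081, -0.4353
# the fitted group cost-of-transport curve COT = a2 U² + b2 U + c2
GROUP_COT = (0.0104, -1.6239, 88.767)


def _points(smr, a, b, speeds=(25.0, 50.0, 75.0, 100.0)):
    return [MetabolicPoint(u, smr + a * u**2 + b * u) for u in speeds]


class TestVO2Fit:
    def test_exact_coefficient_recovery(self):
        curve = fit_vo2_curve(_points(GROUP_SMR, GROUP_A, GROUP_B))
        assert curve.smr == pytest.approx(GROUP_SMR, rel=1e-12)
        assert curve.a == pytest.approx(GROUP_A, rel=1e-9)
        assert curve.b == pytest.approx(GROUP_B, rel=1e-9)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_points_give_flat_curve(self):
        curve = fit_vo2_curve([MetabolicPoint(u, 50.0) for u in (25, 50, 75, 100)])
        assert curve.smr == pytest.approx(50.0, abs=1e-9)
        assert curve.a == pytest.approx(0.0, abs=1e-12)
        assert curve.b == pytest.approx(0.0, abs=1e-10)

    def test_three_points_interpolated_exactly(self):
        curve = fit_vo2_curve(_points(40.0, 0.01, -0.5, speeds=(20.0, 55.0, 90.0)))
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_underdetermined_raises(self):
        with pytest.raises(UnderdeterminedError):
            fit_vo2_curve(_points(40.0, 0.01, -0.5, speeds=(25.0, 50.0)))


class TestCot:
    def test_unit_arithmetic(self):
        # 36 µmol/g/h at 1 cm/s (= 36 m/h) is exactly 1 µmol/g/m
        assert cot_from_vo2(36.0, 1.0) == pytest.approx(1.0)
        assert cot_from_vo2(54.6, 39.6) == pytest.approx(54.6 / (39.6 * 36.0), rel=1e-12)

    def test_linear_in_mo2_decreasing_in_speed(self):
        assert cot_from_vo2(72.0, 10.0) == pytest.approx(2 * cot_from_vo2(36.0, 10.0))
        assert cot_from_vo2(36.0, 20.0) < cot_from_vo2(36.0, 10.0)

    def test_zero_speed_diverges(self):
        with pytest.raises(InvalidConditionError):
            cot_from_vo2(36.0, 0.0)

    def test_exact_curve_recovery(self):
        a2, b2, c2 = GROUP_COT
        speeds = np.array([25.0, 50.0, 75.0, 100.0])
        curve = fit_cot_curve(speeds, a2 * speeds**2 + b2 * speeds + c2)
        assert (curve.a2, curve.b2, curve.c2) == pytest.approx((a2, b2, c2), rel=1e-9)

    def test_symmetric_points_vertex_at_centre(self):
        u0 = 60.0
        speeds = np.array([u0 - 20, u0 - 5, u0 + 5, u0 + 20])
        curve = fit_cot_curve(speeds, (speeds - u0) ** 2 + 3.0)
        uopt, cot_opt = find_uopt(curve)
        assert uopt == pytest.approx(u0, rel=1e-10)
        assert cot_opt == pytest.approx(3.0, rel=1e-9)


class TestFindUopt:
    @pytest.mark.parametrize(
        "coeffs, expected",
        [((1.0, 0.0, 5.0), (0.0, 5.0)), ((1.0, -4.0, 0.0), (2.0, -4.0))],
    )
    def test_vertex_arithmetic(self, coeffs, expected):
        assert find_uopt(COTCurve(*coeffs)) == pytest.approx(expected)

    def test_group_curve_vertex(self):
        uopt, cot_opt = find_uopt(COTCurve(*GROUP_COT))
        assert uopt == pytest.approx(78.07, abs=0.01)
        assert cot_opt == pytest.approx(25.38, abs=0.01)

    def test_downward_parabola_rejected(self):
        with pytest.raises(NoMinimumError):
            find_uopt(COTCurve(-0.5, 1.0, 10.0))

    @settings(derandomize=True, max_examples=50)
    @given(
        a2=st.floats(min_value=1e-3, max_value=1.0),
        b2=st.floats(min_value=-100.0, max_value=0.0),
        c2=st.floats(min_value=0.0, max_value=200.0),
    )
    def test_vertex_matches_grid_search_oracle(self, a2, b2, c2):
        curve = COTCurve(a2, b2, c2)
        uopt, _ = find_uopt(curve)
        grid = np.arange(0.0, 120.0, 1e-3)
        u_grid = grid[np.argmin(curve.predict(grid))]
        if 0.0 < uopt < 120.0:
            assert abs(uopt - u_grid) < 1e-2


class TestSummarizeGroup:
    def _result(self, uopt_ms):
        fish = FishRecord("f", standard_bl_cm=3.05, total_tl_cm=3.6, body_weight_g=0.43)
        truth = SyntheticTruth(trace_noise_sd_pct_as=0.0)
        pts = simulate_metabolic_points(truth)
        r = analyze_fish(fish, 0.548, pts)
        return r

    def test_two_values_hand_arithmetic(self):
        import dataclasses

        base = self._result(0.4)
        r1 = dataclasses.replace(base, smr=1.0)
        r2 = dataclasses.replace(base, smr=3.0)
        table = summarize_group([r1, r2])
        assert table.loc["smr", "mean"] == pytest.approx(2.0)
        assert table.loc["smr", "sem"] == pytest.approx(1.0)

    def test_identical_results_have_zero_sem(self):
        r = self._result(0.4)
        table = summarize_group([r] * 5)
        assert table["sem"].max() == pytest.approx(0.0, abs=1e-12)

    def test_monte_carlo_uopt_recovery(self):
        """Per-fish U_opt with noise SD 0.06 m/s averages back to truth."""
        import dataclasses

        rng = np.random.default_rng(21)
        base = self._result(0.4)
        true_uopt = 0.396
        results = [
            dataclasses.replace(base, uopt_ms=float(true_uopt + rng.normal(0, 0.06)))
            for _ in range(10)
        ]
        table = summarize_group(results)
        mean, sem = table.loc["uopt_ms", "mean"], table.loc["uopt_ms", "sem"]
        assert abs(mean - true_uopt) < 3 * sem


class TestPerFishAnalysis:
    def test_uopt_speed_representations_consistent(self, fish, noiseless_truth):
        pts = simulate_metabolic_points(noiseless_truth)
        r = analyze_fish(fish, noiseless_truth.true_ucrit_ms, pts)
        assert r.uopt_ms == pytest.approx(r.uopt_pct_ucrit / 100.0 * r.ucrit_ms, rel=1e-14)
        assert r.uopt_bl_s == pytest.approx(r.uopt_ms / (fish.standard_bl_cm / 100.0), rel=1e-14)

    def test_noiseless_end_to_end_curve_recovery(self, fish, noiseless_truth, tunnel):
        """Traces generated from a known (SMR, a, b) invert through the stack."""
        speeds = (25.0, 50.0, 75.0, 100.0)
        points = []
        for u in speeds:
            trace = simulate_o2_trace(noiseless_truth, fish, u, duration_s=1200.0, tunnel=tunnel)
            points.append(MetabolicPoint(u, mo2_from_trace(trace, tunnel, fish.body_weight_g)))
        curve = fit_vo2_curve(points)
        assert curve.smr == pytest.approx(noiseless_truth.smr, rel=1e-8)
        assert curve.a == pytest.approx(noiseless_truth.a, rel=1e-8)
        assert curve.b == pytest.approx(noiseless_truth.b, rel=1e-8)
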