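"""Oxygen solubility, decline fitting and MO2 arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from zfswim.errors import InsufficientDataError, InvalidConditionError, TraceFormatError
from zfswim.respirometry import (
    DeclineFit,
    OxygenTrace,
    TunnelSpec,
    concentration_to_percent_as,
    fit_decline,
    mo2,
    mo2_from_trace,
    o2_saturation_umol_l,
    percent_as_to_concentration,
)

# Benson & Krause freshwater saturation at 1 atm, frozen from the published
# USGS solubility tables (mg/L, converted at 31.9988 g/mol O2).
SOLUBILITY_REFERENCE_UMOL_L = {20.0: 9.092e3 / 31.9988, 25.0: 8.263e3 / 31.9988, 28.0: 7.827e3 / 31.9988}


@pytest.mark.parametrize("temp_c, expected", sorted(SOLUBILITY_REFERENCE_UMOL_L.items()))
def test_saturation_matches_published_tables(temp_c, expected):
    assert o2_saturation_umol_l(temp_c) == pytest.approx(expected, rel=2e-4)


def test_percent_as_conversion_is_linear_and_zero_at_zero(tunnel):
    full = percent_as_to_concentration(100.0, tunnel)
    assert full == pytest.approx(244.6, abs=0.5)  # ~245 µmol/L at 28 °C fresh water
    assert percent_as_to_concentration(0.0, tunnel) == 0.0
    assert percent_as_to_concentration(50.0, tunnel) == pytest.approx(full / 2, rel=1e-15)


def test_conversion_roundtrip_is_identity(tunnel):
    pct = np.linspace(0, 119, 40)
    back = concentration_to_percent_as(percent_as_to_concentration(pct, tunnel), tunnel)
    np.testing.assert_allclose(back, pct, rtol=1e-14)


def test_out_of_range_conditions_rejected():
    with pytest.raises(InvalidConditionError):
        o2_saturation_umol_l(45.0)
    with pytest.raises(InvalidConditionError):
        TunnelSpec(volume_l=1.8, temperature_c=-3.0)
    with pytest.raises(InvalidConditionError):
        TunnelSpec(volume_l=0.0)


def _linear_trace(slope_umol_l_h, tunnel, n=600, dt=2.0, start_pct=100.0):
    t = np.arange(n) * dt
    conc0 = percent_as_to_concentration(start_pct, tunnel)
    conc = conc0 + slope_umol_l_h * t / 3600.0
    return OxygenTrace("f01", t, concentration_to_percent_as(conc, tunnel))


class TestFitDecline:
    def test_exact_line_recovered(self, tunnel):
        fit = fit_decline(_linear_trace(-10.0, tunnel), tunnel)
        assert fit.slope_umol_l_h == pytest.approx(-10.0, rel=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_trace_has_zero_slope(self, tunnel):
        t = np.arange(100) * 2.0
        fit = fit_decline(OxygenTrace("f01", t, np.full(100, 90.0)), tunnel)
        assert fit.slope_umol_l_h == pytest.approx(0.0, abs=1e-9)

    def test_noisy_slope_recovered_and_matches_ols_oracle(self, tunnel):
        rng = np.random.default_rng(11)
        t = np.arange(600) * 2.0
        conc0 = percent_as_to_concentration(100.0, tunnel)
        conc = conc0 - 8.5 * t / 3600.0
        pct = concentration_to_percent_as(conc, tunnel) + rng.normal(0, 0.5, t.size)
        trace = OxygenTrace("f01", t, pct)
        fit = fit_decline(trace, tunnel)
        assert fit.slope_umol_l_h == pytest.approx(-8.5, abs=0.5)
        # independent OLS oracle on the same converted samples
        from scipy import stats as sps

        oracle = sps.linregress(t / 3600.0, percent_as_to_concentration(pct, tunnel))
        assert fit.slope_umol_l_h == pytest.approx(oracle.slope, rel=1e-9)

    def test_too_few_closed_samples_raise(self, tunnel):
        tr = OxygenTrace("f01", [0.0, 2.0, 4.0], [100, 99, 98], ["flush", "flush", "closed"])
        with pytest.raises(InsufficientDataError):
            fit_decline(tr, tunnel)

    def test_non_monotone_timestamps_rejected(self):
        with pytest.raises(TraceFormatError):
            OxygenTrace("f01", [0.0, 2.0, 1.0], [100, 99, 98])

    def test_flush_samples_excluded_from_fit(self, tunnel):
        base = _linear_trace(-10.0, tunnel, n=100)
        phase = np.array(["flush"] * 20 + ["closed"] * 80, dtype=object)
        pct = base.o2_pct_as.copy()
        pct[:20] = 100.0  # flat flush phase would wreck the slope if included
        trace = OxygenTrace("f01", base.time_s, pct, phase)
        fit = fit_decline(trace, tunnel)
        assert fit.n_points == 80
        assert fit.slope_umol_l_h == pytest.approx(-10.0, rel=1e-9)

    def test_low_r_squared_warns(self, tunnel):
        rng = np.random.default_rng(5)
        t = np.arange(50) * 2.0
        trace = OxygenTrace("f01", t, 90 + rng.normal(0, 3.0, 50).clip(-10, 10))
        with pytest.warns(UserWarning, match="r²"):
            fit_decline(trace, tunnel)


class TestMo2:
    def test_reference_arithmetic(self, tunnel):
        # 10 µmol/L/h decline in a 1.8 L tunnel for a 0.43 g fish
        fit = DeclineFit(-10.0, 240.0, 1.0, 600)
        assert mo2(fit, tunnel, 0.43) == pytest.approx(41.86, abs=0.01)

    def test_zero_slope_gives_zero(self, tunnel):
        assert mo2(DeclineFit(0.0, 240.0, 1.0, 10), tunnel, 0.43) == 0.0

    def test_proportional_to_volume_inverse_in_mass(self):
        fit = DeclineFit(-10.0, 240.0, 1.0, 10)
        small = mo2(fit, TunnelSpec(volume_l=1.8), 0.43)
        assert mo2(fit, TunnelSpec(volume_l=3.6), 0.43) == pytest.approx(2 * small)
        assert mo2(fit, TunnelSpec(volume_l=1.8), 0.86) == pytest.approx(small / 2)

    def test_positive_slope_warns_then_raises(self, tunnel):
        fit = DeclineFit(+2.0, 240.0, 1.0, 10)
        with pytest.warns(UserWarning), pytest.raises(InvalidConditionError):
            mo2(fit, tunnel, 0.43)
        with pytest.warns(UserWarning):
            assert mo2(fit, tunnel, 0.43, allow_increasing=True) < 0

    def test_blank_subtraction(self, tunnel):
        fit = DeclineFit(-10.0, 240.0, 1.0, 10)
        blank = DeclineFit(-1.0, 240.0, 1.0, 10)
        assert mo2(fit, tunnel, 0.43, blank=blank) == pytest.approx(9.0 * 1.8 / 0.43)


def test_mo2_invariant_to_time_shift(tunnel):
    trace = _linear_trace(-8.0, tunnel)
    a = mo2_from_trace(trace, tunnel, 0.43)
    b = mo2_from_trace(trace.shifted(1234.5), tunnel, 0.43)
    assert a == pytest.approx(b, rel=1e-9)


@settings(derandomize=True, max_examples=30)
@given(slope=st.floats(min_value=-30.0, max_value=-0.5), mass=st.floats(min_value=0.1, max_value=2.0))
def test_noiseless_pipeline_recovers_true_rate(slope, mass):
    """mo2 ∘ fit_decline inverts the linear-decline generator exactly."""
    tunnel = TunnelSpec(volume_l=1.8)
    trace = _linear_trace(slope, tunnel, n=200)
    expected = -slope * tunnel.volume_l / mass
    assert mo2_from_trace(trace, tunnel, mass) == pytest.approx(expected, rel=1e-10)
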