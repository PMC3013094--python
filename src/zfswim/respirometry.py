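"""Closed-phase respirometry: oxygen traces to mass-specific uptake rates.

A Blazka-style swim tunnel is sealed ("closed" phase) while a fish swims at a
fixed speed; dissolved oxygen, logged as percent air saturation (%AS), falls
linearly while the fish respires.  The rate of oxygen uptake is

    MO2 = |d[O2]/dt| * V / M       (µmol O2 g⁻¹ h⁻¹)

where d[O2]/dt is the slope of an ordinary-least-squares line through the
closed-phase concentration record (µmol L⁻¹ h⁻¹), V the tunnel water volume
(L) and M the fish body mass (g).  %AS readings are converted to absolute
concentration through the Benson & Krause (1984) oxygen-solubility relation
(the equation behind the USGS DOTABLES tables), parameterised by water
temperature, salinity and barometric pressure.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError, InvalidConditionError, TraceFormatError

__all__ = [
    "TunnelSpec",
    "OxygenTrace",
    "DeclineFit",
    "o2_saturation_umol_l",
    "percent_as_to_concentration",
    "concentration_to_percent_as",
    "fit_decline",
    "mo2",
    "mo2_from_trace",
]

#: molar mass of O2, mg per mmol
O2_MOLAR_MASS = 31.9988

#: one standard atmosphere in kPa
STANDARD_ATMOSPHERE_KPA = 101.325

PHASE_CLOSED = "closed"
PHASE_FLUSH = "flush"
PHASE_VOCABULARY = frozenset({PHASE_CLOSED, PHASE_FLUSH})


@dataclass(frozen=True)
class TunnelSpec:
    """Physical description of one swim-tunnel respirometer.

    Parameters
    ----------
    volume_l:
        Water volume of the sealed system in litres (1.8 L for the small
        individual tunnels, 127 L for the group tunnels).
    temperature_c, salinity, pressure_kpa:
        Water conditions used for the %AS -> µmol/L conversion.  Salinity is
        on the practical scale (0 for fresh water).
    flow_cal_slope, flow_cal_intercept:
        Linear calibration of the motor ammeter: water speed (cm/s) =
        slope * current (µA) + intercept.
    """

    volume_l: float
    temperature_c: float = 28.0
    salinity: float = 0.0
    pressure_kpa: float = STANDARD_ATMOSPHERE_KPA
    flow_cal_slope: float = 0.3257
    flow_cal_intercept: float = -1.238

    def __post_init__(self) -> None:
        if not self.volume_l > 0:
            raise InvalidConditionError(f"tunnel volume must be positive, got {self.volume_l}")
        if not 0.0 < self.temperature_c < 40.0:
            raise InvalidConditionError(
                f"temperature {self.temperature_c} °C outside the supported (0, 40) °C range"
            )
        if not self.pressure_kpa > 0:
            raise InvalidConditionError(f"pressure must be positive, got {self.pressure_kpa}")
        if self.salinity < 0:
            raise InvalidConditionError(f"salinity must be non-negative, got {self.salinity}")

    @property
    def saturation_umol_l(self) -> float:
        """Air-saturation O2 concentration (= 100 %AS) under these conditions."""
        return o2_saturation_umol_l(self.temperature_c, self.salinity, self.pressure_kpa)


def o2_saturation_umol_l(
    temperature_c: float,
    salinity: float = 0.0,
    pressure_kpa: float = STANDARD_ATMOSPHERE_KPA,
) -> float:
    """Oxygen solubility at equilibrium with moist air, in µmol O2 per litre.

    Benson & Krause (1984) fit as standardised by USGS, with the moist-air
    barometric pressure correction.  Valid for 0-40 °C and salinities on the
    practical scale.
    """
    if not 0.0 < temperature_c < 40.0:
        raise InvalidConditionError(f"temperature {temperature_c} °C outside (0, 40)")
    if pressure_kpa <= 0:
        raise InvalidConditionError("pressure must be positive")
    t_k = temperature_c + 273.15
    ln_c = (
        -139.34411
        + 1.575701e5 / t_k
        - 6.642308e7 / t_k**2
        + 1.2438e10 / t_k**3
        - 8.621949e11 / t_k**4
    )
    ln_c -= salinity * (0.017674 - 10.754 / t_k + 2140.7 / t_k**2)
    c_mg_l = math.exp(ln_c)  # mg/L at 1 atm moist air

    p_atm = pressure_kpa / STANDARD_ATMOSPHERE_KPA
    ln_pwv = 11.8571 - 3840.70 / t_k - 216961.0 / t_k**2
    pwv = math.exp(ln_pwv)  # water vapour pressure, atm
    theta = 0.000975 - 1.426e-5 * temperature_c + 6.436e-8 * temperature_c**2
    pressure_factor = (
        p_atm * (1.0 - pwv / p_atm) * (1.0 - theta * p_atm) / ((1.0 - pwv) * (1.0 - theta))
    )
    return c_mg_l * pressure_factor / O2_MOLAR_MASS * 1000.0


def percent_as_to_concentration(pct_as, spec: TunnelSpec):
    """Convert oxygen in % air saturation to µmol O2 L⁻¹ (scalar or array)."""
    pct = np.asarray(pct_as, dtype=float)
    if np.any(pct < 0):
        raise InvalidConditionError("%AS values must be non-negative")
    out = pct / 100.0 * spec.saturation_umol_l
    return float(out) if np.isscalar(pct_as) else out


def concentration_to_percent_as(conc_umol_l, spec: TunnelSpec):
    """Inverse of :func:`percent_as_to_concentration`."""
    conc = np.asarray(conc_umol_l, dtype=float)
    out = conc / spec.saturation_umol_l * 100.0
    return float(out) if np.isscalar(conc_umol_l) else out


@dataclass
class OxygenTrace:
    """Time-stamped oxygen record for one fish at one speed step."""

    fish_id: str
    time_s: np.ndarray
    o2_pct_as: np.ndarray
    phase: np.ndarray = field(default=None)  # type: ignore[assignment]
    speed_pct_ucrit: float | None = None
    speed_cm_s: float | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.o2_pct_as = np.asarray(self.o2_pct_as, dtype=float)
        if self.phase is None:
            self.phase = np.full(self.time_s.shape, PHASE_CLOSED, dtype=object)
        self.phase = np.asarray(self.phase, dtype=object)
        if not (self.time_s.shape == self.o2_pct_as.shape == self.phase.shape):
            raise TraceFormatError("time, oxygen and phase columns differ in length")
        if self.time_s.size >= 2 and not np.all(np.diff(self.time_s) > 0):
            raise TraceFormatError(f"timestamps not strictly increasing for fish {self.fish_id}")
        if np.any((self.o2_pct_as < 0) | (self.o2_pct_as > 120)):
            raise TraceFormatError("oxygen readings outside the plausible [0, 120] %AS range")
        bad = set(self.phase) - PHASE_VOCABULARY
        if bad:
            raise TraceFormatError(f"unknown phase flags {sorted(bad)}; expected closed|flush")

    @property
    def closed_mask(self) -> np.ndarray:
        return self.phase == PHASE_CLOSED

    @property
    def n_closed(self) -> int:
        return int(self.closed_mask.sum())

    def shifted(self, offset_s: float) -> "OxygenTrace":
        """Same trace with all timestamps moved by ``offset_s``."""
        return OxygenTrace(
            fish_id=self.fish_id,
            time_s=self.time_s + offset_s,
            o2_pct_as=self.o2_pct_as.copy(),
            phase=self.phase.copy(),
            speed_pct_ucrit=self.speed_pct_ucrit,
            speed_cm_s=self.speed_cm_s,
        )


@dataclass(frozen=True)
class DeclineFit:
    """OLS line through the closed-phase concentration record.

    ``slope_umol_l_h`` is signed: negative while the fish consumes oxygen.
    """

    slope_umol_l_h: float
    intercept_umol_l: float
    r_squared: float
    n_points: int


def fit_decline(
    trace: OxygenTrace,
    spec: TunnelSpec,
    *,
    trim_leading_s: float = 0.0,
    trim_trailing_s: float = 0.0,
    min_r_squared: float = 0.9,
    units: str = "pct_as",
) -> DeclineFit:
    """Fit the closed-phase oxygen decline by ordinary least squares.

    Time is taken in hours and oxygen in µmol L⁻¹ so the slope lands directly
    in µmol L⁻¹ h⁻¹.  ``trim_leading_s`` / ``trim_trailing_s`` drop samples at
    the ends of the closed phase (mixing artefacts); a fit with r² below
    ``min_r_squared`` triggers a warning but is still returned.

    ``units`` selects the input dialect: ``"pct_as"`` (canonical) or
    ``"umol_l"`` for traces already in absolute concentration.
    """
    if units not in ("pct_as", "umol_l"):
        raise InvalidConditionError(f"unknown oxygen units {units!r}")
    mask = trace.closed_mask
    if mask.sum() >= 1:
        t_closed = trace.time_s[mask]
        lo = t_closed[0] + trim_leading_s
        hi = t_closed[-1] - trim_trailing_s
        mask = mask & (trace.time_s >= lo) & (trace.time_s <= hi)
    if mask.sum() < 2:
        raise InsufficientDataError(
            f"need >= 2 closed-phase samples to fit a decline, have {int(mask.sum())}"
        )
    t_h = trace.time_s[mask] / 3600.0
    if units == "pct_as":
        conc = percent_as_to_concentration(trace.o2_pct_as[mask], spec)
    else:
        conc = trace.o2_pct_as[mask]

    slope, intercept = np.polyfit(t_h, conc, 1)
    resid = conc - (slope * t_h + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((conc - conc.mean()) ** 2))
    if ss_tot == 0.0:
        r_squared = 1.0 if ss_res <= 1e-20 else 0.0
    else:
        r_squared = max(0.0, 1.0 - ss_res / ss_tot)
    if r_squared < min_r_squared:
        warnings.warn(
            f"decline fit r²={r_squared:.3f} below QC threshold {min_r_squared} "
            f"for fish {trace.fish_id}",
            stacklevel=2,
        )
    return DeclineFit(
        slope_umol_l_h=float(slope),
        intercept_umol_l=float(intercept),
        r_squared=float(r_squared),
        n_points=int(mask.sum()),
    )


def mo2(
    fit: DeclineFit,
    spec: TunnelSpec,
    body_mass_g: float,
    *,
    blank: DeclineFit | None = None,
    allow_increasing: bool = False,
) -> float:
    """Mass-specific oxygen uptake, µmol O2 g⁻¹ h⁻¹.

    ``blank`` optionally subtracts a background (microbial) respiration slope
    measured on an empty tunnel; off unless provided.  An oxygen *increase*
    (net positive slope) indicates a measurement problem and raises unless
    ``allow_increasing`` is set, in which case the (negative) rate is
    returned with a warning.
    """
    if not body_mass_g > 0:
        raise InvalidConditionError(f"body mass must be positive, got {body_mass_g}")
    slope = fit.slope_umol_l_h - (blank.slope_umol_l_h if blank is not None else 0.0)
    if slope > 0:
        warnings.warn(
            f"oxygen concentration increasing (slope {slope:.3g} µmol/L/h); "
            "check electrode calibration or flush timing",
            stacklevel=2,
        )
        if not allow_increasing:
            raise InvalidConditionError("positive oxygen slope; pass allow_increasing=True to override")
    return -slope * spec.volume_l / body_mass_g


def mo2_from_trace(
    trace: OxygenTrace,
    spec: TunnelSpec,
    body_mass_g: float,
    **fit_kwargs,
) -> float:
    """Convenience composition of :func:`fit_decline` and :func:`mo2`."""
    return mo2(fit_decline(trace, spec, **fit_kwargs), spec, body_mass_g)
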