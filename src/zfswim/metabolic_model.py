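"""Quadratic metabolic-rate model, SMR extrapolation, cost of transport, U_opt.

Oxygen uptake against swimming speed is modelled as

    VO2(U) = SMR + a U² + b U

with the standard metabolic rate SMR obtained by extrapolating the fitted
parabola to zero speed.  Cost of transport is VO2 divided by speed; its own
quadratic fit COT(U) = a2 U² + b2 U + c2 has an interior minimum at the
vertex U_opt = −b2/(2 a2), the optimal (most economical) swimming speed, with
COT_opt the curve value there.

The default speed axis is percent of the fish's own U_crit; conversions to
absolute (m/s) and body-length-relative (BL/s) speeds always go through the
individual's U_crit and standard body length.

Two COT scales are reported side by side: the *curve scale* (VO2 divided by
speed on the chosen axis — the scale the group curve is printed on, and the
only input the vertex location needs, since rescaling COT by any constant
leaves U_opt unchanged) and strict µmol O2 g⁻¹ m⁻¹ (VO2 divided by metres
travelled per hour).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    InsufficientDataError,
    InvalidConditionError,
    NoMinimumError,
    UnderdeterminedError,
)
from .swim_performance import FishRecord, to_relative_speed

__all__ = [
    "MetabolicPoint",
    "VO2Curve",
    "COTCurve",
    "SwimFitnessResult",
    "fit_vo2_curve",
    "cot_from_vo2",
    "fit_cot_curve",
    "find_uopt",
    "analyze_fish",
    "summarize_group",
]

#: metres travelled per hour at 1 cm/s
M_PER_H_PER_CM_S = 36.0


@dataclass(frozen=True)
class MetabolicPoint:
    """One speed step: oxygen uptake at a known fraction of U_crit."""

    speed_pct_ucrit: float
    mo2: float  #: µmol O2 g⁻¹ h⁻¹
    speed_cm_s: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.speed_pct_ucrit <= 110:
            raise InvalidConditionError(
                f"speed {self.speed_pct_ucrit} %U_crit outside [0, 110]"
            )
        if not self.mo2 > 0:
            raise InvalidConditionError(f"MO2 must be positive, got {self.mo2}")


def _quadratic_r_squared(x: np.ndarray, y: np.ndarray, coeffs: np.ndarray) -> float:
    resid = y - np.polyval(coeffs, x)
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res <= 1e-18 else 0.0
    return max(0.0, 1.0 - ss_res / ss_tot)


@dataclass(frozen=True)
class VO2Curve:
    """Fitted VO2(U) = SMR + a U² + b U."""

    smr: float
    a: float
    b: float
    r_squared: float
    speed_axis: str = "pct_ucrit"

    def predict(self, u) -> np.ndarray | float:
        return self.smr + self.a * np.asarray(u, dtype=float) ** 2 + self.b * np.asarray(u, dtype=float)


@dataclass(frozen=True)
class COTCurve:
    """Fitted COT(U) = a2 U² + b2 U + c2."""

    a2: float
    b2: float
    c2: float
    speed_axis: str = "pct_ucrit"
    r_squared: float | None = None

    def predict(self, u) -> np.ndarray | float:
        u = np.asarray(u, dtype=float)
        return self.a2 * u**2 + self.b2 * u + self.c2


def _speeds_and_values(points: Iterable[MetabolicPoint]) -> tuple[np.ndarray, np.ndarray]:
    pts = list(points)
    speeds = np.array([p.speed_pct_ucrit for p in pts], dtype=float)
    values = np.array([p.mo2 for p in pts], dtype=float)
    return speeds, values


def fit_vo2_curve(points: Iterable[MetabolicPoint], speed_axis: str = "pct_ucrit") -> VO2Curve:
    """Least-squares quadratic through the (speed, VO2) steps, free intercept.

    The intercept is reported as the standard metabolic rate (extrapolation
    to zero swimming speed).
    """
    speeds, values = _speeds_and_values(points)
    if np.unique(speeds).size < 3:
        raise UnderdeterminedError(
            f"need >= 3 distinct speeds for a quadratic fit, have {np.unique(speeds).size}"
        )
    coeffs = np.polyfit(speeds, values, 2)
    return VO2Curve(
        smr=float(coeffs[2]),
        a=float(coeffs[0]),
        b=float(coeffs[1]),
        r_squared=_quadratic_r_squared(speeds, values, coeffs),
        speed_axis=speed_axis,
    )


def cot_from_vo2(mo2: float, speed: float, scale: str = "per_metre"):
    """Cost of transport: oxygen uptake per unit distance.

    ``scale="per_metre"`` expects ``speed`` in cm/s and returns strict
    µmol O2 g⁻¹ m⁻¹ (dividing by metres travelled per hour).
    ``scale="per_speed_unit"`` divides VO2 by the numeric speed on whatever
    axis it is given (the curve scale used for the group polynomial).
    """
    speed_arr = np.asarray(speed, dtype=float)
    if np.any(speed_arr <= 0):
        raise InvalidConditionError("COT undefined at zero or negative speed")
    if scale == "per_metre":
        out = np.asarray(mo2, dtype=float) / (speed_arr * M_PER_H_PER_CM_S)
    elif scale == "per_speed_unit":
        out = np.asarray(mo2, dtype=float) / speed_arr
    else:
        raise InvalidConditionError(f"unknown COT scale {scale!r}")
    return float(out) if out.ndim == 0 else out


def fit_cot_curve(
    speeds: Sequence[float],
    cot: Sequence[float],
    speed_axis: str = "pct_ucrit",
) -> COTCurve:
    """Least-squares quadratic COT(U) = a2 U² + b2 U + c2."""
    speeds = np.asarray(speeds, dtype=float)
    cot = np.asarray(cot, dtype=float)
    if np.unique(speeds).size < 3:
        raise UnderdeterminedError(
            f"need >= 3 distinct speeds for a quadratic fit, have {np.unique(speeds).size}"
        )
    coeffs = np.polyfit(speeds, cot, 2)
    return COTCurve(
        a2=float(coeffs[0]),
        b2=float(coeffs[1]),
        c2=float(coeffs[2]),
        speed_axis=speed_axis,
        r_squared=_quadratic_r_squared(speeds, cot, coeffs),
    )


def find_uopt(curve: COTCurve) -> tuple[float, float]:
    """Optimal swimming speed and COT there: the vertex of the parabola.

    The first derivative 2 a2 U + b2 vanishes at U_opt = −b2/(2 a2), the
    global minimum whenever a2 > 0.
    """
    if not curve.a2 > 0:
        raise NoMinimumError(
            f"COT parabola needs a2 > 0 for a minimum, got a2={curve.a2}"
        )
    uopt = -curve.b2 / (2.0 * curve.a2)
    return float(uopt), float(curve.predict(uopt))


@dataclass(frozen=True)
class SwimFitnessResult:
    """Per-fish summary of the swimming-economy analysis."""

    fish_id: str
    ucrit_ms: float
    ucrit_bl_s: float | None
    smr: float
    rmr: float | None
    vo2max: float
    uopt_pct_ucrit: float
    uopt_ms: float
    uopt_bl_s: float | None
    cot_opt_curve: float  #: vertex COT on the curve (VO2/%U_crit) scale
    cot_opt_umol_g_m: float  #: strict µmol O2 g⁻¹ m⁻¹ at U_opt
    vo2_r_squared: float
    cot_r_squared: float


def analyze_fish(
    fish: FishRecord,
    ucrit_ms: float,
    points: Sequence[MetabolicPoint],
    rmr: float | None = None,
) -> SwimFitnessResult:
    """Full per-fish economy analysis from measured (speed, VO2) steps.

    Fits the VO2 parabola (SMR = intercept), derives COT on the %U_crit axis,
    fits the COT parabola and locates its vertex.  VO2max is the measured
    uptake at the fastest step.  Speeds convert to m/s via the fish's U_crit
    and to BL/s via its standard body length (None if BL unrecorded).
    """
    vo2_curve = fit_vo2_curve(points)
    speeds, values = _speeds_and_values(points)
    moving = speeds > 0
    if moving.sum() < 3:
        raise UnderdeterminedError("need >= 3 non-zero speeds for the COT fit")
    cot_curve_scale = cot_from_vo2(values[moving], speeds[moving], scale="per_speed_unit")
    cot_curve = fit_cot_curve(speeds[moving], cot_curve_scale)
    uopt_pct, cot_opt_curve = find_uopt(cot_curve)

    uopt_ms = uopt_pct / 100.0 * ucrit_ms
    uopt_cm_s = uopt_ms * 100.0
    vo2_at_uopt = float(vo2_curve.predict(uopt_pct))
    cot_opt_strict = cot_from_vo2(vo2_at_uopt, uopt_cm_s, scale="per_metre")

    vo2max = float(values[np.argmax(speeds)])
    bl_known = fish.standard_bl_cm is not None
    return SwimFitnessResult(
        fish_id=fish.fish_id,
        ucrit_ms=float(ucrit_ms),
        ucrit_bl_s=to_relative_speed(ucrit_ms, fish) if bl_known else None,
        smr=vo2_curve.smr,
        rmr=rmr,
        vo2max=vo2max,
        uopt_pct_ucrit=float(uopt_pct),
        uopt_ms=float(uopt_ms),
        uopt_bl_s=to_relative_speed(uopt_ms, fish) if bl_known else None,
        cot_opt_curve=float(cot_opt_curve),
        cot_opt_umol_g_m=float(cot_opt_strict),
        vo2_r_squared=vo2_curve.r_squared,
        cot_r_squared=cot_curve.r_squared if cot_curve.r_squared is not None else float("nan"),
    )


def summarize_group(results: Sequence[SwimFitnessResult]) -> pd.DataFrame:
    """Mean ± standard error of every numeric field across fish.

    SEM is sample SD (n−1 denominator) over √n, the convention used for all
    reported group values.
    """
    if len(results) < 2:
        raise InsufficientDataError("need >= 2 fish for a group mean ± SEM")
    rows = {}
    for f in fields(SwimFitnessResult):
        if f.name == "fish_id":
            continue
        vals = np.array(
            [getattr(r, f.name) for r in results if getattr(r, f.name) is not None],
            dtype=float,
        )
        if vals.size < 2:
            continue
        rows[f.name] = {
            "mean": float(vals.mean()),
            "sem": float(vals.std(ddof=1) / np.sqrt(vals.size)),
            "n": int(vals.size),
        }
    return pd.DataFrame(rows).T[["mean", "sem", "n"]]
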