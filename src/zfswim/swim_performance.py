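"""Critical swimming speed and speed-representation conversions.

U_crit is estimated from a stepped-velocity trial by Brett's interpolation:
the fish swims at increasing speeds (increment ``u_ii``, interval ``t_ii``)
until it fatigues part-way (``t_i`` seconds) through an interval, giving

    U_crit = U_i + (T_i / T_ii) * U_ii

with U_i the highest speed held for a full interval.  Absolute speeds are
converted to standard body lengths per second (BL s⁻¹) using each fish's own
standard body length, and raw ammeter currents are mapped to water speed
through the tunnel's linear motor calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import (
    InsufficientDataError,
    MeasurementMissingError,
    ProtocolError,
)
from .respirometry import TunnelSpec

__all__ = [
    "StepRecord",
    "FishRecord",
    "compute_ucrit",
    "ucrit_from_events",
    "to_relative_speed",
    "from_relative_speed",
    "current_to_speed",
]

GROUP_VOCABULARY = frozenset({"swimmer", "rester", "individual"})

#: protocol constants of the stepped trial: 0.05 m/s increments, 10 min intervals
DEFAULT_U_II_MS = 0.05
DEFAULT_T_II_S = 600.0


@dataclass(frozen=True)
class StepRecord:
    """One incremental-velocity trial ending in fatigue."""

    u_i_ms: float  #: highest velocity maintained for a whole interval, m/s
    u_ii_ms: float  #: velocity increment, m/s
    t_i_s: float  #: time swum into the fatigue interval, s
    t_ii_s: float  #: full interval length, s

    def __post_init__(self) -> None:
        if self.u_i_ms < 0:
            raise ProtocolError(f"u_i must be non-negative, got {self.u_i_ms}")
        if not self.u_ii_ms > 0:
            raise ProtocolError(f"velocity increment must be positive, got {self.u_ii_ms}")
        if not self.t_ii_s > 0:
            raise ProtocolError(f"interval length must be positive, got {self.t_ii_s}")
        if not 0 <= self.t_i_s <= self.t_ii_s:
            raise ProtocolError(
                f"fatigue time {self.t_i_s} s outside [0, {self.t_ii_s}] s interval"
            )


@dataclass(frozen=True)
class FishRecord:
    """Morphometrics and group assignment for one fish."""

    fish_id: str
    standard_bl_cm: float | None = None
    total_tl_cm: float | None = None
    body_weight_g: float | None = None
    group: str = "individual"

    def __post_init__(self) -> None:
        for name in ("standard_bl_cm", "total_tl_cm", "body_weight_g"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise MeasurementMissingError(f"{name} must be positive, got {v}")
        if self.standard_bl_cm is not None and self.total_tl_cm is not None:
            if not self.standard_bl_cm < self.total_tl_cm:
                raise MeasurementMissingError(
                    f"standard BL ({self.standard_bl_cm} cm) must be shorter than "
                    f"total TL ({self.total_tl_cm} cm)"
                )
        if self.group not in GROUP_VOCABULARY:
            raise MeasurementMissingError(
                f"group {self.group!r} not in {sorted(GROUP_VOCABULARY)}"
            )


def compute_ucrit(step: StepRecord) -> float:
    """Brett-interpolated critical swimming speed, m s⁻¹."""
    return step.u_i_ms + (step.t_i_s / step.t_ii_s) * step.u_ii_ms


def ucrit_from_events(events: Sequence[StepRecord], policy: str = "first") -> float:
    """Combine repeated fatigue events into a single U_crit.

    The stepped protocol is repeated until the fish fatigues three times;
    ``policy="first"`` (default) scores only the first event, ``"mean"``
    averages the per-event estimates.
    """
    if len(events) == 0:
        raise InsufficientDataError("no fatigue events recorded")
    if policy == "first":
        return compute_ucrit(events[0])
    if policy == "mean":
        return float(np.mean([compute_ucrit(e) for e in events]))
    raise ProtocolError(f"unknown repeated-fatigue policy {policy!r}")


def to_relative_speed(speed_ms: float, fish: FishRecord) -> float:
    """Absolute speed (m/s) to standard body lengths per second."""
    if fish.standard_bl_cm is None:
        raise MeasurementMissingError(f"fish {fish.fish_id} has no standard BL recorded")
    return speed_ms / (fish.standard_bl_cm / 100.0)


def from_relative_speed(speed_bl_s: float, fish: FishRecord) -> float:
    """Exact inverse of :func:`to_relative_speed`."""
    if fish.standard_bl_cm is None:
        raise MeasurementMissingError(f"fish {fish.fish_id} has no standard BL recorded")
    return speed_bl_s * (fish.standard_bl_cm / 100.0)


def current_to_speed(current_ua: float, spec: TunnelSpec) -> float:
    """Ammeter current (µA) to water speed (cm/s) via the motor calibration.

    Speeds implied below zero (currents under the calibration root) are
    clamped to 0 with a warning.
    """
    if current_ua < 0:
        raise ProtocolError(f"ammeter current must be non-negative, got {current_ua}")
    speed = spec.flow_cal_slope * current_ua + spec.flow_cal_intercept
    if speed < 0:
        warnings.warn(
            f"calibration maps {current_ua} µA to {speed:.3f} cm/s; clamping to 0",
            stacklevel=2,
        )
        return 0.0
    return float(speed)
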