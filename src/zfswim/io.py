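"""CSV dialects, run configuration and input validation.

All CSVs are UTF-8, comma-separated, '.' decimal, with a mandatory header
row; no sniffing.  Dialects:

- traces:  ``fish_id,time_s,o2_pct_as,phase,speed_pct_ucrit`` (phase closed|flush)
- trials:  ``fish_id,u_i_ms,u_ii_ms,t_i_s,t_ii_s,fatigue_index``
- cohort:  ``fish_id,group,standard_bl_cm,total_tl_cm,body_weight_g,stage``
- ct:      ``fish_id,group,gene,primer_set,rep1_ct,rep2_ct,rep3_ct,dilution``
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigError, TraceFormatError
from .qpcr import GENE_VOCABULARY
from .respirometry import PHASE_VOCABULARY, OxygenTrace, TunnelSpec
from .swim_performance import FishRecord, StepRecord

__all__ = [
    "TRACE_COLUMNS",
    "TRIAL_COLUMNS",
    "COHORT_COLUMNS",
    "CT_COLUMNS",
    "RunConfig",
    "read_trace_csv",
    "write_trace_csv",
    "read_trial_csv",
    "write_trial_csv",
    "read_cohort_csv",
    "read_ct_csv",
    "fish_records_from_cohort",
    "validate_inputs",
    "ValidationReport",
]

TRACE_COLUMNS = ["fish_id", "time_s", "o2_pct_as", "phase", "speed_pct_ucrit"]
TRIAL_COLUMNS = ["fish_id", "u_i_ms", "u_ii_ms", "t_i_s", "t_ii_s", "fatigue_index"]
COHORT_COLUMNS = ["fish_id", "group", "standard_bl_cm", "total_tl_cm", "body_weight_g", "stage"]
CT_COLUMNS = ["fish_id", "group", "gene", "primer_set", "rep1_ct", "rep2_ct", "rep3_ct", "dilution"]

STAGE_VOCABULARY = frozenset({"pre", "post"})


def _read_checked(path, required: list[str], kind: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TraceFormatError(f"{kind} CSV {path}: missing column(s) {missing}")
    return df


def read_trace_csv(path) -> list[OxygenTrace]:
    """Load oxygen traces, one per (fish, speed) block, in file order."""
    df = _read_checked(path, TRACE_COLUMNS, "trace")
    traces = []
    for (fish_id, speed), sub in df.groupby(["fish_id", "speed_pct_ucrit"], sort=False):
        traces.append(
            OxygenTrace(
                fish_id=str(fish_id),
                time_s=sub["time_s"].to_numpy(dtype=float),
                o2_pct_as=sub["o2_pct_as"].to_numpy(dtype=float),
                phase=sub["phase"].to_numpy(dtype=object),
                speed_pct_ucrit=float(speed),
            )
        )
    return traces


def write_trace_csv(traces: list[OxygenTrace], path) -> None:
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "fish_id": tr.fish_id,
                    "time_s": tr.time_s,
                    "o2_pct_as": tr.o2_pct_as,
                    "phase": tr.phase,
                    "speed_pct_ucrit": tr.speed_pct_ucrit,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trial_csv(path) -> dict[str, list[StepRecord]]:
    """Load fatigue events per fish, ordered by fatigue_index."""
    df = _read_checked(path, TRIAL_COLUMNS, "trial")
    out: dict[str, list[StepRecord]] = {}
    for fish_id, sub in df.groupby("fish_id", sort=False):
        sub = sub.sort_values("fatigue_index")
        out[str(fish_id)] = [
            StepRecord(
                u_i_ms=float(r.u_i_ms),
                u_ii_ms=float(r.u_ii_ms),
                t_i_s=float(r.t_i_s),
                t_ii_s=float(r.t_ii_s),
            )
            for r in sub.itertuples()
        ]
    return out


def write_trial_csv(events_by_fish: dict[str, list[StepRecord]], path) -> None:
    rows = []
    for fish_id, events in events_by_fish.items():
        for i, e in enumerate(events, start=1):
            rows.append(
                {
                    "fish_id": fish_id,
                    "u_i_ms": e.u_i_ms,
                    "u_ii_ms": e.u_ii_ms,
                    "t_i_s": e.t_i_s,
                    "t_ii_s": e.t_ii_s,
                    "fatigue_index": i,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = _read_checked(path, COHORT_COLUMNS, "cohort")
    bad_stage = set(df["stage"]) - STAGE_VOCABULARY
    if bad_stage:
        raise TraceFormatError(f"cohort CSV {path}: unknown stage value(s) {sorted(bad_stage)}")
    return df


def read_ct_csv(path) -> pd.DataFrame:
    return _read_checked(path, CT_COLUMNS, "ct")


def fish_records_from_cohort(cohort: pd.DataFrame, stage: str = "pre") -> dict[str, FishRecord]:
    """Build per-fish morphometric records from one stage of a cohort table."""
    out = {}
    sub = cohort[cohort["stage"] == stage]
    for r in sub.itertuples():
        out[str(r.fish_id)] = FishRecord(
            fish_id=str(r.fish_id),
            standard_bl_cm=float(r.standard_bl_cm) if pd.notna(r.standard_bl_cm) else None,
            total_tl_cm=float(r.total_tl_cm) if pd.notna(r.total_tl_cm) else None,
            body_weight_g=float(r.body_weight_g) if pd.notna(r.body_weight_g) else None,
            group=str(r.group),
        )
    return out


@dataclass
class RunConfig:
    """Paths, tunnel description and analysis options for a pipeline run."""

    out_dir: Path
    traces_csv: Path | None = None
    trials_csv: Path | None = None
    fish_csv: Path | None = None  #: cohort-dialect morphometrics of the economy fish
    cohort_csv: Path | None = None
    ct_csv: Path | None = None
    tunnel_volume_l: float = 1.8
    temperature_c: float = 28.0
    salinity: float = 0.0
    pressure_kpa: float = 101.325
    flow_cal_slope: float = 0.3257
    flow_cal_intercept: float = -1.238
    speed_axis: str = "pct_ucrit"
    min_r_squared: float = 0.9
    ct_sd_threshold: float = 0.5
    outlier_alpha: float = 0.05
    max_outlier_removals: int = 2
    ucrit_policy: str = "first"
    seed: int = 0

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        for name in ("traces_csv", "trials_csv", "fish_csv", "cohort_csv", "ct_csv"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, Path(v))
        if self.speed_axis not in ("pct_ucrit", "cm_s"):
            raise ConfigError(f"speed_axis must be pct_ucrit or cm_s, got {self.speed_axis!r}")
        if self.ucrit_policy not in ("first", "mean"):
            raise ConfigError(f"ucrit_policy must be first or mean, got {self.ucrit_policy!r}")

    @property
    def tunnel(self) -> TunnelSpec:
        return TunnelSpec(
            volume_l=self.tunnel_volume_l,
            temperature_c=self.temperature_c,
            salinity=self.salinity,
            pressure_kpa=self.pressure_kpa,
            flow_cal_slope=self.flow_cal_slope,
            flow_cal_intercept=self.flow_cal_intercept,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} must be a mapping")
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        try:
            cfg = cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
        base = Path(path).parent
        for name in ("traces_csv", "trials_csv", "fish_csv", "cohort_csv", "ct_csv"):
            v = getattr(cfg, name)
            if v is not None and not v.is_absolute():
                setattr(cfg, name, base / v)
        missing = [
            str(getattr(cfg, name))
            for name in ("traces_csv", "trials_csv", "fish_csv", "cohort_csv", "ct_csv")
            if getattr(cfg, name) is not None and not getattr(cfg, name).exists()
        ]
        if missing:
            raise ConfigError(f"input file(s) not found: {missing}")
        return cfg


@dataclass
class ValidationReport:
    issues: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def add(self, msg: str) -> None:
        self.issues.append(msg)


def validate_inputs(
    traces_csv=None,
    trials_csv=None,
    cohort_csv=None,
    ct_csv=None,
) -> ValidationReport:
    """Schema-check every provided CSV; report-only, never raises on content."""
    report = ValidationReport()

    def _frame(path, required, kind):
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # noqa: BLE001 - report, don't crash
            report.add(f"{kind} {path}: unreadable ({exc})")
            return None
        for col in required:
            if col not in df.columns:
                report.add(f"{kind} {path}: missing column {col!r}")
                return None
        return df

    if traces_csv is not None:
        df = _frame(traces_csv, TRACE_COLUMNS, "trace")
        if df is not None:
            bad = set(df["phase"]) - PHASE_VOCABULARY
            if bad:
                report.add(f"trace {traces_csv}: phase value(s) {sorted(bad)} outside closed|flush")
            if ((df["o2_pct_as"] < 0) | (df["o2_pct_as"] > 120)).any():
                report.add(f"trace {traces_csv}: oxygen readings outside [0, 120] %AS")
    if trials_csv is not None:
        df = _frame(trials_csv, TRIAL_COLUMNS, "trial")
        if df is not None:
            if (df["t_i_s"] > df["t_ii_s"]).any():
                report.add(f"trial {trials_csv}: fatigue time exceeds interval length")
            if (df["u_ii_ms"] <= 0).any():
                report.add(f"trial {trials_csv}: non-positive velocity increment")
    if cohort_csv is not None:
        df = _frame(cohort_csv, COHORT_COLUMNS, "cohort")
        if df is not None:
            bad = set(df["stage"]) - STAGE_VOCABULARY
            if bad:
                report.add(f"cohort {cohort_csv}: stage value(s) {sorted(bad)} outside pre|post")
    if ct_csv is not None:
        df = _frame(ct_csv, CT_COLUMNS, "ct")
        if df is not None:
            for col in ("rep1_ct", "rep2_ct", "rep3_ct"):
                if df[col].isna().any():
                    report.add(f"ct {ct_csv}: missing replicate value(s) in {col}")
            bad = set(df["gene"]) - GENE_VOCABULARY
            if bad:
                report.add(f"ct {ct_csv}: unknown gene symbol(s) {sorted(bad)}")
    return report
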