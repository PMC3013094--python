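"""Synthetic-data generators with known ground truth for every pipeline stage.

Each generator is a deterministic function of a :class:`SyntheticTruth` and
the seed it carries.  Per-fish random streams are derived by hashing the
fish id into the seed tree, so adding or removing a fish never perturbs the
data of any other fish.

Default truth constants are the headline study conditions: a quadratic
metabolic curve VO2(U) = 43.79 + 0.0081 U² − 0.4353 U on the %U_crit axis, a
true critical speed of 0.548 m/s, 0.05 m/s × 600 s stepped trials, 2-s
oxygen sampling in a 1.8 L tunnel at 28 °C, cohort growth effects of
+0.18 cm TL / +0.10 g BW for swimmers vs 0 cm / −0.07 g for resters, and a
fourteen-gene qPCR panel with stable housekeeping expression at Ct 18.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InvalidConditionError, ProtocolError
from .metabolic_model import MetabolicPoint
from .qpcr import GENE_VOCABULARY, HOUSEKEEPING_GENE, PRIMER_SETS
from .respirometry import (
    PHASE_CLOSED,
    PHASE_FLUSH,
    OxygenTrace,
    TunnelSpec,
    concentration_to_percent_as,
)
from .swim_performance import (
    DEFAULT_T_II_S,
    DEFAULT_U_II_MS,
    FishRecord,
    StepRecord,
)

__all__ = [
    "GroupGrowthTruth",
    "SyntheticTruth",
    "simulate_o2_trace",
    "simulate_ucrit_trial",
    "simulate_cohort",
    "simulate_ct_table",
    "simulate_metabolic_points",
    "fold_change_recovery",
]

#: printed group fold changes used as default generator truth; unlisted
#: panel genes default to no change (fc 1)
DEFAULT_FOLD_CHANGES: dict[str, float] = {
    "ghrb": 0.58,
    "igf1ra": 0.53,
    "stnnc": 3.47,
    "smyhc1": 3.60,
    "tnni2": 3.42,
    "myhz2": 7.92,
    "mstnb": 5.44,
}


@dataclass(frozen=True)
class GroupGrowthTruth:
    """Baseline and change distributions of one cohort group."""

    tl_mean_cm: float
    tl_sd_cm: float
    dtl_mean_cm: float
    dtl_sd_cm: float
    bw_mean_g: float
    bw_sd_g: float
    dbw_mean_g: float
    dbw_sd_g: float


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth parameter set for all generators."""

    # metabolic curve on the %U_crit axis, µmol O2 g⁻¹ h⁻¹
    smr: float = 43.79
    a: float = 0.0081
    b: float = -0.4353
    true_ucrit_ms: float = 0.548
    # oxygen-trace acquisition
    trace_noise_sd_pct_as: float = 0.5
    sample_interval_s: float = 2.0
    # individual-fish morphometrics for the economy experiment
    fish_bl_cm: float = 3.05
    fish_mass_g: float = 0.43
    # cohort growth (baseline SDs back-computed from reported SEMs at n≈80)
    swimmer_growth: GroupGrowthTruth = field(
        default_factory=lambda: GroupGrowthTruth(3.59, 0.18, 0.18, 0.05, 0.41, 0.09, 0.10, 0.03)
    )
    rester_growth: GroupGrowthTruth = field(
        default_factory=lambda: GroupGrowthTruth(3.60, 0.18, 0.0, 0.05, 0.42, 0.09, -0.07, 0.03)
    )
    bl_to_tl_ratio: float = 3.05 / 3.60  #: standard BL as a fraction of total TL
    # qPCR truth
    true_fold_changes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FOLD_CHANGES)
    )
    ct_noise_sd: float = 0.2
    housekeeping_ct: float = 18.0
    target_baseline_dct: float = 7.0  #: rester ΔCt (target − rps18) for every gene
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("trace_noise_sd_pct_as", "ct_noise_sd"):
            if getattr(self, name) < 0:
                raise InvalidConditionError(f"{name} must be >= 0")
        unknown = set(self.true_fold_changes) - (GENE_VOCABULARY - {HOUSEKEEPING_GENE})
        if unknown:
            raise InvalidConditionError(f"fold changes for unknown genes: {sorted(unknown)}")
        if any(fc <= 0 for fc in self.true_fold_changes.values()):
            raise InvalidConditionError("true fold changes must be positive")

    def vo2(self, speed_pct_ucrit) -> np.ndarray | float:
        """True metabolic rate at a speed in %U_crit."""
        u = np.asarray(speed_pct_ucrit, dtype=float)
        out = self.smr + self.a * u**2 + self.b * u
        return float(out) if out.ndim == 0 else out

    def with_seed(self, seed: int) -> "SyntheticTruth":
        return replace(self, seed=seed)

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        for key in ("swimmer_growth", "rester_growth"):
            d[key] = GroupGrowthTruth(**d[key])
        return cls(**d)


def _rng(truth: SyntheticTruth, *key: object) -> np.random.Generator:
    """Independent stream keyed by (root seed, stable hash of the key parts)."""
    spawn_key = tuple(zlib.crc32(str(k).encode("utf-8")) for k in key)
    return np.random.default_rng(np.random.SeedSequence(truth.seed, spawn_key=spawn_key))


def simulate_o2_trace(
    truth: SyntheticTruth,
    fish: FishRecord,
    speed_pct_ucrit: float,
    duration_s: float = 1200.0,
    tunnel: TunnelSpec | None = None,
    flush_s: float = 0.0,
) -> OxygenTrace:
    """Closed-phase oxygen trace with linear decline plus Gaussian sensor noise.

    Concentration starts at 100 %AS and falls at VO2(speed) × mass / volume
    µmol L⁻¹ h⁻¹.  An optional leading flush phase holds saturation.  Noise is
    i.i.d. on the %AS readings; the stream is keyed by (fish, speed).
    """
    if not duration_s > 2 * truth.sample_interval_s:
        raise ProtocolError("duration must cover more than two sampling intervals")
    if tunnel is None:
        tunnel = TunnelSpec(volume_l=1.8)
    mass = fish.body_weight_g if fish.body_weight_g is not None else truth.fish_mass_g
    rate_umol_l_h = truth.vo2(speed_pct_ucrit) * mass / tunnel.volume_l

    t = np.arange(0.0, flush_s + duration_s + 1e-9, truth.sample_interval_s)
    phase = np.where(t < flush_s, PHASE_FLUSH, PHASE_CLOSED).astype(object)
    closed_elapsed_h = np.clip(t - flush_s, 0.0, None) / 3600.0
    conc = tunnel.saturation_umol_l - rate_umol_l_h * closed_elapsed_h
    if np.any(conc < 0):
        warnings.warn(
            f"trace for fish {fish.fish_id} at {speed_pct_ucrit} %U_crit would go "
            "anoxic; oxygen truncated at 0",
            stacklevel=2,
        )
        conc = np.clip(conc, 0.0, None)
    pct = concentration_to_percent_as(conc, tunnel)
    if truth.trace_noise_sd_pct_as > 0:
        rng = _rng(truth, "trace", fish.fish_id, round(float(speed_pct_ucrit), 6))
        pct = pct + rng.normal(0.0, truth.trace_noise_sd_pct_as, pct.shape)
    pct = np.clip(pct, 0.0, 120.0)
    return OxygenTrace(
        fish_id=fish.fish_id,
        time_s=t,
        o2_pct_as=pct,
        phase=phase,
        speed_pct_ucrit=float(speed_pct_ucrit),
    )


def simulate_metabolic_points(
    truth: SyntheticTruth,
    speeds_pct_ucrit=(25.0, 50.0, 75.0, 100.0),
    noise_sd: float = 0.0,
    fish_id: str = "fish",
) -> list[MetabolicPoint]:
    """Direct (speed, VO2) points off the true curve, optional Gaussian noise."""
    rng = _rng(truth, "points", fish_id)
    pts = []
    for u in speeds_pct_ucrit:
        v = truth.vo2(u) + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        pts.append(MetabolicPoint(speed_pct_ucrit=float(u), mo2=float(v)))
    return pts


def simulate_ucrit_trial(
    truth: SyntheticTruth,
    fish: FishRecord | None = None,
    start_speed_ms: float = 0.05,
    u_ii_ms: float = DEFAULT_U_II_MS,
    t_ii_s: float = DEFAULT_T_II_S,
    n_events: int = 3,
    fatigue_jitter_sd_s: float = 0.0,
) -> list[StepRecord]:
    """Stepped-velocity trial(s) of a fish with a known true U_crit.

    The fish completes every interval whose speed does not exceed the true
    U_crit; in the first exceeding interval it fatigues at
    t_i = t_ii (U_crit − U_i)/u_ii, so Brett interpolation is exact in the
    noiseless case.  ``n_events`` repeated fatigue events are generated
    (protocol: repeat until the third fatigue); optional Gaussian jitter on
    the fatigue time is clipped into the interval.
    """
    ucrit = truth.true_ucrit_ms
    if start_speed_ms >= ucrit:
        raise ProtocolError(
            f"start speed {start_speed_ms} m/s must lie below the true U_crit {ucrit} m/s"
        )
    fish_id = fish.fish_id if fish is not None else "fish"
    rng = _rng(truth, "trial", fish_id)
    # last fully-completed speed: largest start + k*u_ii <= ucrit
    k = int(np.floor((ucrit - start_speed_ms) / u_ii_ms + 1e-12))
    u_i = start_speed_ms + k * u_ii_ms
    t_i_true = t_ii_s * (ucrit - u_i) / u_ii_ms
    events = []
    for _ in range(n_events):
        t_i = t_i_true
        if fatigue_jitter_sd_s > 0:
            t_i = float(np.clip(t_i + rng.normal(0.0, fatigue_jitter_sd_s), 0.0, t_ii_s))
        events.append(StepRecord(u_i_ms=u_i, u_ii_ms=u_ii_ms, t_i_s=t_i, t_ii_s=t_ii_s))
    return events


def _simulate_group(
    truth: SyntheticTruth,
    group: str,
    params: GroupGrowthTruth,
    n: int,
) -> list[dict]:
    rows = []
    for i in range(n):
        fish_id = f"{group[:2]}{i + 1:03d}"
        rng = _rng(truth, "cohort", fish_id)
        tl_pre = max(0.5, rng.normal(params.tl_mean_cm, params.tl_sd_cm))
        bw_pre = max(0.01, rng.normal(params.bw_mean_g, params.bw_sd_g))
        dtl = rng.normal(params.dtl_mean_cm, params.dtl_sd_cm) if params.dtl_sd_cm > 0 else params.dtl_mean_cm
        dbw = rng.normal(params.dbw_mean_g, params.dbw_sd_g) if params.dbw_sd_g > 0 else params.dbw_mean_g
        if params.dtl_sd_cm == 0 and params.dtl_mean_cm == 0:
            dtl = 0.0
        tl_post = max(0.5, tl_pre + dtl)
        bw_post = max(0.01, bw_pre + dbw)
        for stage, tl, bw in (("pre", tl_pre, bw_pre), ("post", tl_post, bw_post)):
            rows.append(
                {
                    "fish_id": fish_id,
                    "group": group,
                    "stage": stage,
                    "standard_bl_cm": tl * truth.bl_to_tl_ratio,
                    "total_tl_cm": tl,
                    "body_weight_g": bw,
                }
            )
    return rows


def simulate_cohort(
    truth: SyntheticTruth,
    n_swimmers: int = 78,
    n_resters: int = 79,
) -> pd.DataFrame:
    """Pre/post cohort table with group-specific growth effects.

    Defaults are the post-mortality group sizes of the training experiment.
    Pairing is preserved through fish_id; standard BL tracks total TL by a
    fixed ratio.
    """
    if n_swimmers < 2 or n_resters < 2:
        raise InvalidConditionError("need at least two fish per group")
    rows = _simulate_group(truth, "swimmer", truth.swimmer_growth, n_swimmers)
    rows += _simulate_group(truth, "rester", truth.rester_growth, n_resters)
    return pd.DataFrame(rows)


def simulate_ct_table(
    truth: SyntheticTruth,
    n_per_group: int = 8,
    genes=None,
) -> pd.DataFrame:
    """Triplicate Ct plates for swimmers and resters with known fold changes.

    Per fish and primer set, the housekeeping well sits at the stable
    housekeeping Ct; each target well sits ΔCt above it, shifted by
    −log2(true fc) in swimmers.  Triplicates add i.i.d. Gaussian noise of SD
    ``ct_noise_sd`` cycles.  The CSV dialect matches the qPCR reader.
    """
    if genes is None:
        genes = sorted(PRIMER_SETS)
    unknown = set(genes) - set(PRIMER_SETS)
    if unknown:
        raise InvalidConditionError(f"unknown genes requested: {sorted(unknown)}")
    primer_sets_needed = sorted({PRIMER_SETS[g] for g in genes})
    rows = []
    for group, prefix in (("swimmer", "sw"), ("rester", "re")):
        for i in range(n_per_group):
            fish_id = f"{prefix}{i + 1:03d}"
            for pset in primer_sets_needed:
                rng = _rng(truth, "ct", fish_id, pset)
                hk_true = truth.housekeeping_ct
                hk_reps = hk_true + rng.normal(0.0, truth.ct_noise_sd, 3)
                rows.append(
                    _ct_row(fish_id, group, HOUSEKEEPING_GENE, pset, hk_reps)
                )
                for gene in [g for g in genes if PRIMER_SETS[g] == pset]:
                    fc = truth.true_fold_changes.get(gene, 1.0)
                    target_true = hk_true + truth.target_baseline_dct
                    if group == "swimmer":
                        target_true -= np.log2(fc)
                    reps = target_true + rng.normal(0.0, truth.ct_noise_sd, 3)
                    rows.append(_ct_row(fish_id, group, gene, pset, reps))
    return pd.DataFrame(rows)


def _ct_row(fish_id: str, group: str, gene: str, pset: str, reps) -> dict:
    return {
        "fish_id": fish_id,
        "group": group,
        "gene": gene,
        "primer_set": pset,
        "rep1_ct": float(reps[0]),
        "rep2_ct": float(reps[1]),
        "rep3_ct": float(reps[2]),
        "dilution": 10,
    }


def fold_change_recovery(
    gene: str,
    true_fc: float,
    n_replicates: int = 500,
    n_per_group: int = 8,
    ct_noise_sd: float = 0.2,
    housekeeping_ct: float = 18.0,
    root_seed: int = 0,
) -> dict[str, float]:
    """Monte-Carlo recovery of a known fold change through the full pipeline.

    Each replicate simulates fresh triplicate plates, runs the ΔΔCt pipeline
    and records the group-form fold-change estimate (unbiased on the log
    scale).  Replicates are aggregated geometrically with a delta-method SEM
    on the fold-change scale, the appropriate averaging for a ratio quantity.
    """
    from .qpcr import analyze_expression  # local import to avoid cycle at module load

    children = np.random.SeedSequence(root_seed).spawn(n_replicates)
    log2_estimates = np.empty(n_replicates)
    for r, child in enumerate(children):
        seed = int(child.generate_state(1)[0] % 2**31)
        truth = SyntheticTruth(
            true_fold_changes={gene: true_fc},
            ct_noise_sd=ct_noise_sd,
            housekeeping_ct=housekeeping_ct,
            seed=seed,
        )
        table = simulate_ct_table(truth, n_per_group=n_per_group, genes=[gene])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = analyze_expression(table)[gene]
        log2_estimates[r] = np.log2(result.fold_change_group)
    mean_log2 = float(log2_estimates.mean())
    sem_log2 = float(log2_estimates.std(ddof=1) / np.sqrt(n_replicates))
    fc_hat = float(2.0**mean_log2)
    return {
        "fc_estimate": fc_hat,
        "fc_sem": fc_hat * np.log(2.0) * sem_log2,
        "n_replicates": n_replicates,
        "true_fc": true_fc,
    }
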