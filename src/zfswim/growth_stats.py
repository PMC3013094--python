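"""Pre/post morphometric comparisons for the training experiment.

The statistical battery mirrors the experimental design: normality is
screened with one-sample Kolmogorov–Smirnov tests, baseline group
equivalence with unpaired two-tailed t-tests, within-group growth with
paired one-tailed t-tests (directions declared a priori: swimmers gain,
resters lose weight), and end-of-experiment group contrasts with unpaired
one-tailed t-tests.  Percent differences are computed on group means,
relative to the reference (rester) group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, InsufficientDataError, PairingError

__all__ = [
    "NormalityResult",
    "GrowthComparison",
    "check_normality",
    "percent_difference",
    "paired_change",
    "compare_groups",
    "run_growth_battery",
    "mortality_percent",
]

#: cohort-table column for each analysis variable
VARIABLE_COLUMNS = {"TL": "total_tl_cm", "BW": "body_weight_g"}


@dataclass(frozen=True)
class NormalityResult:
    statistic: float
    p_value: float
    n: int


def check_normality(values) -> NormalityResult:
    """One-sample KS test against a normal with the sample mean and SD.

    Advisory only: downstream t-tests proceed regardless, a rejection is a
    flag for the analyst.  (Estimating the parameters from the same sample
    makes the test conservative.)
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise InsufficientDataError(f"need >= 3 values for a normality check, have {values.size}")
    sd = values.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("constant sample: normality check undefined")
    stat, p = stats.kstest(values, "norm", args=(values.mean(), sd))
    return NormalityResult(statistic=float(stat), p_value=float(p), n=int(values.size))


def percent_difference(value: float, reference: float) -> float:
    """100 × (value − reference) / reference."""
    if reference == 0:
        raise DegenerateDataError("percent difference undefined for zero reference")
    return 100.0 * (value - reference) / reference


@dataclass(frozen=True)
class GrowthComparison:
    """Result of one t-test comparison from the battery."""

    variable: str
    groups: str  #: e.g. "swimmer pre vs post" or "swimmer vs rester (post)"
    test: str  #: paired_t_one_tailed | unpaired_t_one_tailed | unpaired_t_two_tailed
    n_a: int
    n_b: int
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    t_statistic: float
    p_value: float
    percent_difference: float  #: of mean_a relative to mean_b


def _mean_sem(x: np.ndarray) -> tuple[float, float]:
    return float(x.mean()), float(x.std(ddof=1) / np.sqrt(x.size))


def _column(variable: str) -> str:
    try:
        return VARIABLE_COLUMNS[variable]
    except KeyError:
        raise KeyError(f"unknown variable {variable!r}; expected one of {sorted(VARIABLE_COLUMNS)}")


def paired_change(
    cohort: pd.DataFrame,
    group: str,
    variable: str,
    alternative: str = "greater",
) -> GrowthComparison:
    """Paired one-tailed t-test of post vs pre within one group.

    ``alternative="greater"`` tests for an increase over the experiment,
    ``"less"`` for a decrease.  The direction is part of the comparison
    design, never inferred from the data.  Fish present at only one stage
    raise a pairing error.
    """
    col = _column(variable)
    sub = cohort[cohort["group"] == group]
    wide = sub.pivot(index="fish_id", columns="stage", values=col)
    if "pre" not in wide.columns or "post" not in wide.columns:
        raise PairingError(f"group {group!r} lacks a pre or post stage")
    if wide.isna().any().any():
        missing = wide.index[wide.isna().any(axis=1)].tolist()
        raise PairingError(f"unmatched fish in paired comparison: {missing[:5]}")
    pre = wide["pre"].to_numpy(dtype=float)
    post = wide["post"].to_numpy(dtype=float)
    diff = post - pre
    if np.all(diff == 0):
        # degenerate no-change limit: t -> 0, p at the null centre
        t_stat = 0.0
        p_val = 0.5 if alternative != "two-sided" else 1.0
    else:
        res = stats.ttest_rel(post, pre, alternative=alternative)
        t_stat, p_val = float(res.statistic), float(res.pvalue)
    mean_post, sem_post = _mean_sem(post)
    mean_pre, sem_pre = _mean_sem(pre)
    return GrowthComparison(
        variable=variable,
        groups=f"{group} post vs pre",
        test="paired_t_one_tailed" if alternative != "two-sided" else "paired_t_two_tailed",
        n_a=post.size,
        n_b=pre.size,
        mean_a=mean_post,
        sem_a=sem_post,
        mean_b=mean_pre,
        sem_b=sem_pre,
        t_statistic=t_stat,
        p_value=p_val,
        percent_difference=percent_difference(mean_post, mean_pre),
    )


def compare_groups(
    cohort: pd.DataFrame,
    variable: str,
    stage: str,
    alternative: str = "two-sided",
    welch: bool = False,
    group_a: str = "swimmer",
    group_b: str = "rester",
) -> GrowthComparison:
    """Unpaired t-test between two groups at one stage.

    Classical pooled-variance Student's t by default; Welch via ``welch=True``.
    ``alternative`` follows scipy's convention for group_a relative to
    group_b ("greater" = swimmers larger).
    """
    col = _column(variable)
    at_stage = cohort[cohort["stage"] == stage]
    a = at_stage.loc[at_stage["group"] == group_a, col].to_numpy(dtype=float)
    b = at_stage.loc[at_stage["group"] == group_b, col].to_numpy(dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError(
            f"need >= 2 fish per group at stage {stage!r}, have {a.size}/{b.size}"
        )
    res = stats.ttest_ind(a, b, equal_var=not welch, alternative=alternative)
    mean_a, sem_a = _mean_sem(a)
    mean_b, sem_b = _mean_sem(b)
    test = "unpaired_t_two_tailed" if alternative == "two-sided" else "unpaired_t_one_tailed"
    if welch:
        test += "_welch"
    return GrowthComparison(
        variable=variable,
        groups=f"{group_a} vs {group_b} ({stage})",
        test=test,
        n_a=a.size,
        n_b=b.size,
        mean_a=mean_a,
        sem_a=sem_a,
        mean_b=mean_b,
        sem_b=sem_b,
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        percent_difference=percent_difference(mean_a, mean_b),
    )


#: declared one-tailed directions for within-group change: swimmers are
#: expected to grow in both variables, resters to lose weight and not grow.
PAIRED_DIRECTIONS = {
    ("swimmer", "TL"): "greater",
    ("swimmer", "BW"): "greater",
    ("rester", "TL"): "two-sided",
    ("rester", "BW"): "less",
}


def run_growth_battery(cohort: pd.DataFrame) -> pd.DataFrame:
    """The full comparison battery as a tidy table.

    Baseline two-tailed group equivalence, paired within-group change with
    the a-priori directions above, and one-tailed swimmer-over-rester
    contrasts at the end of the experiment, for both TL and BW.
    """
    comparisons: list[GrowthComparison] = []
    for variable in ("TL", "BW"):
        comparisons.append(compare_groups(cohort, variable, "pre", alternative="two-sided"))
        for group in ("swimmer", "rester"):
            comparisons.append(
                paired_change(cohort, group, variable, PAIRED_DIRECTIONS[(group, variable)])
            )
        comparisons.append(compare_groups(cohort, variable, "post", alternative="greater"))
    return pd.DataFrame([vars(c) for c in comparisons])


def mortality_percent(n_dead: int, n_start: int) -> float:
    """Mortality over the experiment as a percentage of the starting count."""
    if n_start <= 0 or n_dead < 0 or n_dead > n_start:
        raise InsufficientDataError(f"invalid mortality counts {n_dead}/{n_start}")
    return 100.0 * n_dead / n_start
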