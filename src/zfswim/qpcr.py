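"""Relative qPCR quantification: triplicate QC, ΔΔCt fold changes, group tests.

Expression of fourteen muscle-growth marker genes is quantified relative to
the housekeeping gene *rps18* by the Livak 2^−ΔΔCt method: per fish,
ΔCt = Ct(target) − Ct(rps18); per swimmer j, ΔΔCt_j = ΔCt_j − mean rester
ΔCt, and fc_j = E^−ΔΔCt_j with amplification efficiency E = 2 by default.
The gene panel is split over two primer sets (A and B) that use *different*
rps18 primers, so a target well may only be normalised against the rps18
well of its own set.

Outliers are screened per gene and group on the ΔCt scale (where the Gaussian
assumption of the test is plausible; fold changes are lognormal) with an
iterative two-sided Grubbs test, capped at two removals per gene per group.
Group differences are tested with two-sided Mann–Whitney U tests, exact for
small tie-free samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InsufficientDataError,
    NormalizationError,
    PlateFormatError,
)

__all__ = [
    "GENE_VOCABULARY",
    "PRIMER_SETS",
    "HOUSEKEEPING_GENE",
    "TriplicateSummary",
    "FoldChangeResult",
    "aggregate_triplicates",
    "normalize_dct",
    "fold_change",
    "grubbs_critical_value",
    "remove_outliers",
    "mann_whitney",
    "housekeeping_stable",
    "analyze_expression",
]

HOUSEKEEPING_GENE = "rps18"

#: primer-set membership of the marker panel; rps18 has a primer pair in each
PRIMER_SETS: dict[str, str] = {
    "ghra": "A",
    "ghrb": "A",
    "igf1ra": "A",
    "igf1rb": "A",
    "igf1": "A",
    "ztor": "A",
    "foxo5": "A",
    "pgc1a": "A",
    "stnnc": "B",
    "smyhc1": "B",
    "tnni2": "B",
    "myhz2": "B",
    "mstnb": "B",
    "myog": "B",
}

GENE_VOCABULARY = frozenset(PRIMER_SETS) | {HOUSEKEEPING_GENE}


@dataclass(frozen=True)
class TriplicateSummary:
    mean_ct: float
    sd_ct: float
    qc_pass: bool


def aggregate_triplicates(ct_values, sd_threshold: float = 0.5) -> TriplicateSummary:
    """Arithmetic mean of a triplicate, flagged when replicate SD > threshold."""
    cts = np.asarray(ct_values, dtype=float)
    if cts.shape != (3,):
        raise PlateFormatError(f"expected exactly 3 replicate Ct values, got {cts.size}")
    if np.any((cts <= 0) | (cts > 40)):
        raise PlateFormatError(f"Ct values outside (0, 40]: {cts.tolist()}")
    sd = float(cts.std(ddof=1))
    return TriplicateSummary(mean_ct=float(cts.mean()), sd_ct=sd, qc_pass=sd <= sd_threshold)


def normalize_dct(
    target_ct: float,
    housekeeping_ct: float,
    target_primer_set: str | None = None,
    housekeeping_primer_set: str | None = None,
) -> float:
    """ΔCt = target − housekeeping, refusing cross-primer-set normalisation."""
    if (
        target_primer_set is not None
        and housekeeping_primer_set is not None
        and target_primer_set != housekeeping_primer_set
    ):
        raise NormalizationError(
            f"target from primer set {target_primer_set} cannot be normalised "
            f"against rps18 from set {housekeeping_primer_set}"
        )
    return float(target_ct) - float(housekeeping_ct)


@dataclass(frozen=True)
class FoldChangeResult:
    """Per-gene fold change of swimmers relative to resters."""

    gene: str
    fold_change_mean: float  #: arithmetic mean of per-swimmer fc_j
    fold_change_sem: float  #: SEM across per-swimmer fc_j
    fold_change_group: float  #: E^−(mean swimmer ΔCt − mean rester ΔCt)
    fold_change_geometric: float  #: geometric mean of fc_j (same as group form)
    per_swimmer_fc: tuple[float, ...]
    n_swimmers: int
    n_resters: int
    removed_outliers: tuple[str, ...] = ()
    u_statistic: float | None = None
    p_value: float | None = None


def fold_change(
    swimmer_dcts,
    rester_dcts,
    efficiency: float = 2.0,
    gene: str = "",
) -> FoldChangeResult:
    """Livak relative quantification of one gene.

    Per-swimmer fold changes fc_j = E^−(ΔCt_j − mean rester ΔCt) are reported
    as arithmetic mean ± SEM (the conventional presentation).  The group-mean
    form E^−(ΔΔCt of group means) — identical to the geometric mean of the
    fc_j — is carried alongside; being unbiased on the log scale it is the
    better recovery estimator.
    """
    sw = np.asarray(swimmer_dcts, dtype=float)
    re = np.asarray(rester_dcts, dtype=float)
    if sw.size < 2 or re.size < 2:
        raise InsufficientDataError(
            f"need >= 2 fish per group for a fold change, have {sw.size}/{re.size}"
        )
    if not efficiency > 1:
        raise InsufficientDataError(f"amplification efficiency must exceed 1, got {efficiency}")
    ddct = sw - re.mean()
    fc_j = efficiency ** (-ddct)
    group_fc = float(efficiency ** (-(sw.mean() - re.mean())))
    return FoldChangeResult(
        gene=gene,
        fold_change_mean=float(fc_j.mean()),
        fold_change_sem=float(fc_j.std(ddof=1) / np.sqrt(fc_j.size)),
        fold_change_group=group_fc,
        fold_change_geometric=float(np.exp(np.mean(np.log(fc_j)))),
        per_swimmer_fc=tuple(float(v) for v in fc_j),
        n_swimmers=int(sw.size),
        n_resters=int(re.size),
    )


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value G_crit for sample size n."""
    if n < 3:
        raise InsufficientDataError("Grubbs test needs n >= 3")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def remove_outliers(
    values,
    max_removals: int = 2,
    alpha: float = 0.05,
):
    """Iterative two-sided Grubbs screen.

    Returns ``(filtered_values, removed_indices)`` with indices into the
    original array.  At most ``max_removals`` points are dropped; samples
    smaller than 4 are returned unchanged with a warning (the test has no
    power there).
    """
    vals = np.asarray(values, dtype=float)
    removed: list[int] = []
    if max_removals == 0:
        return vals.copy(), removed
    if vals.size < 4:
        warnings.warn(f"sample of {vals.size} too small for outlier screening; skipped", stacklevel=2)
        return vals.copy(), removed
    indices = np.arange(vals.size)
    current = vals.copy()
    while len(removed) < max_removals and current.size >= 4:
        sd = current.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(current - current.mean())
        i_max = int(np.argmax(dev))
        g = dev[i_max] / sd
        if g <= grubbs_critical_value(current.size, alpha):
            break
        removed.append(int(indices[i_max]))
        current = np.delete(current, i_max)
        indices = np.delete(indices, i_max)
    return current, removed


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    Exact null distribution when the combined sample is tie-free and holds at
    most 20 observations; normal approximation with tie correction otherwise.
    Returns (U of group_a, p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("both groups must be non-empty for a Mann-Whitney test")
    combined = np.concatenate([a, b])
    tie_free = np.unique(combined).size == combined.size
    method = "exact" if (tie_free and combined.size <= 20) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def housekeeping_stable(
    hk_ct_group_a,
    hk_ct_group_b,
    alpha: float = 0.05,
) -> tuple[bool, float]:
    """Check that housekeeping Ct does not differ between groups.

    A significant difference invalidates the normalisation assumption; the
    dataset is flagged (returns ``(False, p)``) and a warning emitted.
    """
    _, p = mann_whitney(hk_ct_group_a, hk_ct_group_b)
    stable = p >= alpha
    if not stable:
        warnings.warn(
            f"housekeeping gene Ct differs between groups (p={p:.3g}); "
            "fold changes may be confounded",
            stacklevel=2,
        )
    return stable, float(p)


def _mean_ct_table(ct_table: pd.DataFrame, sd_threshold: float) -> pd.DataFrame:
    """Collapse replicate columns to mean Ct per (fish, gene, primer set)."""
    required = {"fish_id", "group", "gene", "primer_set", "rep1_ct", "rep2_ct", "rep3_ct"}
    missing = required - set(ct_table.columns)
    if missing:
        raise PlateFormatError(f"Ct table missing columns: {sorted(missing)}")
    rows = []
    for _, row in ct_table.iterrows():
        summ = aggregate_triplicates(
            [row["rep1_ct"], row["rep2_ct"], row["rep3_ct"]], sd_threshold=sd_threshold
        )
        rows.append(
            {
                "fish_id": row["fish_id"],
                "group": row["group"],
                "gene": row["gene"],
                "primer_set": row["primer_set"],
                "mean_ct": summ.mean_ct,
                "qc_pass": summ.qc_pass,
            }
        )
    return pd.DataFrame(rows)


def analyze_expression(
    ct_table: pd.DataFrame,
    efficiency: float = 2.0,
    sd_threshold: float = 0.5,
    max_outlier_removals: int = 2,
    outlier_alpha: float = 0.05,
    drop_qc_failures: bool = False,
) -> dict[str, FoldChangeResult]:
    """Full ΔΔCt pipeline over a tidy triplicate Ct table.

    Steps: triplicate aggregation with SD QC, per-fish ΔCt against the rps18
    well of the matching primer set, per-group Grubbs outlier screening on
    ΔCt, Livak fold changes of swimmers over resters, and a two-sided
    Mann–Whitney U test per gene.  Housekeeping between-group stability is
    checked first and a warning raised if it fails.
    """
    means = _mean_ct_table(ct_table, sd_threshold)
    if drop_qc_failures:
        keep_hk = means["gene"] == HOUSEKEEPING_GENE
        means = means[means["qc_pass"] | keep_hk]

    hk = means[means["gene"] == HOUSEKEEPING_GENE]
    if hk.empty:
        raise NormalizationError(f"no {HOUSEKEEPING_GENE} wells found in the Ct table")
    hk_lookup = hk.set_index(["fish_id", "primer_set"])["mean_ct"]

    for pset in sorted(hk["primer_set"].unique()):
        sub = hk[hk["primer_set"] == pset]
        a = sub.loc[sub["group"] == "swimmer", "mean_ct"].to_numpy()
        b = sub.loc[sub["group"] == "rester", "mean_ct"].to_numpy()
        if a.size and b.size:
            housekeeping_stable(a, b)

    results: dict[str, FoldChangeResult] = {}
    targets = means[means["gene"] != HOUSEKEEPING_GENE]
    for gene in sorted(targets["gene"].unique()):
        sub = targets[targets["gene"] == gene]
        dcts: dict[str, list] = {"swimmer": [], "rester": []}
        fish_ids: dict[str, list] = {"swimmer": [], "rester": []}
        for _, row in sub.iterrows():
            key = (row["fish_id"], row["primer_set"])
            if key not in hk_lookup.index:
                raise NormalizationError(
                    f"no {HOUSEKEEPING_GENE} (set {row['primer_set']}) well for fish {row['fish_id']}"
                )
            dct = normalize_dct(row["mean_ct"], hk_lookup[key])
            dcts[row["group"]].append(dct)
            fish_ids[row["group"]].append(row["fish_id"])

        removed_ids: list[str] = []
        clean: dict[str, np.ndarray] = {}
        for grp in ("swimmer", "rester"):
            vals = np.asarray(dcts[grp], dtype=float)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                kept, removed_idx = remove_outliers(
                    vals, max_removals=max_outlier_removals, alpha=outlier_alpha
                )
            clean[grp] = kept
            removed_ids.extend(fish_ids[grp][i] for i in removed_idx)

        fc = fold_change(clean["swimmer"], clean["rester"], efficiency=efficiency, gene=gene)
        u_stat, p = mann_whitney(clean["swimmer"], clean["rester"])
        results[gene] = FoldChangeResult(
            gene=gene,
            fold_change_mean=fc.fold_change_mean,
            fold_change_sem=fc.fold_change_sem,
            fold_change_group=fc.fold_change_group,
            fold_change_geometric=fc.fold_change_geometric,
            per_swimmer_fc=fc.per_swimmer_fc,
            n_swimmers=fc.n_swimmers,
            n_resters=fc.n_resters,
            removed_outliers=tuple(removed_ids),
            u_statistic=u_stat,
            p_value=p,
        )
    return results


def expression_table(results: dict[str, FoldChangeResult]) -> pd.DataFrame:
    """Tidy per-gene summary of an :func:`analyze_expression` run."""
    rows = []
    for gene in sorted(results):
        r = results[gene]
        rows.append(
            {
                "gene": gene,
                "fc_mean": r.fold_change_mean,
                "fc_sem": r.fold_change_sem,
                "fc_group": r.fold_change_group,
                "n_swimmers": r.n_swimmers,
                "n_resters": r.n_resters,
                "n_outliers_removed": len(r.removed_outliers),
                "u_statistic": r.u_statistic,
                "p_value": r.p_value,
            }
        )
    return pd.DataFrame(rows)
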