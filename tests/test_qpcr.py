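"""Triplicate QC, ΔΔCt fold changes, Grubbs screening and Mann-Whitney tests."""

import itertools

import numpy as np
import pytest

from zfswim.errors import InsufficientDataError, NormalizationError, PlateFormatError
from zfswim.qpcr import (
    aggregate_triplicates,
    analyze_expression,
    fold_change,
    grubbs_critical_value,
    housekeeping_stable,
    mann_whitney,
    normalize_dct,
    remove_outliers,
)
from zfswim.synthetic import SyntheticTruth, simulate_ct_table


class TestTriplicates:
    @pytest.mark.parametrize(
        "cts, mean, qc",
        [
            ((20.0, 20.0, 20.0), 20.0, True),
            ((20.0, 20.2, 19.8), 20.0, True),
            ((20.0, 22.5, 20.1), 20.866667, False),  # replicate SD 1.42 cycles
        ],
    )
    def test_mean_and_qc_flag(self, cts, mean, qc):
        summ = aggregate_triplicates(cts)
        assert summ.mean_ct == pytest.approx(mean, abs=1e-6)
        assert summ.qc_pass is qc

    def test_wrong_replicate_count(self):
        with pytest.raises(PlateFormatError):
            aggregate_triplicates([20.0, 20.1])


class TestNormalization:
    def test_dct_arithmetic(self):
        assert normalize_dct(25.0, 20.0) == 5.0
        assert normalize_dct(20.0, 20.0) == 0.0

    def test_additive_shift_cancels(self):
        assert normalize_dct(25.0 + 3.3, 20.0 + 3.3) == pytest.approx(5.0)

    def test_primer_set_mismatch(self):
        with pytest.raises(NormalizationError):
            normalize_dct(25.0, 20.0, target_primer_set="B", housekeeping_primer_set="A")


class TestFoldChange:
    def test_identical_groups_give_unity(self):
        r = fold_change([5.0] * 4, [5.0] * 4)
        assert r.fold_change_mean == pytest.approx(1.0)
        assert r.fold_change_group == pytest.approx(1.0)

    def test_livak_identity(self):
        # every swimmer one cycle earlier than the rester mean -> fc 2
        r = fold_change([4.0] * 4, [5.0] * 4)
        assert r.fold_change_mean == pytest.approx(2.0)

    def test_group_form_equals_geometric_mean(self):
        rng = np.random.default_rng(2)
        r = fold_change(rng.normal(4, 0.3, 8), rng.normal(5, 0.3, 8))
        assert r.fold_change_group == pytest.approx(r.fold_change_geometric, rel=1e-12)

    def test_small_groups_rejected(self):
        with pytest.raises(InsufficientDataError):
            fold_change([5.0], [5.0, 5.1])

    def test_null_distribution_expectation_is_unity(self):
        """fc on identically distributed groups averages to 1 (Monte-Carlo)."""
        rng = np.random.default_rng(13)
        ests = np.array(
            [
                fold_change(rng.normal(5, 0.2, 8), rng.normal(5, 0.2, 8)).fold_change_group
                for _ in range(1000)
            ]
        )
        sem = ests.std(ddof=1) / np.sqrt(ests.size)
        assert abs(ests.mean() - 1.0) < 3 * sem


class TestGrubbs:
    def test_critical_values_match_published_table(self):
        # two-sided, alpha 0.05: n=5 -> 1.715, n=10 -> 2.290
        assert grubbs_critical_value(5) == pytest.approx(1.715, abs=0.001)
        assert grubbs_critical_value(10) == pytest.approx(2.290, abs=0.001)

    def test_gross_outlier_removed(self):
        kept, removed = remove_outliers([1.0, 1.1, 0.9, 1.0, 15.0])
        assert removed == [4]
        assert 15.0 not in kept

    def test_homogeneous_sample_untouched(self):
        kept, removed = remove_outliers([1.0, 1.1, 0.9, 1.05, 0.95])
        assert removed == []
        assert kept.size == 5

    def test_removals_capped(self):
        # staircase of three increasingly gross outliers avoids masking; the
        # cap stops the iteration after two removals
        vals = [1.0, 1.1, 0.9, 1.0, 1.05, 0.95, 1.02, 0.98, 6.0, 12.0, 25.0]
        kept, removed = remove_outliers(vals, max_removals=2)
        assert removed == [10, 9]
        _, removed3 = remove_outliers(vals, max_removals=3)
        assert removed3 == [10, 9, 8]

    def test_zero_budget_is_identity(self):
        vals = [1.0, 1.1, 0.9, 1.0, 15.0]
        kept, removed = remove_outliers(vals, max_removals=0)
        assert removed == [] and kept.tolist() == vals

    def test_small_samples_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="too small"):
            kept, removed = remove_outliers([1.0, 2.0, 30.0])
        assert removed == []


def _enumeration_p(a, b):
    """Exhaustive permutation null of the U statistic (tie-free data)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    pooled = np.concatenate([a, b])

    def u_of(idx):
        grp = pooled[list(idx)]
        rest = np.delete(pooled, list(idx))
        return sum(x > y for x in grp for y in rest)

    u_obs = u_of(range(na))
    m = min(u_obs, na * nb - u_obs)
    us = np.array([u_of(c) for c in itertools.combinations(range(na + nb), na)])
    return u_obs, float(np.mean((us <= m) | (us >= na * nb - m)))


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 of the 20 arrangements are this extreme

    def test_identical_groups_sit_at_null_centre(self):
        u, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert u == pytest.approx(4.5)
        assert p > 0.9

    def test_exact_p_equals_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for na in range(2, 7):
            for nb in range(2, 7):
                a = rng.normal(size=na)
                b = rng.normal(1.0, 1.0, size=nb)
                u, p = mann_whitney(a, b)
                u0, p0 = _enumeration_p(a, b)
                assert u == u0
                assert p == pytest.approx(p0, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            mann_whitney([], [1.0])


class TestPipeline:
    def test_noiseless_unity_panel(self):
        truth = SyntheticTruth(true_fold_changes={}, ct_noise_sd=0.0, seed=1)
        results = analyze_expression(simulate_ct_table(truth, n_per_group=4))
        for gene, r in results.items():
            assert r.fold_change_mean == pytest.approx(1.0, abs=1e-9), gene

    def test_noiseless_panel_recovers_programmed_fold_changes(self):
        truth = SyntheticTruth(ct_noise_sd=0.0, seed=1)
        results = analyze_expression(simulate_ct_table(truth, n_per_group=4))
        for gene, true_fc in truth.true_fold_changes.items():
            assert results[gene].fold_change_mean == pytest.approx(true_fc, rel=1e-9)

    def test_plate_wide_ct_shift_cancels(self):
        truth = SyntheticTruth(seed=5)
        table = simulate_ct_table(truth, n_per_group=4)
        shifted = table.copy()
        for col in ("rep1_ct", "rep2_ct", "rep3_ct"):
            shifted[col] = shifted[col] + 2.5
        base = analyze_expression(table)
        moved = analyze_expression(shifted)
        for gene in base:
            assert moved[gene].fold_change_mean == pytest.approx(
                base[gene].fold_change_mean, rel=1e-12
            )

    def test_noisy_recovery_within_two_sem(self):
        """True myhz2 fold change 7.92 recovered from noisy plates (n=8/8).

        Monte-Carlo over simulated experiments with triplicate noise SD 0.2
        cycles; the replicate-averaged estimate must land within 2 SEM.
        """
        from zfswim.synthetic import fold_change_recovery

        rec = fold_change_recovery("myhz2", 7.92, n_replicates=120, root_seed=5)
        assert abs(rec["fc_estimate"] - 7.92) < 2 * rec["fc_sem"]

    def test_unstable_housekeeping_flagged(self):
        rng = np.random.default_rng(1)
        stable, p = housekeeping_stable(rng.normal(18, 0.1, 8), rng.normal(18, 0.1, 8))
        assert stable
        with pytest.warns(UserWarning, match="housekeeping"):
            unstable, p = housekeeping_stable(rng.normal(18, 0.1, 8), rng.normal(20, 0.1, 8))
        assert not unstable
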