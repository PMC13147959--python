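"""ROC/AUC, threshold grids, Fisher's exact test, length matching."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from refoldkit.designability import DesignRecord, designability_fraction
from refoldkit.oracle_eval import (
    DEFAULT_PLDDT_AXIS,
    DEFAULT_SCRMSD_AXIS,
    OutcomeTable,
    fisher_exact_2x2,
    matched_subset_by_length,
    roc_auc,
    select_optimum,
    threshold_grid_sweep,
)


def brute_force_auc(scores, labels):
    """Pair counting: P(pos > neg) + half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def hypergeom_two_sided(table):
    """Exhaustive enumeration of all tables with the observed margins."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs + 1e-12)


def outcome_table(plddt, scrmsd, labels, dataset="d"):
    return OutcomeTable(pd.DataFrame({
        "design_id": [f"x{i}" for i in range(len(labels))],
        "plddt_mean": plddt,
        "scrmsd": scrmsd,
        "outcome": labels,
        "dataset": dataset,
    }))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([3, 4, 1, 2], [1, 1, 0, 0]) == 1.0

    def test_hand_counted_example(self):
        assert roc_auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]) == 0.75

    def test_matches_brute_force_small_instances(self, rng):
        for i in range(300):
            n = int(rng.integers(4, 25))
            scores = np.round(rng.normal(size=n), 1)  # rounded: frequent ties
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            assert roc_auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_complement_symmetry(self, rng):
        scores = rng.normal(size=500)
        labels = rng.integers(0, 2, 500)
        assert roc_auc(scores, labels) + roc_auc(scores, 1 - labels) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=200)
        labels = rng.integers(0, 2, 200)
        base = roc_auc(scores, labels)
        assert roc_auc(np.exp(scores), labels) == pytest.approx(base, abs=1e-12)
        assert roc_auc(3 * scores - 7, labels) == pytest.approx(base, abs=1e-12)

    def test_orientation_flip(self, rng):
        scores = rng.normal(size=100)
        labels = rng.integers(0, 2, 100)
        assert roc_auc(scores, labels, higher_is_better=False) == pytest.approx(
            1.0 - roc_auc(scores, labels), abs=1e-12
        )

    def test_null_scores_near_half(self, rng):
        scores = rng.normal(size=2000)
        labels = rng.integers(0, 2, 2000)
        assert 0.45 <= roc_auc(scores, labels) <= 0.55

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestGridSweep:
    def test_default_axes_121_cells(self, rng):
        table = outcome_table(
            rng.uniform(50, 100, 30), rng.uniform(0, 5, 30), rng.integers(0, 2, 30)
        )
        grid = threshold_grid_sweep(table)
        assert grid.tp.shape == (11, 11)
        assert len(DEFAULT_PLDDT_AXIS) == len(DEFAULT_SCRMSD_AXIS) == 11

    def test_counts_sum_to_n(self, rng):
        table = outcome_table(
            rng.uniform(50, 100, 40), rng.uniform(0, 5, 40), rng.integers(0, 2, 40)
        )
        grid = threshold_grid_sweep(table)
        np.testing.assert_array_equal(
            grid.tp + grid.fp + grid.fn + grid.tn, 40
        )

    def test_every_cell_matches_per_row_recount(self, rng):
        """Independent per-row recount of all 121 confusion matrices."""
        n = 60
        plddt = rng.uniform(50, 100, n)
        scrmsd = rng.uniform(0, 5, n)
        labels = rng.integers(0, 2, n)
        grid = threshold_grid_sweep(outcome_table(plddt, scrmsd, labels))
        for i, p in enumerate(grid.plddt_axis):
            for j, r in enumerate(grid.scrmsd_axis):
                tp = fp = fn = tn = 0
                for k in range(n):
                    pred = plddt[k] >= p and scrmsd[k] <= r
                    if pred and labels[k]:
                        tp += 1
                    elif pred:
                        fp += 1
                    elif labels[k]:
                        fn += 1
                    else:
                        tn += 1
                assert (grid.tp[i, j], grid.fp[i, j], grid.fn[i, j], grid.tn[i, j]) == \
                    (tp, fp, fn, tn)

    def test_separable_table_reaches_f1_one(self):
        table = outcome_table(
            [95, 96, 97, 55, 56, 57], [0.5, 0.4, 0.3, 4.0, 4.5, 4.8],
            [1, 1, 1, 0, 0, 0],
        )
        grid = threshold_grid_sweep(table)
        assert grid.f1.max() == 1.0

    def test_designability_cell_consistency(self, rng):
        """The (70, 2.0) cell's predicted-positive set is exactly the
        designability module's pass set."""
        n = 80
        plddt = rng.uniform(50, 100, n)
        scrmsd = rng.uniform(0, 5, n)
        labels = rng.integers(0, 2, n)
        grid = threshold_grid_sweep(outcome_table(plddt, scrmsd, labels))
        i = list(grid.plddt_axis).index(70.0)
        j = list(grid.scrmsd_axis).index(2.0)
        records = [
            DesignRecord(f"d{k}", "t", float(plddt[k]), float(scrmsd[k]), 100)
            for k in range(n)
        ]
        frac = designability_fraction(records, 70.0, 2.0)
        assert (grid.tp[i, j] + grid.fp[i, j]) / n == pytest.approx(frac)


class TestSelectOptimum:
    def test_unique_maximum(self, rng):
        table = outcome_table(
            [95, 96, 55, 56], [0.4, 0.3, 4.0, 4.5], [1, 1, 0, 0]
        )
        opt = select_optimum(threshold_grid_sweep(table), "f1")
        assert opt.value == 1.0

    def test_stringency_tie_break(self):
        """All positives concentrated at high pLDDT/low scRMSD: many cells
        tie at the maximum; the highest pLDDT threshold must win, then the
        lowest scRMSD threshold."""
        table = outcome_table([99.0, 99.0], [0.1, 0.1], [1, 1])
        opt = select_optimum(threshold_grid_sweep(table), "f1")
        assert opt.plddt_min == 95.0
        assert opt.scrmsd_max == 0.5

    def test_degenerate_flagged(self):
        # nothing can be predicted positive on the default grid
        table = outcome_table([40.0, 45.0], [6.0, 7.0], [1, 0])
        opt = select_optimum(threshold_grid_sweep(table), "precision")
        assert opt.degenerate

    def test_bad_criterion(self, rng):
        table = outcome_table([80.0, 70.0], [1.0, 2.0], [1, 0])
        with pytest.raises(ValueError):
            select_optimum(threshold_grid_sweep(table), "accuracy")


class TestFisher:
    def test_balanced_table(self):
        assert fisher_exact_2x2([[1, 1], [1, 1]]) == 1.0

    def test_diagonal_table_enumerated(self):
        assert fisher_exact_2x2([[5, 0], [0, 5]]) == pytest.approx(2 / 252, abs=1e-12)

    def test_zero_margin_gives_one(self):
        assert fisher_exact_2x2([[0, 0], [3, 4]]) == 1.0
        assert fisher_exact_2x2([[0, 3], [0, 4]]) == 1.0

    def test_matches_exhaustive_enumeration_all_small_tables(self):
        """Agreement with direct hypergeometric enumeration for every 2×2
        table with all margins ≤ 10."""
        checked = 0
        for a, b, c, d in itertools.product(range(11), repeat=4):
            if a + b > 10 or c + d > 10 or a + c > 10 or b + d > 10:
                continue
            if a + b + c + d == 0:
                continue
            table = [[a, b], [c, d]]
            assert fisher_exact_2x2(table) == pytest.approx(
                hypergeom_two_sided(table), abs=1e-9
            ), table
            checked += 1
        assert checked > 2500

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [0, 2]])


class TestMatchedSubset:
    @staticmethod
    def records(lengths, prefix):
        return [
            DesignRecord(f"{prefix}{i}", "t", 80.0, 1.0, int(l))
            for i, l in enumerate(lengths)
        ]

    def test_self_matching_returns_pool(self, rng):
        lengths = rng.integers(60, 300, 40)
        cases = self.records(lengths, "c")
        pool = self.records(lengths, "p")
        subset = matched_subset_by_length(cases, pool, rng_seed=0)
        assert len(subset) == len(pool)

    def test_three_fold_pool(self, rng):
        lengths = rng.integers(60, 300, 30)
        cases = self.records(lengths, "c")
        pool = self.records(np.repeat(lengths, 3), "p")
        subset = matched_subset_by_length(cases, pool, rng_seed=1)
        assert len(subset) == 3 * len(cases)

    def test_per_bin_ratio_constant(self, rng):
        case_lengths = rng.integers(100, 200, 50)
        pool_lengths = rng.integers(60, 300, 2000)
        cases = self.records(case_lengths, "c")
        pool = self.records(pool_lengths, "p")
        subset = matched_subset_by_length(cases, pool, n_bins=5, rng_seed=2)
        lo, hi = case_lengths.min(), case_lengths.max()
        case_hist, edges = np.histogram(case_lengths, bins=5, range=(lo, hi))
        sub_hist, _ = np.histogram([r.length for r in subset], bins=edges)
        ratios = sub_hist[case_hist > 0] / case_hist[case_hist > 0]
        assert len(set(ratios)) == 1

    def test_empty_pool_bin(self):
        cases = self.records([100, 200], "c")
        pool = self.records([100, 101], "p")
        with pytest.raises(ValueError, match="pool"):
            matched_subset_by_length(cases, pool, n_bins=2, rng_seed=0)
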