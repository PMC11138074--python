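"""Downstream statistics: correlations, ROC, contrasts, intolerance."""

import itertools

import numpy as np
import pandas as pd
import pytest

from kcne1_dms.evaluate import (
    crosstab_independence,
    group_contrast,
    operating_point,
    rank_correlation,
    residue_intolerance,
    roc,
    splice_flags,
)


def _brute_force_spearman(x, y):
    """Rank both vectors with average ties, then Pearson on the ranks."""
    def avg_ranks(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v), dtype=float)
        i = 0
        sv = np.asarray(v)[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks
    rx, ry = avg_ranks(x), avg_ranks(y)
    return np.corrcoef(rx, ry)[0, 1]


class TestRankCorrelation:
    def test_perfect_concordance(self):
        rho, _, n = rank_correlation([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0) and n == 4

    def test_perfect_discordance(self):
        rho, _, _ = rank_correlation([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_matches_rank_formula_with_ties(self, rng):
        x = rng.integers(0, 5, 10).astype(float)
        y = rng.normal(size=10)
        rho, _, _ = rank_correlation(x, y)
        assert rho == pytest.approx(_brute_force_spearman(x, y), abs=1e-12)

    def test_nan_pairs_dropped_and_minimum_enforced(self):
        with pytest.raises(ValueError):
            rank_correlation([1.0, np.nan, 3.0], [1.0, 2.0, np.nan])


class TestRoc:
    def test_perfect_separation(self):
        # deleterious = low score
        labels = [1, 1, 1, 0, 0, 0]
        scores = [0.1, 0.2, 0.3, 0.9, 1.0, 1.1]
        _, auc = roc(labels, scores)
        assert auc == pytest.approx(1.0)

    def test_permuted_scores_near_half(self, rng):
        labels = np.repeat([0, 1], 300)
        scores = rng.permutation(np.linspace(0, 2, 600))
        _, auc = roc(labels, scores)
        assert auc == pytest.approx(0.5, abs=0.08)

    def test_auc_invariant_under_monotone_transform(self, rng):
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        scores = rng.normal(size=50)
        _, auc1 = roc(labels, scores)
        _, auc2 = roc(labels, np.exp(3 * scores) + 1)
        assert auc1 == pytest.approx(auc2, abs=1e-12)

    def test_operating_point_example(self):
        labels = [1, 1, 1, 0, 0, 0]
        scores = [0.1, 0.2, 0.5, 0.9, 1.0, 1.1]
        sens, spec = operating_point(labels, scores, cutoff=0.44)
        assert sens == pytest.approx(2 / 3)
        assert spec == pytest.approx(1.0)

    def test_operating_point_matches_confusion_matrix(self, rng):
        labels = rng.integers(0, 2, 200).astype(bool)
        labels[:2] = [False, True]
        scores = rng.uniform(0, 2, 200)
        cutoff = 0.8
        sens, spec = operating_point(labels, scores, cutoff)
        tp = np.sum(labels & (scores < cutoff))
        fn = np.sum(labels & (scores >= cutoff))
        tn = np.sum(~labels & (scores >= cutoff))
        fp = np.sum(~labels & (scores < cutoff))
        assert sens == pytest.approx(tp / (tp + fn))
        assert spec == pytest.approx(tn / (tn + fp))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc([1, 1], [0.1, 0.2])


class TestGroupContrast:
    def test_identical_groups_not_significant(self):
        _, p = group_contrast([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert p > 0.9

    def test_fully_separated_small_groups_extreme_statistic(self):
        stat, p = group_contrast([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        assert stat == 0.0  # all pairwise comparisons lost
        assert p == pytest.approx(2 / 252)  # 2 / C(10,5) under the exact null

    def test_exact_p_matches_enumeration_at_n5(self, rng):
        a = rng.normal(size=5)
        b = rng.normal(loc=0.8, size=5)
        _, p = group_contrast(a, b)
        pooled = np.concatenate([a, b])
        observed = sum(x < y for x in a for y in b) + 0.5 * sum(
            x == y for x in a for y in b
        )
        null = []
        for combo in itertools.combinations(range(10), 5):
            ga = pooled[list(combo)]
            gb = pooled[[i for i in range(10) if i not in combo]]
            u = sum(x < y for x in ga for y in gb) + 0.5 * sum(
                x == y for x in ga for y in gb
            )
            null.append(u)
        null = np.array(null)
        centre = 12.5  # n*m/2
        expected = np.mean(np.abs(null - centre) >= abs(observed - centre) - 1e-9)
        assert p == pytest.approx(expected, abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_contrast([], [1.0])


class TestCrosstabIndependence:
    def test_diagonal_two_by_two(self):
        chi2, p = crosstab_independence(pd.DataFrame([[10, 0], [0, 10]]))
        assert chi2 == pytest.approx(20.0)

    def test_independent_uniform_fill_is_null(self):
        chi2, p = crosstab_independence(pd.DataFrame([[25, 25], [25, 25]]))
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_three_by_three_diagonal_analytic(self):
        # all off-diagonal expectations are n/9 with observed 0, diagonal
        # observed n/3 vs expected n/9: chi2 = 9 * (2n/27 + ... ) = 2n
        n = 90
        table = pd.DataFrame(np.diag([n // 3] * 3))
        chi2, _ = crosstab_independence(table)
        assert chi2 == pytest.approx(2 * n)

    def test_degenerate_margins_rejected(self):
        with pytest.raises(ValueError):
            crosstab_independence(pd.DataFrame([[1, 2], [0, 0]]))


class TestResidueIntolerance:
    @staticmethod
    def _variants(per_residue: dict[int, list[str]]) -> tuple[pd.Series, pd.DataFrame]:
        names, cats, rows = [], [], []
        for residue, categories in per_residue.items():
            for i, cat in enumerate(categories):
                name = f"A{residue}X{i}"
                names.append(name)
                cats.append(cat)
                rows.append({"position": residue, "vclass": "missense"})
        frame = pd.DataFrame(rows, index=pd.Index(names, name="name"))
        return pd.Series(cats, index=frame.index), frame

    def test_above_seventy_percent_is_intolerant(self):
        cats, var = self._variants({7: ["loss"] * 15 + ["normal"] * 5})
        out = residue_intolerance(cats, var)
        assert bool(out.loc[7, "intolerant"]) and out.loc[7, "fraction_lof"] == 0.75

    def test_seventy_percent_boundary_is_strict(self):
        cats, var = self._variants({7: ["partial_loss"] * 14 + ["normal"] * 6})
        out = residue_intolerance(cats, var)
        assert not bool(out.loc[7, "intolerant"])

    def test_all_normal_is_tolerant(self):
        cats, var = self._variants({3: ["normal"] * 12})
        out = residue_intolerance(cats, var)
        assert bool(out.loc[3, "tolerant"]) and not bool(out.loc[3, "intolerant"])

    def test_flags_mutually_exclusive(self, rng):
        per_residue = {
            r: list(rng.choice(["loss", "partial_loss", "normal", "possible_loss"], 19))
            for r in range(1, 25)
        }
        cats, var = self._variants(per_residue)
        out = residue_intolerance(cats, var)
        assert not (out["intolerant"] & out["tolerant"]).any()


class TestSpliceFlags:
    def test_threshold_flags(self):
        flags = splice_flags(pd.Series([0.55, 0.30, 0.10, 0.2, 0.5]))
        assert list(flags) == ["recommended", "high_recall", "none", "none", "high_recall"]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            splice_flags(pd.Series([1.2]))
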