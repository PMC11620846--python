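import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coexistkit.association import (assign_species_groups, correlation_tests,
                                    pair_cells, pairwise_association,
                                    to_presence, variance_ratio_test,
                                    yates_chi2)


def _chi2_oracle(a, b, c, d):
    """Straight evaluation of the corrected statistic, coded independently."""
    n = a + b + c + d
    return n * (abs(a * d - b * c) - 0.5 * n) ** 2 / (
        (a + b) * (b + d) * (c + d) * (a + c))


class TestToPresence:
    def test_species_everywhere_gives_ones_row(self):
        iv = pd.DataFrame([[1.0, 2, 3], [0, 1, 0]], index=["A", "B"],
                          columns=["p1", "p2", "p3"])
        p = to_presence(iv)
        assert p.loc["A"].tolist() == [1, 1, 1]
        assert p.loc["B"].tolist() == [0, 1, 0]

    def test_subset_restricts_and_orders(self):
        iv = pd.DataFrame(np.eye(3), index=["A", "B", "C"],
                          columns=["p1", "p2", "p3"])
        p = to_presence(iv, ["C", "A"])
        assert list(p.index) == ["C", "A"]

    def test_absent_species_rejected(self):
        iv = pd.DataFrame([[1.0, 1]], index=["A"], columns=["p1", "p2"])
        with pytest.raises(ValueError, match="absent"):
            to_presence(iv, ["A", "Z"])


class TestVarianceRatio:
    def test_identical_presence_rows(self):
        p = pd.DataFrame([[1, 1, 0, 0], [1, 1, 0, 0]], index=["A", "B"])
        r = variance_ratio_test(p)
        assert r.vr == pytest.approx(2.0)
        assert r.w == pytest.approx(8.0)

    def test_complementary_presence_rows(self):
        p = pd.DataFrame([[1, 1, 0, 0], [0, 0, 1, 1]], index=["A", "B"])
        assert variance_ratio_test(p).vr == pytest.approx(0.0)

    def test_bounds_for_40_plots(self):
        p = pd.DataFrame(np.random.default_rng(0).integers(0, 2, (5, 40)))
        r = variance_ratio_test(p)
        assert round(r.lower, 2) == 26.51
        assert round(r.upper, 2) == 55.76

    def test_degenerate_matrix_rejected(self):
        p = pd.DataFrame([[1, 1], [1, 1]])
        with pytest.raises(ValueError):
            variance_ratio_test(p)


class TestYatesChi2:
    def test_hand_worked_table(self):
        r = yates_chi2(4, 10, 20, 6)
        assert r.chi2 == pytest.approx(973440 / 139776, abs=1e-9)
        assert r.significance == "extremely-significant"
        assert r.sign == "+"  # b=10 > expected 14*16/40 = 5.6

    def test_both_everywhere_no_association(self):
        r = yates_chi2(0, 40, 0, 0)
        assert r.significance == "no-association" and r.chi2 is None

    def test_sign_none_at_exact_independence(self):
        # margins 20x20 over N=40: expected b = 10
        r = yates_chi2(10, 10, 10, 10)
        assert r.sign == "none"

    def test_species_swap_invariance(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            cells = rng.integers(0, 15, 4)
            if cells.sum() == 0:
                continue
            a, b, c, d = (int(v) for v in cells)
            r1 = yates_chi2(a, b, c, d)
            r2 = yates_chi2(d, b, c, a)  # swap which species is 'first'
            assert (r1.chi2 is None) == (r2.chi2 is None)
            if r1.chi2 is not None:
                assert r1.chi2 == pytest.approx(r2.chi2)
                assert r1.sign == r2.sign

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            a, b, c, d = (int(v) for v in rng.integers(1, 20, 4))
            assert yates_chi2(a, b, c, d).chi2 == pytest.approx(
                _chi2_oracle(a, b, c, d), abs=1e-10)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            yates_chi2(-1, 2, 3, 4)


class TestPairwise:
    def test_pair_count_and_sum(self):
        p = pd.DataFrame(np.random.default_rng(3).integers(0, 2, (8, 30)))
        pairs, summary = pairwise_association(p)
        assert len(pairs) == 28
        c = summary["counts"]
        total = (sum(c["positive"].values()) + sum(c["negative"].values())
                 + c["no-association"])
        assert total == 28

    def test_perfect_cooccurrence_positive(self):
        row = [1, 0, 1, 0, 1, 0]
        p = pd.DataFrame([row, row], index=["A", "B"])
        pairs, _ = pairwise_association(p)
        assert pairs[0].sign == "+"

    def test_cells_from_rows(self):
        i = np.array([1, 1, 0, 0])
        k = np.array([1, 0, 1, 0])
        assert pair_cells(i, k) == (1, 1, 1, 1)


class TestCorrelations:
    def test_identical_vectors(self):
        ab = pd.DataFrame([[1, 3, 5, 7, 9]] * 2, index=["A", "B"])
        table, _ = correlation_tests(ab)
        assert table["r_pearson"].iloc[0] == pytest.approx(1.0)
        assert table["r_spearman"].iloc[0] == pytest.approx(1.0)

    def test_monotone_nonlinear_relationship(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        ab = pd.DataFrame([x, np.exp(x)], index=["A", "B"])
        table, _ = correlation_tests(ab)
        assert table["r_spearman"].iloc[0] == pytest.approx(1.0)
        assert table["r_pearson"].iloc[0] < 1.0

    def test_spearman_equals_pearson_on_ranks(self):
        rng = np.random.default_rng(4)
        x = rng.permutation(10).astype(float)  # tie-free
        y = rng.permutation(10).astype(float)
        ab = pd.DataFrame([x, y], index=["A", "B"])
        table, _ = correlation_tests(ab)
        expected = stats.pearsonr(stats.rankdata(x), stats.rankdata(y))[0]
        assert table["r_spearman"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_row_reported_no_association(self):
        ab = pd.DataFrame([[2, 2, 2, 2], [1, 2, 3, 4]], index=["A", "B"])
        table, summaries = correlation_tests(ab)
        assert np.isnan(table["r_pearson"].iloc[0])
        assert summaries["pearson"]["counts"]["no-association"] == 1

    def test_summary_counts_sum_to_pairs(self):
        rng = np.random.default_rng(5)
        ab = pd.DataFrame(rng.poisson(4, (6, 20)).astype(float))
        table, summaries = correlation_tests(ab)
        for s in summaries.values():
            c = s["counts"]
            assert (sum(c["positive"].values()) + sum(c["negative"].values())
                    + c["no-association"]) == len(table)


class TestSpeciesGroups:
    def test_separable_sign_blocks_recovered(self):
        scores = pd.DataFrame({"axis1": [1.0, 1.1, 0.9, -1.0, -1.1, -0.9]},
                              index=list("ABCDEF"))
        groups = assign_species_groups(scores, k=2)
        assert len(set(groups[list("ABC")])) == 1
        assert len(set(groups[list("DEF")])) == 1
        assert groups["A"] != groups["D"]

    def test_three_planted_guilds(self):
        rng = np.random.default_rng(6)
        centers = np.array([[2, 0], [-2, 1], [0, -2]])
        rows, idx = [], []
        for g, c in enumerate(centers):
            for i in range(5):
                rows.append(c + rng.normal(0, 0.15, 2))
                idx.append(f"g{g}s{i}")
        groups = assign_species_groups(pd.DataFrame(rows, index=idx), k=3)
        for g in range(3):
            members = groups[[f"g{g}s{i}" for i in range(5)]]
            assert len(set(members)) == 1

    def test_k_one_single_group(self):
        scores = pd.DataFrame({"a": [1.0, 2, 3]}, index=list("ABC"))
        assert set(assign_species_groups(scores, k=1)) == {1}

    def test_k_exceeding_species_rejected(self):
        with pytest.raises(ValueError):
            assign_species_groups(pd.DataFrame({"a": [1.0]}, index=["A"]), k=2)
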