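"""Exact-test construction, table reconstruction, correlation, Mann-Whitney
and survival comparisons, each against independent oracles where one exists."""

import numpy as np
import pandas as pd
import pytest

from cytoctc.stats import (
    ContingencyTable2x2,
    DegenerateTableError,
    boschloo_unconditional,
    compare_counts_mannwhitney,
    fisher_statistic,
    km_logrank,
    pearson_marker_correlation,
    reconstruct_table,
)
from tests.oracles import (
    all_tables_with_total,
    boschloo_bruteforce,
    mannwhitney_exact_bruteforce,
)


class TestBoschlooUnconditional:
    def test_balanced_table_p_is_one(self):
        for model in ("binomial", "multinomial"):
            res = boschloo_unconditional([[2, 2], [2, 2]], model=model)
            assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_small_table_matches_bruteforce_binomial(self):
        res = boschloo_unconditional([[1, 2], [2, 1]], model="binomial")
        oracle = boschloo_bruteforce((1, 2, 2, 1), model="binomial")
        assert res.p_value == pytest.approx(oracle, abs=1e-4)

    def test_extreme_association_small_p(self):
        res = boschloo_unconditional([[0, 3], [5, 0]], model="multinomial")
        assert round(res.p_value, 3) == 0.003

    def test_row_and_column_swap_symmetry(self):
        """Two-sided p is invariant under simultaneous row+column swaps; the
        ER-like [[3,5],[4,2]] and PR-like [[2,4],[5,3]] tables coincide."""
        a = boschloo_unconditional([[3, 5], [4, 2]]).p_value
        b = boschloo_unconditional([[2, 4], [5, 3]]).p_value
        assert a == pytest.approx(b, abs=1e-9)

    def test_one_sided_dominates_fisher(self):
        """Binomial-model one-sided p never exceeds the one-sided Fisher p
        (the test is uniformly more powerful than Fisher's)."""
        for tab in all_tables_with_total(6):
            res = boschloo_unconditional(tab, model="binomial", alternative="less")
            fisher = fisher_statistic(*tab, "less")
            assert res.p_value <= fisher + 1e-9

    def test_grid_monotonicity_on_nested_grids(self):
        # 101 | 202 | 404 | 808 interior points: each grid contains the last
        tab = [[3, 5], [4, 2]]
        ps = [
            boschloo_unconditional(tab, grid_resolution=g, refine=False).p_value
            for g in (100, 201, 403, 807)
        ]
        assert all(p2 >= p1 - 1e-12 for p1, p2 in zip(ps, ps[1:]))

    def test_stable_to_3_decimals_from_resolution_500(self):
        for tab in ([[0, 3], [5, 0]], [[0, 2], [3, 1]], [[3, 5], [4, 2]],
                    [[2, 4], [5, 3]], [[4, 6], [2, 1]]):
            p_500 = boschloo_unconditional(tab, grid_resolution=500).p_value
            p_1001 = boschloo_unconditional(tab, grid_resolution=1001).p_value
            assert abs(p_500 - p_1001) < 1e-3

    def test_degenerate_margin_raises_naming_margin(self):
        with pytest.raises(DegenerateTableError, match="row 1"):
            boschloo_unconditional([[0, 0], [2, 3]])
        with pytest.raises(DegenerateTableError, match="column"):
            boschloo_unconditional([[0, 2], [0, 3]])

    def test_result_metadata(self):
        res = boschloo_unconditional([[1, 2], [2, 1]], model="binomial",
                                     alternative="less", grid_resolution=501)
        assert res.model == "binomial"
        assert res.alternative == "less"
        assert res.grid_resolution == 501
        assert len(res.nuisance_argmax) == 1
        assert 0 < res.nuisance_argmax[0] < 1
        assert 0 < res.p_value <= 1
        assert res.statistic_observed == pytest.approx(
            fisher_statistic(1, 2, 2, 1, "less")
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            boschloo_unconditional([[1, 2], [2, 1]], grid_resolution=50)
        with pytest.raises(ValueError):
            boschloo_unconditional([[1, 2], [2, 1]], model="poisson")
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 2, 1)


class TestReconstructTable:
    def test_er_row(self):
        t = reconstruct_table(8, 37.5, (7, 7, 14))
        assert (t.a, t.b, t.c, t.d) == (3, 5, 4, 2)

    def test_her2_row_full_cohort(self):
        t = reconstruct_table(10, 40.0, (7, 7, 14))
        assert (t.a, t.b, t.c, t.d) == (4, 6, 3, 1)

    def test_melanoma_liver_rows(self):
        t = reconstruct_table(3, 0.0, (5, 3, 8))
        assert (t.a, t.b, t.c, t.d) == (0, 3, 5, 0)

    def test_rounded_percentage_accepted(self):
        # 33.3% of 6 = 1.998 -> 2 within tolerance
        t = reconstruct_table(6, 33.3, (7, 7, 14))
        assert (t.a, t.b, t.c, t.d) == (2, 4, 5, 3)

    def test_integer_inconsistent_percentage_rejected(self):
        # 60% of n=2 is 1.2 cells: impossible
        with pytest.raises(ValueError, match="integer"):
            reconstruct_table(2, 60.0, (7, 7, 14))

    def test_negative_complement_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            reconstruct_table(10, 90.0, (7, 7, 14))


class TestPearson:
    def test_identity_is_one(self):
        df = pd.DataFrame({"mean_CD74": [1.0, 2, 3, 4], "mean_CD44": [1.0, 2, 3, 4]})
        assert pearson_marker_correlation(df, ctc_only=False) == pytest.approx(1.0)

    def test_antilinear_is_minus_one(self):
        x = np.array([10.0, 20, 30, 40])
        df = pd.DataFrame({"mean_CD74": x, "mean_CD44": 100 - x})
        assert pearson_marker_correlation(df, ctc_only=False) == pytest.approx(-1.0)

    def test_restricts_to_ctcs(self):
        df = pd.DataFrame(
            {
                "mean_CD74": [1.0, 2, 3, 100],
                "mean_CD44": [1.0, 2, 3, -50],
                "is_ctc": [True, True, True, False],
            }
        )
        assert pearson_marker_correlation(df) == pytest.approx(1.0)

    def test_too_few_or_constant_raises(self):
        with pytest.raises(ValueError, match=">= 3"):
            pearson_marker_correlation(
                pd.DataFrame({"mean_CD74": [1.0, 2], "mean_CD44": [1.0, 2]}),
                ctc_only=False,
            )
        with pytest.raises(ValueError, match="variance"):
            pearson_marker_correlation(
                pd.DataFrame({"mean_CD74": [1.0, 1, 1], "mean_CD44": [1.0, 2, 3]}),
                ctc_only=False,
            )


class TestMannWhitney:
    def test_identical_singletons(self):
        assert compare_counts_mannwhitney([5], [5]) == pytest.approx(1.0)

    def test_extreme_separation_closed_form(self):
        # most extreme ranking of 3 vs 3: p = 2 / C(6,3) = 0.1
        assert compare_counts_mannwhitney([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_tied_groups_match_enumeration(self):
        x, y = [3, 4], [4, 4, 5, 6, 15]
        assert compare_counts_mannwhitney(x, y) == pytest.approx(
            mannwhitney_exact_bruteforce(x, y)
        )

    @pytest.mark.parametrize("seed", range(6))
    def test_random_small_samples_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1 = int(rng.integers(1, 6))
        n2 = int(rng.integers(1, 10 - n1 + 1))
        x = rng.integers(0, 6, n1).tolist()
        y = rng.integers(0, 6, n2).tolist()
        assert compare_counts_mannwhitney(x, y) == pytest.approx(
            mannwhitney_exact_bruteforce(x, y)
        )

    def test_large_sample_asymptotic_path(self):
        rng = np.random.default_rng(1)
        x = rng.poisson(5, 15).tolist()
        y = rng.poisson(8, 15).tolist()
        p = compare_counts_mannwhitney(x, y)
        assert 0 < p <= 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_counts_mannwhitney([], [1])


class TestSurvival:
    def test_identical_groups_p_one(self):
        rec = pd.DataFrame(
            {
                "survival_months": [2.0, 4, 6] * 2,
                "event": [True, False, True] * 2,
                "group": ["a"] * 3 + ["b"] * 3,
            }
        )
        res = km_logrank(rec)
        assert res.p_value == pytest.approx(1.0)
        assert res.test_statistic == pytest.approx(0.0, abs=1e-12)

    def test_extreme_separation_significant(self):
        rec = pd.DataFrame(
            {
                "survival_months": [1.0] * 5 + [10.0] * 5,
                "event": [True] * 5 + [False] * 5,
                "group": ["pos"] * 5 + ["neg"] * 5,
            }
        )
        assert km_logrank(rec).p_value < 0.05

    def test_km_without_censoring_is_empirical_survival(self):
        times = [1.0, 2.0, 3.0, 4.0]
        rec = pd.DataFrame(
            {
                "survival_months": times + [1.0, 2.0],
                "event": [True] * 6,
                "group": ["a"] * 4 + ["b"] * 2,
            }
        )
        curve = km_logrank(rec).curves["a"]
        # S(t) after k-th of 4 deaths = 1 - k/4
        surv = curve["survival"]
        for t, expected in [(1.0, 0.75), (2.0, 0.5), (3.0, 0.25), (4.0, 0.0)]:
            assert surv.loc[t] == pytest.approx(expected)

    def test_single_stratum_rejected(self):
        rec = pd.DataFrame(
            {"survival_months": [1.0, 2.0], "event": [True, True], "group": ["a", "a"]}
        )
        with pytest.raises(ValueError, match="strata"):
            km_logrank(rec)

    def test_nonpositive_time_rejected(self):
        rec = pd.DataFrame(
            {"survival_months": [0.0, 2.0], "event": [True, True], "group": ["a", "b"]}
        )
        with pytest.raises(ValueError, match="positive"):
            km_logrank(rec)
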