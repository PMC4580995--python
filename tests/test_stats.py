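import itertools

import numpy as np
import pandas as pd
import pytest

from splicesense.stats import (
    build_control_set,
    four_way_comparison,
    nine_category_analysis,
    overlap_independence_test,
    wilcoxon_rank_sum,
)


def brute_rank_sum_p(x, y):
    """Exact two-sided rank-sum p by enumerating all rank assignments."""
    pooled = sorted(x + y)
    n, m = len(x), len(y)
    u_obs = sum(1 for xi in x for yi in y if xi > yi)
    center = n * m / 2
    dist = []
    for comb in itertools.combinations(range(n + m), n):
        chosen = set(comb)
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in range(n + m) if i not in chosen]
        dist.append(sum(1 for xi in xs for yi in ys if xi > yi))
    extreme = sum(
        1 for u in dist if abs(u - center) >= abs(u_obs - center) - 1e-12
    )
    return extreme / len(dist)


class TestWilcoxonRankSum:
    def test_separated_groups_exact(self):
        assert wilcoxon_rank_sum([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_single_observations(self):
        assert wilcoxon_rank_sum([1], [2]) == pytest.approx(1.0)

    def test_identical_multisets(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_mode_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(2, 6, size=2)
        pool = rng.permutation(np.arange(1.0, 20.0))[: n + m]  # no ties
        x, y = list(pool[:n]), list(pool[n:])
        assert wilcoxon_rank_sum(x, y) == pytest.approx(brute_rank_sum_p(x, y))


class TestNineCategory:
    def test_expected_from_marginals(self):
        pairs = [("skip", "skip"), ("skip", "no_effect"),
                 ("no_effect", "skip"), ("no_effect", "no_effect")]
        table = nine_category_analysis(pairs)
        assert table.expected[0, 0] == pytest.approx(1.0)  # 2 * 2 / 4

    def test_observed_equal_expected_gives_zero_chi2(self):
        pairs = []
        for ca in ("skip", "no_effect", "inclusion"):
            for cb in ("skip", "no_effect", "inclusion"):
                pairs.extend([(ca, cb)] * 4)
        table = nine_category_analysis(pairs)
        assert table.chi2 == pytest.approx(0.0)
        assert table.p_value == pytest.approx(1.0)

    def test_diagonal_toy_table(self):
        pairs = (
            [("skip", "skip")] * 10
            + [("no_effect", "no_effect")] * 10
            + [("inclusion", "inclusion")] * 10
        )
        table = nine_category_analysis(pairs)
        assert table.chi2 == pytest.approx(60.0)

    def test_marginal_conservation(self):
        rng = np.random.default_rng(3)
        classes = ("skip", "no_effect", "inclusion")
        pairs = [
            (classes[rng.integers(3)], classes[rng.integers(3)])
            for _ in range(200)
        ]
        table = nine_category_analysis(pairs)
        assert table.observed.sum() == pytest.approx(table.expected.sum())
        assert table.observed.sum() == 200

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(4)
        classes = ("skip", "no_effect", "inclusion")
        pairs = [
            (classes[rng.integers(3)], classes[rng.integers(3)])
            for _ in range(120)
        ]
        perm = {"skip": "inclusion", "inclusion": "skip",
                "no_effect": "no_effect"}
        relabeled = [(perm[a], perm[b]) for a, b in pairs]
        assert nine_category_analysis(pairs).chi2 == pytest.approx(
            nine_category_analysis(relabeled).chi2
        )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            nine_category_analysis([])


class TestOverlapIndependence:
    def test_expected_value(self):
        a = set(range(100))
        b = set(range(95, 145))
        obs, exp, _ = overlap_independence_test(a, b, 1000)
        assert obs == 5
        assert exp == pytest.approx(5.0)

    def test_symmetry_of_expectation(self):
        a, b = set(range(30)), set(range(20, 60))
        _, e1, _ = overlap_independence_test(a, b, 500)
        _, e2, _ = overlap_independence_test(b, a, 500)
        assert e1 == pytest.approx(e2)

    def test_chi_square_matches_hand_table(self):
        # |A|=100, |B|=50, N=1000, observed=20 -> 2x2 (20, 80, 30, 870)
        a = set(range(100))
        b = set(range(80, 130))
        obs, exp, p = overlap_independence_test(a, b, 1000)
        assert obs == 20
        table = np.array([[20, 80], [30, 870]], dtype=float)
        n = table.sum()
        e = np.outer(table.sum(1), table.sum(0)) / n
        chi2 = ((table - e) ** 2 / e).sum()
        from scipy.stats import chi2 as chi2_dist
        assert p == pytest.approx(chi2_dist.sf(chi2, 1))

    def test_universe_too_small_rejected(self):
        with pytest.raises(ValueError):
            overlap_independence_test(set(range(10)), set(range(5, 20)), 15)


class TestControlSet:
    def test_exact_zero_required(self):
        pairs = [("a1", "b1"), ("a2", "b2"), ("a3", "b3")]
        da = {"a1": (0.0, 0.0), "a2": (0.0, 0.01), "a3": (0.0, 0.0)}
        db = {"b1": (0.0, 0.0), "b2": (0.0, 0.0), "b3": (0.0, None)}
        assert build_control_set(pairs, da, db) == [("a1", "b1")]

    def test_empty_input(self):
        assert build_control_set([], {}, {}) == []


class TestFourWay:
    def _groups(self, rng, shift_ppt=0.0, n=40):
        def frame(loc_ppt):
            return pd.DataFrame(
                {
                    "exon_length": rng.normal(80, 10, n),
                    "ppt_score": rng.normal(loc_ppt, 3, n),
                }
            )
        return {
            "H_skip": frame(15 + shift_ppt),
            "M_paired": frame(15),
            "H_ctrl": frame(15),
            "M_ctrl": frame(15),
        }

    def test_null_false_positive_rate_near_alpha(self):
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(60):
            report = four_way_comparison(self._groups(rng), ["exon_length"])
            pvals.extend(report["p_value"])
        frac = np.mean(np.array(pvals) < 0.05)
        assert frac < 0.12  # ~5 % expected under the null

    def test_constructed_shift_detected_in_comparison_a(self):
        rng = np.random.default_rng(8)
        report = four_way_comparison(
            self._groups(rng, shift_ppt=-8.0), ["ppt_score"]
        )
        row = report[(report["feature"] == "ppt_score")
                     & (report["comparison"] == "A")].iloc[0]
        assert row["p_value"] < 0.001
        assert row["median1"] < row["median2"]  # direction: weaker tract

    def test_identical_groups_give_p_one(self):
        df = pd.DataFrame({"exon_length": [1.0, 2.0, 3.0]})
        groups = {g: df for g in ("H_skip", "M_paired", "H_ctrl", "M_ctrl")}
        report = four_way_comparison(groups, ["exon_length"])
        assert (report["p_value"] == 1.0).all()

    def test_paired_variant_detects_consistent_within_pair_shift(self):
        rng = np.random.default_rng(10)
        base = rng.normal(20, 6, 30)
        groups = {
            "H_skip": pd.DataFrame({"ppt_score": base - 2.0}),
            "M_paired": pd.DataFrame({"ppt_score": base}),
            "H_ctrl": pd.DataFrame({"ppt_score": rng.normal(20, 6, 30)}),
            "M_ctrl": pd.DataFrame({"ppt_score": rng.normal(20, 6, 30)}),
        }
        paired = four_way_comparison(groups, ["ppt_score"], paired_a=True)
        row = paired[paired["comparison"] == "A"].iloc[0]
        assert row["p_value"] < 0.001  # constant within-pair shift

    def test_empty_group_named_in_error(self):
        groups = self._groups(np.random.default_rng(9))
        groups["M_ctrl"] = pd.DataFrame()
        with pytest.raises(ValueError, match="M_ctrl"):
            four_way_comparison(groups)
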