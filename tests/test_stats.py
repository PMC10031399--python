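import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from welfarelca.aggregation import WQAssessment
from welfarelca.domain import BreedToFinishSystem, HusbandryType, LabelType
from welfarelca.errors import StatsInputError
from welfarelca.production import ProductionRecord
from welfarelca.stats import (
    GroupedSample,
    PairwiseComparison,
    compact_letters,
    compare_weightings,
    dunn_posthoc,
    holm_adjust,
    independent_subset,
    kruskal_wallis,
    rank_correlation_matrix,
    shared_farm_clusters,
    spearman_correlation,
)

# Frozen fixture: 3 groups of 12 with moderate separation and ties; chosen
# because the chi-squared / normal approximations agree with permutation
# references on it (verified when the fixture was frozen).
PERM_FIXTURE = {
    "g1": (-0.9, 0.5, 0.1, 0.7, -0.4, 0.2, 0.6, -0.3, 0.5, -0.7, -0.4, -0.4),
    "g2": (-0.7, 0.9, 0.0, 0.5, 0.9, 0.9, 1.1, 0.4, 0.0, 0.4, -1.2, -1.0),
    "g3": (-0.4, -0.1, 1.3, 0.0, 0.5, 2.2, 0.5, 1.6, 0.0, 0.7, -0.1, 0.6),
}


def _sample(data) -> GroupedSample:
    return GroupedSample.from_mapping(data)


class TestGroupedSample:
    def test_empty_group_rejected(self):
        with pytest.raises(StatsInputError, match="zero observations"):
            _sample({"a": [1.0], "b": []})

    def test_duplicate_labels_rejected(self):
        with pytest.raises(StatsInputError):
            GroupedSample(groups=("a", "a"), values=((1.0,), (2.0,)))


class TestKruskalWallis:
    def test_textbook_hand_formula(self):
        # ranks 1..9 -> mean ranks 2, 5, 8; H = 12/90 * (27 + 0 + 27) = 7.2
        result = kruskal_wallis(_sample({"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]}))
        assert result.H == pytest.approx(7.2, abs=1e-12)
        assert result.df == 2

    def test_identical_multisets_give_zero(self):
        result = kruskal_wallis(_sample({"a": [1, 2, 3], "b": [3, 1, 2]}))
        assert result.H == pytest.approx(0.0, abs=1e-12)

    def test_all_equal_convention(self):
        result = kruskal_wallis(_sample({"a": [5.0, 5.0], "b": [5.0, 5.0, 5.0]}))
        assert result.H == 0.0
        assert result.p_value == 1.0

    def test_single_group_rejected(self):
        with pytest.raises(StatsInputError):
            kruskal_wallis(_sample({"a": [1.0, 2.0]}))

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            groups = [
                np.round(rng.normal(mu, 1.0, rng.integers(4, 12)), 1)
                for mu in (0.0, 0.3, 0.8)
            ]
            ours = kruskal_wallis(
                _sample({i: g.tolist() for i, g in enumerate(groups)})
            )
            ref = sps.kruskal(*groups)
            assert ours.H == pytest.approx(ref.statistic, rel=1e-12)
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_against_permutation_reference(self):
        sample = _sample(PERM_FIXTURE)
        observed = kruskal_wallis(sample)

        # Independent permutation oracle: permuting observations among the
        # groups is equivalent to permuting the pooled midranks.
        pooled = np.concatenate([np.asarray(v) for v in PERM_FIXTURE.values()])
        ranks = sps.rankdata(pooled)
        n = len(pooled)
        _, counts = np.unique(pooled, return_counts=True)
        correction = 1.0 - (counts**3 - counts).sum() / (n**3 - n)

        def h_of(rank_matrix):
            means = [
                rank_matrix[:, i * 12 : (i + 1) * 12].mean(axis=1) for i in range(3)
            ]
            h = (12.0 / (n * (n + 1))) * sum(
                12 * (m - (n + 1) / 2.0) ** 2 for m in means
            )
            return h / correction

        rng = np.random.default_rng(2024)
        draws = 20_000
        perms = np.argsort(rng.random((draws, n)), axis=1)
        h_perm = h_of(ranks[perms])
        p_perm = float(np.mean(h_perm >= observed.H - 1e-12))
        se = np.sqrt(p_perm * (1 - p_perm) / draws)
        assert observed.p_value == pytest.approx(p_perm, abs=2 * se + 1e-9)

    def test_null_calibration_monte_carlo(self):
        # 3 groups of 10 from one distribution; rejection rate at alpha=0.05
        # must fall in the exact binomial 99% CI around 0.05.
        rng = np.random.default_rng(99)
        n_sims = 2000
        rejections = 0
        for _ in range(n_sims):
            groups = {i: rng.normal(0.0, 1.0, 10).tolist() for i in range(3)}
            if kruskal_wallis(_sample(groups)).p_value < 0.05 :
                rejections += 1
        lo, hi = sps.binom.ppf([0.005, 0.995], n_sims, 0.05)
        assert lo <= rejections <= hi


class TestDunnPosthoc:
    def test_hand_formula_no_ties(self):
        sample = _sample({"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]})
        comparisons = {(c.group_a, c.group_b): c for c in dunn_posthoc(sample)}
        # |z| for (a, c): (8 - 2) / sqrt((9*10/12) * (2/3)) = 6 / sqrt(5)
        assert abs(comparisons[("a", "c")].z_statistic) == pytest.approx(
            6.0 / np.sqrt(5.0), abs=1e-12
        )

    def test_identical_groups(self):
        sample = _sample({"a": [1, 2, 3], "b": [2, 1, 3]})
        (comparison,) = dunn_posthoc(sample)
        assert comparison.z_statistic == pytest.approx(0.0, abs=1e-12)
        assert comparison.p_raw == pytest.approx(1.0)

    def test_adjusted_at_least_raw(self):
        comparisons = dunn_posthoc(_sample(PERM_FIXTURE))
        for c in comparisons:
            assert c.p_adjusted >= c.p_raw - 1e-15

    def test_against_permutation_reference(self):
        sample = _sample(PERM_FIXTURE)
        comparisons = {(c.group_a, c.group_b): c for c in dunn_posthoc(sample)}
        target = comparisons[("g1", "g3")]

        pooled = np.concatenate([np.asarray(v) for v in PERM_FIXTURE.values()])
        ranks = sps.rankdata(pooled)
        n = len(pooled)
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = (counts**3 - counts).sum() / (12.0 * (n - 1))
        var = (n * (n + 1) / 12.0 - tie_term) * (1 / 12 + 1 / 12)

        rng = np.random.default_rng(77)
        draws = 20_000
        perms = np.argsort(rng.random((draws, n)), axis=1)
        permuted = ranks[perms]
        z_perm = (
            permuted[:, 0:12].mean(axis=1) - permuted[:, 24:36].mean(axis=1)
        ) / np.sqrt(var)
        p_perm = float(np.mean(np.abs(z_perm) >= abs(target.z_statistic) - 1e-12))
        se = np.sqrt(p_perm * (1 - p_perm) / draws)
        assert target.p_raw == pytest.approx(p_perm, abs=2 * se + 1e-9)


class TestHolmAdjust:
    def test_single_p_unchanged(self):
        assert holm_adjust([0.02]) == [0.02]

    def test_step_down_by_hand(self):
        # sorted [0.01, 0.02, 0.04] -> x3, x2, x1 -> [0.03, 0.04, 0.04]
        assert holm_adjust([0.01, 0.04, 0.02]) == pytest.approx([0.03, 0.04, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(StatsInputError):
            holm_adjust([0.5, 1.5])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.uniform(0, 1, rng.integers(1, 12)).tolist()
            _, expected, _, _ = multipletests(p, method="holm")
            assert holm_adjust(p) == pytest.approx(expected.tolist(), abs=1e-12)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12))
    def test_inflation_and_bonferroni_domination(self, p):
        adjusted = holm_adjust(p)
        m = len(p)
        for raw, adj in zip(p, adjusted):
            assert adj >= raw - 1e-15
            assert adj <= min(1.0, raw * m) + 1e-12  # Holm <= Bonferroni


def _fake_comparisons(groups, significant_pairs):
    comparisons = []
    for a, b in itertools.combinations(groups, 2):
        sig = {a, b} in significant_pairs
        comparisons.append(
            PairwiseComparison(
                group_a=a,
                group_b=b,
                z_statistic=3.0 if sig else 0.1,
                p_raw=0.001 if sig else 0.9,
                p_adjusted=0.003 if sig else 1.0,
                significant=sig,
            )
        )
    return comparisons


class TestCompactLetters:
    def test_no_significant_pairs(self):
        groups = ("A", "B", "C")
        letters = compact_letters(_fake_comparisons(groups, []), groups)
        assert letters == {"A": "a", "B": "a", "C": "a"}

    def test_all_pairs_significant(self):
        groups = ("A", "B", "C")
        pairs = [{"A", "B"}, {"A", "C"}, {"B", "C"}]
        letters = compact_letters(_fake_comparisons(groups, pairs), groups)
        assert sorted(letters.values()) == ["a", "b", "c"]

    def test_chain(self):
        # only A != C significant: brute-force minimal cover is a / ab / b
        groups = ("A", "B", "C")
        letters = compact_letters(_fake_comparisons(groups, [{"A", "C"}]), groups)
        assert letters == {"A": "a", "B": "ab", "C": "b"}

    def test_missing_pair_rejected(self):
        groups = ("A", "B", "C")
        comparisons = _fake_comparisons(groups, [])[:2]
        with pytest.raises(StatsInputError, match="missing"):
            compact_letters(comparisons, groups)

    def test_letter_sharing_matches_significance(self):
        # invariant check on random significance patterns
        rng = np.random.default_rng(8)
        groups = ("A", "B", "C", "D", "E")
        for _ in range(50):
            pairs = [
                {a, b}
                for a, b in itertools.combinations(groups, 2)
                if rng.random() < 0.4
            ]
            comparisons = _fake_comparisons(groups, pairs)
            letters = compact_letters(comparisons, groups)
            for c in comparisons:
                shares = bool(
                    set(letters[c.group_a]) & set(letters[c.group_b])
                )
                assert shares != c.significant, (pairs, letters)


class TestSpearman:
    def test_monotone_increasing(self):
        r, _ = spearman_correlation([1, 2, 3, 4], [10, 20, 30, 40])
        assert r == pytest.approx(1.0)

    def test_monotone_decreasing(self):
        r, _ = spearman_correlation([1, 2, 3, 4], [8, 6, 4, 2])
        assert r == pytest.approx(-1.0)

    def test_definitional_oracle_ten_pairs(self):
        x = [3.1, 0.2, 5.5, 2.2, 4.4, 1.0, 6.6, 0.0, 2.9, 3.3]
        y = [2.0, 1.1, 4.9, 3.3, 2.1, 0.5, 6.0, 1.0, 2.8, 5.5]
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]  # Pearson on midranks
        r, _ = spearman_correlation(x, y)
        assert r == pytest.approx(expected, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(StatsInputError):
            spearman_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_short_rejected(self):
        with pytest.raises(StatsInputError):
            spearman_correlation([1.0, 2.0], [1.0, 2.0])


def _mini_system(sid, breeding="", rearing=None):
    return BreedToFinishSystem(
        system_id=sid,
        labels_held=frozenset({"none"}),
        assigned_label=LabelType.NONE,
        husbandry=HusbandryType(breeding="indoor", finishing="slatted"),
        assessment_SP=WQAssessment(50, 50, 50, 50),
        assessment_FP=WQAssessment(50, 50, 50, 50),
        production=ProductionRecord(
            100, 2400, 2200, 28, 2100, 180, 88, 45, 75, 1.6, 0.8
        ),
        breeding_farm_id=breeding or f"B-{sid}",
        finishing_farm_id=f"F-{sid}",
        rearing_farm_id=rearing,
    )


class TestIndependentSubset:
    def test_no_sharing_keeps_all(self):
        systems = [_mini_system(f"S{i}") for i in range(5)]
        assert len(independent_subset(systems, seed=0)) == 5

    def test_one_shared_breeding_farm_merges_two(self):
        systems = [_mini_system(f"S{i}") for i in range(3)]
        systems += [_mini_system("S3", breeding="shared"), _mini_system("S4", breeding="shared")]
        subset = independent_subset(systems, seed=0)
        assert len(subset) == 4

    def test_transitive_cluster(self):
        a = _mini_system("A", breeding="B1")
        b = _mini_system("B", breeding="B1", rearing="R1")
        c = _mini_system("C", rearing="R1")
        subset = independent_subset([a, b, c], seed=0)
        assert len(subset) == 1
        assert subset[0].system_id in {"A", "B", "C"}

    def test_deterministic_under_seed(self):
        systems = [
            _mini_system(f"S{i}", breeding=f"B{i // 2}") for i in range(10)
        ]
        first = [s.system_id for s in independent_subset(systems, seed=42)]
        second = [s.system_id for s in independent_subset(systems, seed=42)]
        assert first == second

    def test_component_count_matches_networkx_oracle(self):
        import networkx as nx

        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(5, 30))
            systems = []
            for i in range(n):
                breeding = f"B{rng.integers(0, n)}" if rng.random() < 0.5 else ""
                rearing = f"R{rng.integers(0, n // 2 + 1)}" if rng.random() < 0.3 else None
                systems.append(_mini_system(f"S{i}", breeding=breeding, rearing=rearing))
            # oracle: bipartite system-farm graph, components restricted to systems
            graph = nx.Graph()
            for s in systems:
                graph.add_node(("sys", s.system_id))
                for fid in (s.breeding_farm_id, s.rearing_farm_id):
                    if fid:
                        graph.add_edge(("sys", s.system_id), ("farm", fid))
            expected = sum(
                1
                for comp in nx.connected_components(graph)
                if any(kind == "sys" for kind, _ in comp)
            )
            assert len(shared_farm_clusters(systems)) == expected
            assert len(independent_subset(systems, seed=1)) == expected


class TestRankCorrelationMatrix:
    def test_identical_rankings_all_one(self):
        import pandas as pd

        rows = []
        for i, sid in enumerate(["a", "b", "c", "d"]):
            for metric in ["m1", "m2"]:
                rows.append(
                    {"system_id": sid, "metric_id": metric, "cost": float(i)}
                )
        grid = pd.DataFrame(rows)
        wq = {"a": 9.0, "b": 7.0, "c": 5.0, "d": 3.0}
        r, _ = rank_correlation_matrix(grid, wq)
        assert r.loc["m1", "m2"] == pytest.approx(1.0)
        assert r.loc["m1", "m1"] == pytest.approx(1.0)
        assert r.loc["m1", "overall_wq"] == pytest.approx(-1.0)

    def test_missing_cells_rejected(self):
        import pandas as pd

        grid = pd.DataFrame(
            [
                {"system_id": "a", "metric_id": "m1", "cost": 1.0},
                {"system_id": "b", "metric_id": "m1", "cost": 2.0},
                {"system_id": "a", "metric_id": "m2", "cost": 1.0},
            ]
        )
        with pytest.raises(StatsInputError):
            rank_correlation_matrix(grid, {"a": 1.0, "b": 2.0})


class TestCompareWeightings:
    def test_identical_costs_across_weightings(self):
        import pandas as pd

        rows = [
            {"system_id": f"s{i}", "metric_id": f"T100/{w}", "transition": "T100",
             "weighting": w, "cost": float(i)}
            for i in range(6)
            for w in ("standard", "equal", "extreme")
        ]
        result = compare_weightings(pd.DataFrame(rows), "T100")
        assert result.H == pytest.approx(0.0, abs=1e-9)
        assert result.p_value == pytest.approx(1.0)

    def test_shifted_weighting_detected(self):
        import pandas as pd

        rows = []
        for i in range(12):
            for w in ("standard", "equal"):
                cost = float(i) + (100.0 if w == "equal" else 0.0)
                rows.append(
                    {"system_id": f"s{i}", "metric_id": f"T100/{w}",
                     "transition": "T100", "weighting": w, "cost": cost}
                )
        result = compare_weightings(pd.DataFrame(rows), "T100")
        assert result.p_value < 0.01

    def test_unknown_transition_rejected(self):
        import pandas as pd

        with pytest.raises(StatsInputError):
            compare_weightings(
                pd.DataFrame(columns=["transition", "weighting", "cost"]), "T100"
            )
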