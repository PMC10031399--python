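"""Nonparametric statistics for the metric-robustness analysis.

Kruskal-Wallis omnibus tests (tie-corrected, midranks), Dunn's post hoc
z-tests with Holm step-down adjustment, compact letter displays, Spearman
rank correlations across metric variants, and one-per-cluster selection of
independent systems from the shared-farm graph.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from welfarelca.domain import BreedToFinishSystem
from welfarelca.errors import StatsInputError

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class GroupedSample:
    """Values partitioned into named groups."""

    groups: tuple[Hashable, ...]
    values: tuple[tuple[float, ...], ...]

    @classmethod
    def from_mapping(cls, data: Mapping[Hashable, Sequence[float]]) -> "GroupedSample":
        return cls(
            groups=tuple(data.keys()),
            values=tuple(tuple(float(v) for v in vs) for vs in data.values()),
        )

    def __post_init__(self) -> None:
        if len(self.groups) != len(self.values):
            raise StatsInputError("groups and values must align")
        if len(self.groups) != len(set(self.groups)):
            raise StatsInputError("duplicate group labels")
        for g, vs in zip(self.groups, self.values):
            if len(vs) == 0:
                raise StatsInputError(f"group {g!r} has zero observations")

    @property
    def n_total(self) -> int:
        return sum(len(vs) for vs in self.values)


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: Hashable
    group_b: Hashable
    z_statistic: float
    p_raw: float
    p_adjusted: float
    significant: bool


@dataclass(frozen=True)
class KruskalWallisResult:
    H: float
    df: int
    p_value: float


def _midranks(sample: GroupedSample) -> tuple[np.ndarray, list[np.ndarray], float]:
    """Pooled midranks split back per group, plus the tie-correction sum."""
    pooled = np.concatenate([np.asarray(vs, dtype=float) for vs in sample.values])
    ranks = sps.rankdata(pooled, method="average")
    per_group: list[np.ndarray] = []
    start = 0
    for vs in sample.values:
        per_group.append(ranks[start : start + len(vs)])
        start += len(vs)
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    return ranks, per_group, tie_sum


def kruskal_wallis(sample: GroupedSample) -> KruskalWallisResult:
    """Tie-corrected Kruskal-Wallis H test.

    ``df = k - 1``; p from the chi-squared reference distribution.  When
    every observation is identical the tie-corrected denominator vanishes;
    by convention H = 0 and p = 1.
    """
    if len(sample.groups) < 2:
        raise StatsInputError("Kruskal-Wallis requires at least two groups")
    n = sample.n_total
    _, per_group, tie_sum = _midranks(sample)
    h = 12.0 / (n * (n + 1)) * sum(
        len(r) * (r.mean() - (n + 1) / 2.0) ** 2 for r in per_group
    )
    correction = 1.0 - tie_sum / (n**3 - n)
    if correction <= 0.0:  # all observations identical
        h = 0.0
    else:
        h /= correction
    df = len(sample.groups) - 1
    p = float(sps.chi2.sf(h, df)) if h > 0 else 1.0
    return KruskalWallisResult(H=float(h), df=df, p_value=p)


def dunn_posthoc(
    sample: GroupedSample, alpha: float = DEFAULT_ALPHA
) -> list[PairwiseComparison]:
    """All-pairs Dunn z-tests on pooled midranks, Holm-adjusted.

    ``z_ab = (R̄_a - R̄_b) / sqrt((N(N+1)/12 - tie_term) (1/n_a + 1/n_b))``
    with ``tie_term = Σ(t³ - t) / (12 (N - 1))``; two-sided normal p-values;
    the Holm family is the full set of pairwise comparisons of this sample.
    """
    if len(sample.groups) < 2:
        raise StatsInputError("Dunn's test requires at least two groups")
    n = sample.n_total
    _, per_group, tie_sum = _midranks(sample)
    tie_term = tie_sum / (12.0 * (n - 1)) if n > 1 else 0.0
    base_var = n * (n + 1) / 12.0 - tie_term

    pairs = list(itertools.combinations(range(len(sample.groups)), 2))
    z_values: list[float] = []
    p_raw: list[float] = []
    for i, j in pairs:
        ri, rj = per_group[i], per_group[j]
        var = base_var * (1.0 / len(ri) + 1.0 / len(rj))
        if var <= 0.0:  # all observations identical
            z = 0.0
        else:
            z = (ri.mean() - rj.mean()) / np.sqrt(var)
        z_values.append(float(z))
        p_raw.append(float(2.0 * sps.norm.sf(abs(z))))
    p_adj = holm_adjust(p_raw)
    return [
        PairwiseComparison(
            group_a=sample.groups[i],
            group_b=sample.groups[j],
            z_statistic=z,
            p_raw=pr,
            p_adjusted=pa,
            significant=pa < alpha,
        )
        for (i, j), z, pr, pa in zip(pairs, z_values, p_raw, p_adj)
    ]


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values, returned in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise StatsInputError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m, dtype=float)
    running_max = 0.0
    for i, idx in enumerate(order):
        value = min(1.0, (m - i) * p[idx])
        running_max = max(running_max, value)
        adjusted[idx] = running_max
    return adjusted.tolist()


def compact_letters(
    comparisons: Sequence[PairwiseComparison],
    groups: Sequence[Hashable],
) -> dict[Hashable, str]:
    """Compact letter display via the insert-and-absorb algorithm.

    Two groups share a letter iff their pairwise comparison is not
    significant.  Deterministic given the group ordering.
    """
    significant: dict[frozenset, bool] = {}
    for c in comparisons:
        significant[frozenset((c.group_a, c.group_b))] = c.significant
    for a, b in itertools.combinations(groups, 2):
        if frozenset((a, b)) not in significant:
            raise StatsInputError(f"missing pairwise comparison ({a!r}, {b!r})")

    def differ(a: Hashable, b: Hashable) -> bool:
        return significant[frozenset((a, b))]

    # Start with one letter-set containing every group; for each significant
    # pair occurring together in a set, split the set; absorb subsets.
    letter_sets: list[set] = [set(groups)]
    for a, b in itertools.combinations(groups, 2):
        if not differ(a, b):
            continue
        for s in [s for s in letter_sets if a in s and b in s]:
            letter_sets.remove(s)
            sa, sb = s - {b}, s - {a}
            for candidate in (sa, sb):
                if not any(candidate <= other for other in letter_sets):
                    letter_sets.append(candidate)
    # Deterministic ordering: by first member's position in `groups`.
    position = {g: i for i, g in enumerate(groups)}
    letter_sets.sort(key=lambda s: sorted(position[g] for g in s))
    letters = "abcdefghijklmnopqrstuvwxyz"
    display: dict[Hashable, str] = {g: "" for g in groups}
    for letter, s in zip(letters, letter_sets):
        for g in groups:
            if g in s:
                display[g] += letter
    return display


def spearman_correlation(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Spearman rank correlation (Pearson on midranks, t-approximation p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise StatsInputError("need paired samples of equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatsInputError("rank correlation undefined for constant input")
    result = sps.spearmanr(x, y)
    return float(result.statistic), float(result.pvalue)


def shared_farm_clusters(
    systems: Sequence[BreedToFinishSystem],
) -> list[list[BreedToFinishSystem]]:
    """Connected components of the graph linking systems that share a
    breeding or rearing farm id."""
    parent = list(range(len(systems)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    by_farm: dict[str, int] = {}
    for idx, system in enumerate(systems):
        for fid in (system.breeding_farm_id, system.rearing_farm_id):
            if not fid:
                continue
            if fid in by_farm:
                union(by_farm[fid], idx)
            else:
                by_farm[fid] = idx

    # dict preserves insertion order, so clusters come out ordered by the
    # first appearance of any of their members.
    clusters: dict[int, list[BreedToFinishSystem]] = {}
    for idx, system in enumerate(systems):
        clusters.setdefault(find(idx), []).append(system)
    return list(clusters.values())


def independent_subset(
    systems: Sequence[BreedToFinishSystem],
    seed: int | np.random.Generator | None = None,
) -> list[BreedToFinishSystem]:
    """One uniformly-random system per shared-farm cluster.

    Deterministic under a fixed seed; the output size equals the number of
    connected components of the sharing graph.
    """
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator
    ) else seed
    chosen = []
    for cluster in shared_farm_clusters(systems):
        chosen.append(cluster[int(rng.integers(len(cluster)))])
    order = {id(s): i for i, s in enumerate(systems)}
    chosen.sort(key=lambda s: order[id(s)])
    return chosen


def rank_correlation_matrix(
    grid: pd.DataFrame,
    overall_wq: Mapping[str, float] | pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman correlations of system orderings across metric variants.

    ``grid`` is :func:`welfarelca.metrics.metric_grid` output.  Returns a
    pair of square DataFrames ``(r_s, p)`` indexed by metric_id plus a
    final ``overall_wq`` row/column.  Overall WQ scores high = good while
    costs high = bad, so the WQ column is typically negative.
    """
    wide = grid.pivot(index="system_id", columns="metric_id", values="cost")
    if wide.isna().any().any():
        missing = wide.columns[wide.isna().any()].tolist()
        raise StatsInputError(f"missing costs for metric(s) {missing}")
    wq = pd.Series(dict(overall_wq), dtype=float)
    if not set(wide.index) <= set(wq.index):
        raise StatsInputError("overall WQ scores missing for some systems")
    table = wide.copy()
    table["overall_wq"] = wq.reindex(wide.index)

    cols = list(table.columns)
    k = len(cols)
    r = np.ones((k, k))
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            r_ij, p_ij = spearman_correlation(
                table[cols[i]].to_numpy(), table[cols[j]].to_numpy()
            )
            r[i, j] = r[j, i] = r_ij
            p[i, j] = p[j, i] = p_ij
    r_frame = pd.DataFrame(r, index=cols, columns=cols)
    p_frame = pd.DataFrame(p, index=cols, columns=cols)
    return r_frame, p_frame


def compare_weightings(
    grid: pd.DataFrame, transition: str = "T100"
) -> KruskalWallisResult:
    """Kruskal-Wallis on per-system costs grouped by weighting scheme,
    at a fixed transition — the weighting-insensitivity check."""
    subset = grid[grid["transition"] == transition]
    if subset.empty:
        raise StatsInputError(f"no grid rows with transition {transition!r}")
    data = {
        weighting: frame["cost"].tolist()
        for weighting, frame in subset.groupby("weighting", sort=True)
    }
    if len(data) < 2:
        raise StatsInputError("need at least two weighting variants")
    return kruskal_wallis(GroupedSample.from_mapping(data))


def grouped_sample_from_systems(
    systems: Iterable[BreedToFinishSystem],
    values: Mapping[str, float],
    group_of,
) -> GroupedSample:
    """Build a GroupedSample from systems, a per-system value mapping and a
    grouping function ``system -> label``."""
    data: dict[Hashable, list[float]] = {}
    for system in systems:
        data.setdefault(group_of(system), []).append(values[system.system_id])
    return GroupedSample.from_mapping(data)
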