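"""Permutation tests for pairwise median location shifts among groups.

The single-step procedure pools all values, repeatedly reassigns them to
groups at the observed sizes, and refers every pairwise absolute median
difference to the permutation distribution of the *maximum* pairwise
difference.  This gives strong familywise error control without assuming
normality or equal sample sizes.  The step-down variant retests each
hypothesis, in decreasing order of the observed statistic, against nulls
restricted to the maximal group subsets still jointly consistent with all
not-yet-rejected hypotheses, taking the most conservative (largest)
candidate p at each step; it is uniformly at least as powerful as the
single-step procedure under a shared permutation stream.

Monte Carlo p-values use the add-one convention ``(1 + count) / (B + 1)``
and therefore live in ``[1/(B+1), 1]``.  An exact enumeration oracle over
all labeled assignments is provided for small instances.

Conventions fixed for reproducibility: the median of an even-sized group
is the midpoint of the two central order statistics; quartiles use linear
interpolation; ties are kept as-is (no jitter); permutations are sampled
with replacement from the assignment space.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
from scipy import stats

from ._errors import ConfigError, EmptySelectionError, SizeGuardError
from .io_dataset import GroupedSample

log = logging.getLogger(__name__)

METHODS = ("single_step", "step_down_cms")

#: Absolute slack when comparing permuted max-statistics with an observed
#: statistic; both sides come from medians of the same pooled values, so
#: only representation noise is absorbed.  Errs on the conservative side.
_TIE_EPS = 1e-12


@dataclass(frozen=True)
class PermutationConfig:
    """Settings for the Monte Carlo permutation tests."""

    n_permutations: int = 10_000
    seed: int = 0
    alpha: float = 0.05
    method: str = "single_step"
    chunk_size: int = 1024

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must be in (0, 1)")
        if self.method not in METHODS:
            raise ConfigError(f"method must be one of {METHODS}")
        if self.chunk_size < 1:
            raise ConfigError("chunk_size must be >= 1")


Pair = tuple[str, str]


@dataclass
class PairwiseMedianResult:
    """All-pairs adjusted p-values for median differences among groups."""

    group_labels: tuple[str, ...]
    group_sizes: tuple[int, ...]
    medians: dict[str, float]
    d: dict[Pair, float]
    p_adjusted: dict[Pair, float]
    alpha: float
    method: str
    n_permutations: int | None  # None for the exhaustive oracle
    seed: int | None
    variable: str | None = None

    @property
    def pairs(self) -> tuple[Pair, ...]:
        return tuple(self.d)

    @property
    def rejected(self) -> dict[Pair, bool]:
        return {pair: p <= self.alpha for pair, p in self.p_adjusted.items()}

    def _key(self, a: str, b: str) -> Pair:
        if (a, b) in self.d:
            return (a, b)
        if (b, a) in self.d:
            return (b, a)
        raise KeyError(f"no comparison between {a!r} and {b!r}")

    def p(self, a: str, b: str) -> float:
        """Adjusted p-value for the (symmetric) pair ``a``, ``b``."""
        return self.p_adjusted[self._key(a, b)]

    def statistic(self, a: str, b: str) -> float:
        return self.d[self._key(a, b)]

    def to_rows(self) -> list[dict]:
        """Long-format rows (one per pair) for CSV output."""
        sizes = dict(zip(self.group_labels, self.group_sizes))
        rows = []
        for (a, b), d_ab in self.d.items():
            rows.append(
                {
                    "variable": self.variable or "",
                    "group_a": a,
                    "group_b": b,
                    "n_a": sizes[a],
                    "n_b": sizes[b],
                    "median_a": self.medians[a],
                    "median_b": self.medians[b],
                    "d": d_ab,
                    "p_adjusted": self.p_adjusted[(a, b)],
                    "rejected": self.p_adjusted[(a, b)] <= self.alpha,
                    "method": self.method,
                    "B": "" if self.n_permutations is None else self.n_permutations,
                    "seed": "" if self.seed is None else self.seed,
                }
            )
        return rows


# ---------------------------------------------------------------------------
# internals


def _check_sample(sample: GroupedSample) -> tuple[np.ndarray, tuple[str, ...], tuple[int, ...]]:
    labels = sample.labels
    if len(labels) < 2:
        raise EmptySelectionError("need at least two groups to compare medians")
    sizes = sample.sizes
    pooled = np.concatenate([sample.groups[label] for label in labels])
    return pooled, labels, sizes


def _observed(sample: GroupedSample) -> tuple[dict[str, float], dict[Pair, float]]:
    medians = {label: float(np.median(values)) for label, values in sample.groups.items()}
    labels = sample.labels
    d = {
        (a, b): abs(medians[a] - medians[b])
        for a, b in combinations(labels, 2)
    }
    return medians, d


def _permuted_pair_stats(
    pooled: np.ndarray,
    sizes: tuple[int, ...],
    n_permutations: int,
    rng: np.random.Generator,
    chunk_size: int,
) -> np.ndarray:
    """(B, n_pairs) matrix of pairwise |median difference| under random
    reassignment of the pooled values to groups at the observed sizes."""
    k = len(sizes)
    bounds = np.concatenate(([0], np.cumsum(sizes)))
    n_pairs = k * (k - 1) // 2
    out = np.empty((n_permutations, n_pairs))
    done = 0
    while done < n_permutations:
        m = min(chunk_size, n_permutations - done)
        mat = rng.permuted(np.tile(pooled, (m, 1)), axis=1)
        meds = np.empty((m, k))
        for g in range(k):
            meds[:, g] = np.median(mat[:, bounds[g] : bounds[g + 1]], axis=1)
        col = 0
        for i in range(k):
            for j in range(i + 1, k):
                out[done : done + m, col] = np.abs(meds[:, i] - meds[:, j])
                col += 1
        done += m
    return out


def _mc_p(count: int, n_permutations: int) -> float:
    return (1 + count) / (n_permutations + 1)


def _assert_monotone(d: dict[Pair, float], p: dict[Pair, float]) -> None:
    # d_ij >= d_kl must imply p_ij <= p_kl within a single-step result
    order = sorted(d, key=lambda pair: -d[pair])
    for first, second in zip(order, order[1:]):
        if p[first] > p[second] + 1e-12:
            raise AssertionError(
                "single-step p-values are not monotone in the observed statistic"
            )


# ---------------------------------------------------------------------------
# tests


def single_step_median_test(
    sample: GroupedSample, config: PermutationConfig | None = None
) -> PairwiseMedianResult:
    """All pairwise median comparisons against one max-statistic null.

    Adjusted ``p_ij = (1 + #{b : D_b >= d_ij}) / (B + 1)`` where ``D_b`` is
    the maximum pairwise absolute median difference in permutation ``b``.
    """
    config = config or PermutationConfig()
    pooled, labels, sizes = _check_sample(sample)
    medians, d = _observed(sample)
    if all(v == pooled[0] for v in pooled):
        log.info("all pooled values identical; every adjusted p is 1")
    rng = np.random.default_rng(config.seed)
    pair_stats = _permuted_pair_stats(
        pooled, sizes, config.n_permutations, rng, config.chunk_size
    )
    max_stat = pair_stats.max(axis=1)
    p_adjusted = {
        pair: _mc_p(int(np.sum(max_stat >= d_ab - _TIE_EPS)), config.n_permutations)
        for pair, d_ab in d.items()
    }
    _assert_monotone(d, p_adjusted)
    return PairwiseMedianResult(
        group_labels=labels,
        group_sizes=sizes,
        medians=medians,
        d=d,
        p_adjusted=p_adjusted,
        alpha=config.alpha,
        method="single_step",
        n_permutations=config.n_permutations,
        seed=config.seed,
        variable=sample.variable,
    )


def step_down_cms_test(
    sample: GroupedSample, config: PermutationConfig | None = None
) -> PairwiseMedianResult:
    """Step-down variant (conservative maximal subsets).

    Hypotheses are visited in decreasing order of the observed statistic.
    For the current pair, every maximal subset of groups that is still
    jointly consistent with the not-yet-rejected hypotheses and contains
    both groups defines a candidate null: the permutation max-statistic
    restricted to pairs within that subset, computed on the shared
    permutation stream.  The largest candidate p is taken and adjusted
    p-values are enforced monotone non-decreasing down the ordering, so
    for every pair ``p_stepdown <= p_singlestep`` at the same seed.
    """
    config = config or PermutationConfig()
    pooled, labels, sizes = _check_sample(sample)
    medians, d = _observed(sample)
    rng = np.random.default_rng(config.seed)
    pair_stats = _permuted_pair_stats(
        pooled, sizes, config.n_permutations, rng, config.chunk_size
    )
    pair_index = {pair: idx for idx, pair in enumerate(combinations(labels, 2))}

    graph = nx.complete_graph(labels)
    order = sorted(d, key=lambda pair: (-d[pair], pair))
    p_adjusted: dict[Pair, float] = {}
    running_max = 0.0
    for a, b in order:
        d_ab = d[(a, b)]
        candidate = 0.0
        for clique in nx.find_cliques(graph):
            if a not in clique or b not in clique:
                continue
            cols = [
                pair_index[pair]
                for pair in combinations(labels, 2)
                if pair[0] in clique and pair[1] in clique
            ]
            subset_max = pair_stats[:, cols].max(axis=1)
            p = _mc_p(int(np.sum(subset_max >= d_ab - _TIE_EPS)), config.n_permutations)
            candidate = max(candidate, p)
        running_max = max(running_max, candidate)
        p_adjusted[(a, b)] = running_max
        if running_max <= config.alpha:
            graph.remove_edge(a, b)
    return PairwiseMedianResult(
        group_labels=labels,
        group_sizes=sizes,
        medians=medians,
        d=d,
        p_adjusted=p_adjusted,
        alpha=config.alpha,
        method="step_down_cms",
        n_permutations=config.n_permutations,
        seed=config.seed,
        variable=sample.variable,
    )


def run_median_test(
    sample: GroupedSample, config: PermutationConfig | None = None
) -> PairwiseMedianResult:
    """Dispatch on ``config.method``."""
    config = config or PermutationConfig()
    if config.method == "single_step":
        return single_step_median_test(sample, config)
    return step_down_cms_test(sample, config)


# ---------------------------------------------------------------------------
# exact oracle


def _multinomial(sizes: tuple[int, ...]) -> int:
    total = sum(sizes)
    count = math.factorial(total)
    for s in sizes:
        count //= math.factorial(s)
    return count


def _labeled_assignments(indices: tuple[int, ...], sizes: tuple[int, ...]):
    if len(sizes) == 1:
        yield (indices,)
        return
    for head in combinations(indices, sizes[0]):
        head_set = set(head)
        rest = tuple(i for i in indices if i not in head_set)
        for tail in _labeled_assignments(rest, sizes[1:]):
            yield (head,) + tail


def exhaustive_null(
    sample: GroupedSample, *, max_assignments: int = 1_000_000
) -> PairwiseMedianResult:
    """Exact single-step p-values by enumerating every labeled assignment
    of the pooled values to groups at the observed sizes.

    ``p_ij = #{assignments : D >= d_ij} / (total assignments)`` where D is
    the max pairwise absolute median difference of the assignment.  Guarded
    by ``max_assignments`` (default 10^6).
    """
    pooled, labels, sizes = _check_sample(sample)
    total = _multinomial(sizes)
    if total > max_assignments:
        raise SizeGuardError(
            f"{total} labeled assignments exceed the guard of {max_assignments}"
        )
    medians, d = _observed(sample)
    k = len(sizes)
    max_stats = np.empty(total)
    for idx, assignment in enumerate(
        _labeled_assignments(tuple(range(pooled.size)), sizes)
    ):
        meds = [np.median(pooled[list(group)]) for group in assignment]
        max_stats[idx] = max(
            abs(meds[i] - meds[j]) for i in range(k) for j in range(i + 1, k)
        )
    p_adjusted = {
        pair: float(np.sum(max_stats >= d_ab - _TIE_EPS)) / total
        for pair, d_ab in d.items()
    }
    return PairwiseMedianResult(
        group_labels=labels,
        group_sizes=sizes,
        medians=medians,
        d=d,
        p_adjusted=p_adjusted,
        alpha=0.05,
        method="exhaustive",
        n_permutations=None,
        seed=None,
        variable=sample.variable,
    )


# ---------------------------------------------------------------------------
# distribution diagnostics


@dataclass(frozen=True)
class GroupMoments:
    """Shape diagnostics for one group.

    ``skewness`` is the moment coefficient g1 = m3 / m2^(3/2) and
    ``excess_kurtosis`` is g2 = m4 / m2^2 - 3 (central sample moments);
    both are NaN when undefined (too few values or zero variance).
    """

    label: str
    n: int
    median: float
    q1: float
    q3: float
    minimum: float
    maximum: float
    skewness: float
    excess_kurtosis: float


MomentsSummary = list[GroupMoments]


def group_moments(sample: GroupedSample) -> MomentsSummary:
    """Per-group medians, quartiles (linear interpolation) and moment-based
    skewness/kurtosis; skew needs n >= 3 and kurtosis n >= 4."""
    rows: MomentsSummary = []
    for label, values in sample.groups.items():
        n = values.size
        q1, med, q3 = np.percentile(values, [25, 50, 75])
        zero_var = np.all(values == values[0])
        g1 = float(stats.skew(values, bias=True)) if n >= 3 and not zero_var else math.nan
        g2 = (
            float(stats.kurtosis(values, fisher=True, bias=True))
            if n >= 4 and not zero_var
            else math.nan
        )
        rows.append(
            GroupMoments(
                label=label,
                n=int(n),
                median=float(med),
                q1=float(q1),
                q3=float(q3),
                minimum=float(values.min()),
                maximum=float(values.max()),
                skewness=g1,
                excess_kurtosis=g2,
            )
        )
    return rows
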