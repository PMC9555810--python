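"""Rank-sum comparison of Kano category distributions between two groups.

Each respondent contributes their classified category for an attribute;
categories are mapped to ordinal demand scores (default, from most to
least demanding of provision: M=5, O=4, A=3, I=2, R=1, Q=0) and the two
groups are compared with a two-sided Wilcoxon/Mann-Whitney rank-sum test.
Mid-ranks are used for ties and the normal approximation uses the
tie-corrected variance

    Var(W) = n_a n_b / 12 * [ (N + 1) - sum(t^3 - t) / (N (N - 1)) ]

with N = n_a + n_b and t the tie-group sizes.  For tiny samples
(N <= 12) the exact permutation null of the rank sum is enumerated
instead.  The statistic is reported as a magnitude; no continuity
correction and no multiplicity adjustment by default.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core import build_evaluation_table, classify_pair, tabulate_attribute
from .dataset import SurveyDataset
from .types import AttributeCounts, KanoCategory

__all__ = [
    "DEFAULT_ENCODING",
    "encode_categories",
    "rank_sum_test",
    "compare_groups",
    "ComparisonResult",
]

#: default ordinal encoding, descending demand intensity
DEFAULT_ENCODING: dict[KanoCategory, float] = {
    KanoCategory.MUST_BE: 5,
    KanoCategory.ONE_DIMENSIONAL: 4,
    KanoCategory.ATTRACTIVE: 3,
    KanoCategory.INDIFFERENT: 2,
    KanoCategory.REVERSE: 1,
    KanoCategory.QUESTIONABLE: 0,
}

EXACT_MAX_N = 12


@dataclass(frozen=True)
class ComparisonResult:
    """One attribute's two-group rank-sum comparison."""

    attribute_id: int
    z_statistic: float
    p_value: float
    group_sizes: dict[str, int]
    group_counts: dict[str, AttributeCounts]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


def encode_categories(
    categories: Sequence[KanoCategory],
    encoding: Mapping[KanoCategory, float] | None = None,
) -> list[float]:
    """Map categories to ordinal scores elementwise."""
    if encoding is None:
        encoding = DEFAULT_ENCODING
    out = []
    for c in categories:
        c = KanoCategory.coerce(c)
        if c not in encoding:
            raise ValueError(f"encoding has no score for category {c.value}")
        out.append(float(encoding[c]))
    return out


def _exact_rank_sum_p(pooled_ranks: np.ndarray, n_a: int, w_obs: float) -> float:
    """Two-sided permutation p for the group-a rank sum, enumerating all
    C(N, n_a) assignments of the pooled (mid-)ranks."""
    n = len(pooled_ranks)
    e_w = n_a * (n + 1) / 2.0
    dev = abs(w_obs - e_w)
    hits = total = 0
    for combo in itertools.combinations(range(n), n_a):
        total += 1
        w = pooled_ranks[list(combo)].sum()
        if abs(w - e_w) >= dev - 1e-9:
            hits += 1
    return hits / total


def rank_sum_test(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    *,
    continuity: bool = False,
    exact_max_n: int = EXACT_MAX_N,
) -> tuple[float, float]:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum test; returns (|Z|, p).

    Mid-ranks for ties; tie-corrected variance in the normal approximation;
    exact permutation enumeration when the pooled sample is small.  Two
    identical-score groups give Z=0, p=1 with a warning.
    """
    xa = np.asarray(scores_a, dtype=float)
    xb = np.asarray(scores_b, dtype=float)
    if xa.size == 0 or xb.size == 0:
        raise ValueError("both groups must be non-empty")

    pooled = np.concatenate([xa, xb])
    n_a, n = xa.size, pooled.size
    ranks = stats.rankdata(pooled)
    w = float(ranks[:n_a].sum())
    e_w = n_a * (n + 1) / 2.0

    _, tie_sizes = np.unique(pooled, return_counts=True)
    tie_term = float((tie_sizes.astype(float) ** 3 - tie_sizes).sum())
    var_w = n_a * (n - n_a) / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))

    if var_w <= 0:
        warnings.warn(
            "all observations identical across both groups; Z=0, p=1",
            stacklevel=2,
        )
        return 0.0, 1.0

    dev = abs(w - e_w)
    if continuity:
        dev = max(dev - 0.5, 0.0)
    z = dev / math.sqrt(var_w)

    if n <= exact_max_n:
        p = _exact_rank_sum_p(ranks, n_a, w)
    else:
        p = float(2.0 * stats.norm.sf(z))
    return z, min(p, 1.0)


def compare_groups(
    dataset: SurveyDataset,
    covariate: str,
    encoding: Mapping[KanoCategory, float] | None = None,
    *,
    include_q: bool = True,
    continuity: bool = False,
    adjust: str | None = None,
) -> list[ComparisonResult]:
    """Rank-sum comparison of every attribute's category distribution
    between the two levels of ``covariate``.

    Q-classified respondents are included by default (their counts are part
    of the published group rows); ``include_q=False`` drops them.  ``adjust``
    may name a multiple-testing method ('holm' or 'fdr_bh'); the default is
    no adjustment, one unadjusted test per attribute.
    """
    values = dataset.covariate(covariate)
    groups = sorted(values.dropna().unique())
    if len(groups) != 2:
        raise ValueError(
            f"covariate {covariate!r} must have exactly two levels, got {list(groups)}"
        )
    table = build_evaluation_table()
    masks = {g: (values == g).to_numpy() for g in groups}

    results: list[ComparisonResult] = []
    for k in dataset.attribute_ids:
        pairs = dataset.pairs_for_attribute(k)
        cats = np.array([classify_pair(p, table).value for p in pairs])
        per_group_scores: dict[str, list[float]] = {}
        per_group_counts: dict[str, AttributeCounts] = {}
        for g in groups:
            g_cats = [KanoCategory(c) for c in cats[masks[g]]]
            per_group_counts[g] = tabulate_attribute(
                [pairs[j] for j in np.flatnonzero(masks[g])], k, table
            )
            if not include_q:
                g_cats = [c for c in g_cats if c is not KanoCategory.QUESTIONABLE]
            per_group_scores[g] = encode_categories(g_cats, encoding)
        z, p = rank_sum_test(
            per_group_scores[groups[0]], per_group_scores[groups[1]], continuity=continuity
        )
        results.append(
            ComparisonResult(
                attribute_id=k,
                z_statistic=z,
                p_value=p,
                group_sizes={g: len(per_group_scores[g]) for g in groups},
                group_counts=per_group_counts,
            )
        )

    if adjust is not None:
        from statsmodels.stats.multitest import multipletests

        _, p_adj, _, _ = multipletests([r.p_value for r in results], method=adjust)
        results = [
            ComparisonResult(
                attribute_id=r.attribute_id,
                z_statistic=r.z_statistic,
                p_value=float(p),
                group_sizes=r.group_sizes,
                group_counts=r.group_counts,
            )
            for r, p in zip(results, p_adj)
        ]
    return results
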