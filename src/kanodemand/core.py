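"""Kano evaluation table, pair classification and per-attribute statistics.

The evaluation table maps every (functional, dysfunctional) answer pair to
a quality category.  Per attribute we then report:

* **final category** — the modal category among {M, O, A, I, R};
* **category strength** — the gap between the top two category frequencies,
  as a percent of all respondents;
* **total strength** — percent of respondents in M, O or A (the share of
  respondents who want the service);
* **Better** = (A+O)/(A+O+M+I) — expected satisfaction gain from providing
  the service;
* **Worse** = (O+M)/(A+O+M+I) — expected dissatisfaction from withholding it.

Better/Worse exclude R and Q from both numerator and denominator; category
and total strength are taken over the full respondent count including R
and Q.
"""

from __future__ import annotations

from collections import Counter
from typing import TYPE_CHECKING, Iterable, Sequence

from .types import (
    FINAL_CATEGORY_PRIORITY,
    AttributeCounts,
    AttributeMetrics,
    KanoCategory,
    LikertLevel,
    ResponsePair,
    round_half_away,
)

if TYPE_CHECKING:  # pragma: no cover
    from .dataset import SurveyDataset

__all__ = [
    "EvaluationTable",
    "build_evaluation_table",
    "classify_pair",
    "tabulate_attribute",
    "final_category",
    "category_strength",
    "total_strength",
    "better_coefficient",
    "worse_coefficient",
    "analyze_attribute",
    "analyze_survey",
]

EvaluationTable = dict[tuple[LikertLevel, LikertLevel], KanoCategory]

# rows: functional answer LIKE..DISLIKE; columns: dysfunctional LIKE..DISLIKE
_TABLE_LAYOUT = (
    "QAAAO",
    "RIIIM",
    "RIIIM",
    "RIIIM",
    "RRRRQ",
)


def build_evaluation_table() -> EvaluationTable:
    """Return the 25-cell Kano evaluation table.

    Cell histogram is {A:3, O:1, M:3, I:9, R:7, Q:2}; the two Q cells are
    the contradictory pairs (LIKE, LIKE) and (DISLIKE, DISLIKE).
    """
    table: EvaluationTable = {}
    for f, row in zip(LikertLevel, _TABLE_LAYOUT):
        for d, cat in zip(LikertLevel, row):
            table[(f, d)] = KanoCategory(cat)
    return table


def classify_pair(pair: ResponsePair, table: EvaluationTable | None = None) -> KanoCategory:
    """Look up a response pair's category; pure and deterministic."""
    if table is None:
        table = _default_table()
    f = LikertLevel.coerce(pair.functional)
    d = LikertLevel.coerce(pair.dysfunctional)
    return table[(f, d)]


_DEFAULT_TABLE: EvaluationTable | None = None


def _default_table() -> EvaluationTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = build_evaluation_table()
    return _DEFAULT_TABLE


def tabulate_attribute(
    pairs: Sequence[ResponsePair] | Iterable[ResponsePair],
    attribute_id: int,
    table: EvaluationTable | None = None,
) -> AttributeCounts:
    """Tally the six categories over one attribute's response pairs.

    Q and R responses are retained in the tallies (they are reported, not
    dropped); an empty input is an error — there are no respondents to count.
    """
    counts = Counter(classify_pair(p, table) for p in pairs)
    n = sum(counts.values())
    if n == 0:
        raise ValueError(f"attribute {attribute_id}: no respondents to tabulate")
    return AttributeCounts(
        attribute_id=attribute_id,
        **{c.value.lower(): counts.get(c, 0) for c in KanoCategory},
    )


def _competing_tallies(counts: AttributeCounts) -> dict[KanoCategory, int]:
    # Q is reported but never competes for the final category
    return {c: counts[c] for c in FINAL_CATEGORY_PRIORITY}


def final_category(counts: AttributeCounts) -> KanoCategory:
    """Modal category among {M, O, A, I, R}; ties broken by the fixed
    priority M > O > A > I > R (most to least demanding of provision)."""
    tallies = _competing_tallies(counts)
    if all(v == 0 for v in tallies.values()):
        raise ValueError(f"attribute {counts.attribute_id}: all competing tallies are zero")
    return max(FINAL_CATEGORY_PRIORITY, key=lambda c: (tallies[c], -FINAL_CATEGORY_PRIORITY.index(c)))


def category_strength(counts: AttributeCounts, *, rounded: bool = True) -> float:
    """Percent gap between the two most frequent categories (over M,O,A,I,R),
    relative to the total respondent count n (Q and R included in n)."""
    if counts.n == 0:
        raise ValueError("category strength undefined for n = 0")
    ordered = sorted(_competing_tallies(counts).values(), reverse=True)
    value = 100.0 * (ordered[0] - ordered[1]) / counts.n
    return round_half_away(value) if rounded else value


def total_strength(counts: AttributeCounts, *, rounded: bool = True) -> float:
    """Percent of all n respondents classifying the attribute as M, O or A."""
    if counts.n == 0:
        raise ValueError("total strength undefined for n = 0")
    value = 100.0 * (counts.m + counts.o + counts.a) / counts.n
    return round_half_away(value) if rounded else value


def _better_worse_denominator(counts: AttributeCounts) -> int:
    denom = counts.a + counts.o + counts.m + counts.i
    if denom == 0:
        raise ValueError(
            f"attribute {counts.attribute_id}: Better/Worse undefined (A+O+M+I = 0)"
        )
    return denom


def better_coefficient(counts: AttributeCounts, *, rounded: bool = True) -> float:
    """Coefficient of satisfaction, 100*(A+O)/(A+O+M+I); R and Q excluded."""
    value = 100.0 * (counts.a + counts.o) / _better_worse_denominator(counts)
    return round_half_away(value) if rounded else value


def worse_coefficient(counts: AttributeCounts, *, rounded: bool = True) -> float:
    """Coefficient of dissatisfaction, 100*(O+M)/(A+O+M+I); R and Q excluded."""
    value = 100.0 * (counts.o + counts.m) / _better_worse_denominator(counts)
    return round_half_away(value) if rounded else value


def analyze_attribute(counts: AttributeCounts) -> AttributeMetrics:
    """Bundle all derived statistics for one attribute."""
    raw = {
        "category_strength_pct": category_strength(counts, rounded=False),
        "total_strength_pct": total_strength(counts, rounded=False),
        "better_pct": better_coefficient(counts, rounded=False),
        "worse_pct": worse_coefficient(counts, rounded=False),
    }
    return AttributeMetrics(
        attribute_id=counts.attribute_id,
        final_category=final_category(counts),
        category_strength_pct=round_half_away(raw["category_strength_pct"]),
        total_strength_pct=round_half_away(raw["total_strength_pct"]),
        better_pct=round_half_away(raw["better_pct"]),
        worse_pct=round_half_away(raw["worse_pct"]),
        raw=raw,
    )


def analyze_survey(dataset: "SurveyDataset") -> list[AttributeMetrics]:
    """Per-attribute metrics for a whole survey, in attribute order.

    Classification uses one shared evaluation table for every pair.
    """
    table = build_evaluation_table()
    return [
        analyze_attribute(tabulate_attribute(dataset.pairs_for_attribute(k), k, table))
        for k in dataset.attribute_ids
    ]
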