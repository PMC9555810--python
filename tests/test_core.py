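"""Evaluation table, pair classification and per-attribute statistics."""

from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import kanodemand as kd
from kanodemand.types import FINAL_CATEGORY_PRIORITY, round_half_away

L = kd.LikertLevel
C = kd.KanoCategory


class TestEvaluationTable:
    def test_has_25_cells_with_printed_histogram(self, evaluation_table):
        assert len(evaluation_table) == 25
        hist = Counter(c.value for c in evaluation_table.values())
        assert hist == {"A": 3, "O": 1, "M": 3, "I": 9, "R": 7, "Q": 2}

    def test_questionable_cells_are_the_contradictory_pairs(self, evaluation_table):
        q_cells = {cell for cell, cat in evaluation_table.items() if cat is C.QUESTIONABLE}
        assert q_cells == {(L.LIKE, L.LIKE), (L.DISLIKE, L.DISLIKE)}

    @pytest.mark.parametrize(
        "functional, dysfunctional, expected",
        [
            (L.LIKE, L.DISLIKE, C.ONE_DIMENSIONAL),
            (L.LIKE, L.LIKE, C.QUESTIONABLE),
            (L.LIKE, L.MUST_BE, C.ATTRACTIVE),
            (L.NEUTRAL, L.NEUTRAL, C.INDIFFERENT),
            (L.DISLIKE, L.NEUTRAL, C.REVERSE),
            (L.LIVE_WITH, L.DISLIKE, C.MUST_BE),
            (L.MUST_BE, L.LIKE, C.REVERSE),
        ],
    )
    def test_classify_pair_matches_printed_table(self, functional, dysfunctional, expected):
        assert kd.classify_pair(kd.ResponsePair(functional, dysfunctional)) == expected

    def test_invalid_level_rejected_naming_the_value(self):
        with pytest.raises(ValueError, match="6"):
            kd.ResponsePair(6, 1)
        with pytest.raises(ValueError, match="sometimes"):
            L.coerce("sometimes")

    def test_labels_accepted_case_insensitively(self):
        assert L.coerce("like") is L.LIKE
        assert L.coerce("Must_Be") is L.MUST_BE
        assert L.coerce("5") is L.DISLIKE


class TestTabulate:
    def test_single_pair_tally(self):
        counts = kd.tabulate_attribute([kd.ResponsePair(L.LIKE, L.DISLIKE)], 1)
        assert counts.as_dict() == {"M": 0, "O": 1, "A": 0, "I": 0, "R": 0, "Q": 0}
        assert counts.n == 1

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError, match="no respondents"):
            kd.tabulate_attribute([], 1)

    def test_reconstructed_study_row_tabulates_to_printed_counts(self, fixtures):
        counts = fixtures.attribute_counts[1]
        ds = kd.reconstruct_from_counts(counts)
        got = kd.tabulate_attribute(ds.pairs_for_attribute(1), 1)
        assert got.as_dict() == {"M": 8, "O": 34, "A": 170, "I": 122, "Q": 7, "R": 7}
        assert got.n == 348

    @given(
        st.lists(
            st.tuples(st.sampled_from(list(L)), st.sampled_from(list(L))),
            min_size=1,
            max_size=60,
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_tallies_conserve_n(self, raw_pairs):
        pairs = [kd.ResponsePair(f, d) for f, d in raw_pairs]
        counts = kd.tabulate_attribute(pairs, 1)
        assert sum(v for _, v in counts) == counts.n == len(pairs)


class TestDerivedStatistics:
    # rows of the published evaluation table, frozen after recomputation
    @pytest.mark.parametrize(
        "attr, expected",
        [
            (1, ("A", 13.79, 60.92, 61.08, 12.57)),
            (6, ("M", 4.89, 76.44, 47.49, 56.93)),
            (9, ("I", 14.94, 47.41, 47.48, 13.35)),
            (11, ("M", 27.30, 82.47, 35.29, 63.24)),
            (13, ("O", 34.20, 83.05, 83.98, 61.42)),
        ],
    )
    def test_study_rows_reproduce(self, fixtures, attr, expected):
        m = kd.analyze_attribute(fixtures.attribute_counts[attr])
        fc, cs, ts, better, worse = expected
        assert m.final_category.value == fc
        assert m.category_strength_pct == cs
        assert m.total_strength_pct == ts
        assert m.better_pct == better
        assert m.worse_pct == worse

    def test_final_category_tie_broken_by_priority(self):
        counts = kd.AttributeCounts(1, m=10, o=10, a=10, i=10, r=10)
        assert kd.final_category(counts) is C.MUST_BE
        counts = kd.AttributeCounts(1, o=7, a=7, i=2)
        assert kd.final_category(counts) is C.ONE_DIMENSIONAL

    def test_q_never_wins_final_category(self):
        counts = kd.AttributeCounts(1, q=90, i=10)
        assert kd.final_category(counts) is C.INDIFFERENT

    def test_all_competing_tallies_zero_is_an_error(self):
        with pytest.raises(ValueError, match="zero"):
            kd.final_category(kd.AttributeCounts(1, q=5))

    def test_degenerate_single_category(self):
        counts = kd.AttributeCounts(1, o=10)
        m = kd.analyze_attribute(counts)
        assert (m.category_strength_pct, m.total_strength_pct) == (100.0, 100.0)
        assert (m.better_pct, m.worse_pct) == (100.0, 100.0)

    def test_better_worse_exclude_r_and_q(self):
        with_rq = kd.AttributeCounts(1, m=10, o=20, a=30, i=40, r=7, q=3)
        without = kd.AttributeCounts(1, m=10, o=20, a=30, i=40)
        assert kd.better_coefficient(with_rq) == kd.better_coefficient(without) == 50.0
        assert kd.worse_coefficient(with_rq) == kd.worse_coefficient(without) == 30.0

    def test_better_worse_undefined_when_denominator_zero(self):
        counts = kd.AttributeCounts(1, r=5, q=1)
        with pytest.raises(ValueError, match="A\\+O\\+M\\+I"):
            kd.better_coefficient(counts)

    def test_worse_zero_when_no_m_or_o(self):
        assert kd.worse_coefficient(kd.AttributeCounts(1, a=5, i=5)) == 0.0

    def test_rounding_is_half_away_from_zero(self):
        assert round_half_away(4.885) == 4.89
        assert round_half_away(2.675) == 2.68  # banker's rounding would give 2.67
        assert round_half_away(34.195) == 34.20


@st.composite
def count_vectors(draw):
    tallies = {c: draw(st.integers(0, 50)) for c in "moairq"}
    if tallies["m"] + tallies["o"] + tallies["a"] + tallies["i"] == 0:
        tallies["o"] = 1
    return kd.AttributeCounts(1, **tallies)


class TestInvariants:
    @given(count_vectors())
    @settings(deadline=None, max_examples=100)
    def test_percentage_closure(self, counts):
        """total strength + I% + R% + Q% accounts for every respondent."""
        total = kd.total_strength(counts, rounded=False)
        rest = 100.0 * (counts.i + counts.r + counts.q) / counts.n
        assert total + rest == pytest.approx(100.0)

    @given(count_vectors())
    @settings(deadline=None, max_examples=100)
    def test_all_statistics_bounded(self, counts):
        m = kd.analyze_attribute(counts)
        for v in (m.category_strength_pct, m.total_strength_pct, m.better_pct, m.worse_pct):
            assert 0.0 <= v <= 100.0

    @given(count_vectors())
    @settings(deadline=None, max_examples=50)
    def test_final_category_has_maximal_tally(self, counts):
        winner = kd.final_category(counts)
        assert all(counts[winner] >= counts[c] for c in FINAL_CATEGORY_PRIORITY)


class TestAnalyzeSurvey:
    def test_all_neutral_respondent_gives_indifferent_everywhere(self):
        import pandas as pd

        cat = kd.AttributeCatalogue(tuple((k, f"attribute {k}") for k in range(1, 16)))
        data = {"respondent_id": ["r1"]}
        for k in range(1, 16):
            data[f"a{k}_f"] = [3]
            data[f"a{k}_d"] = [3]
        ds = kd.SurveyDataset(pd.DataFrame(data), cat)
        assert all(m.final_category is C.INDIFFERENT for m in kd.analyze_survey(ds))

    def test_matches_brute_force_recount_on_random_dataset(self):
        """Oracle check: a naive one-pair-at-a-time recount, written without
        the tabulation helpers, agrees with the pipeline."""
        import numpy as np

        rng = np.random.default_rng(42)
        mixtures = [
            kd.CategoryMixture(k, {C.coerce(c): p for c, p in
                                   zip("MOAIRQ", rng.dirichlet(np.ones(6)))})
            for k in range(1, 6)
        ]
        ds = kd.generate_dataset(kd.SimulationSpec(300, mixtures, seed=7))
        table = kd.build_evaluation_table()
        for m in kd.analyze_survey(ds):
            k = m.attribute_id
            tally = {c: 0 for c in "MOAIRQ"}
            for _, row in ds.frame.iterrows():
                f = kd.LikertLevel(int(row[f"a{k}_f"]))
                d = kd.LikertLevel(int(row[f"a{k}_d"]))
                tally[table[(f, d)].value] += 1
            n = sum(tally.values())
            comp = {c: tally[c] for c in "MOAIR"}
            top = sorted(comp.values(), reverse=True)
            denom = tally["M"] + tally["O"] + tally["A"] + tally["I"]
            assert m.category_strength_pct == round_half_away(100 * (top[0] - top[1]) / n)
            assert m.total_strength_pct == round_half_away(
                100 * (tally["M"] + tally["O"] + tally["A"]) / n
            )
            assert m.better_pct == round_half_away(100 * (tally["A"] + tally["O"]) / denom)
            assert m.worse_pct == round_half_away(100 * (tally["O"] + tally["M"]) / denom)
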