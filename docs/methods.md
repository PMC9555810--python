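# Methods

## Classification model

Each of the K = 15 service attributes is probed with a functional and a
dysfunctional question on the five-level scale LIKE (1), MUST_BE (2),
NEUTRAL (3), LIVE_WITH (4), DISLIKE (5). The 5×5 evaluation table maps
every answer pair to a category; its layout (functional answer in rows,
dysfunctional in columns, LIKE→DISLIKE) is

```
Q A A A O
R I I I M
R I I I M
R I I I M
R R R R Q
```

giving the cell histogram {A:3, O:1, M:3, I:9, R:7, Q:2}. The two Q cells
are the contradictory pairs (LIKE, LIKE) and (DISLIKE, DISLIKE).

## Per-attribute statistics

With per-attribute tallies m, o, a, i, r, q and n = m+o+a+i+r+q:

- final category: argmax over {M, O, A, I, R}. Q is reported but never
  competes — questionable answers are contradictions, not preferences.
  Ties are broken by the fixed priority M > O > A > I > R (most to least
  demanding of provision). The study data contain no tie; the rule exists
  so that arbitrary data produce reproducible output, and is a design
  choice of this package, not an observed convention.
- category strength = 100·(largest − second largest)/n over those five
  tallies, with n including R and Q. The denominator choice is forced by
  the published numbers (e.g. the vital-signs monitoring attribute:
  (105 − 88)/348 = 4.89%).
- total strength = 100·(m+o+a)/n.
- Better = 100·(a+o)/(a+o+m+i) and Worse = 100·(o+m)/(a+o+m+i); R and Q
  are excluded from numerator and denominator, again forced by the
  published values on all 15 attributes.

Percentages are reported to two decimals with halves rounded away from
zero, matching every printed value; unrounded values are kept internally
(`AttributeMetrics.raw`). Degenerate inputs (no respondents, or
a+o+m+i = 0) raise rather than return NaN.

## Better–Worse quadrants

Each attribute sits at (x = Worse, y = Better). With threshold t (default
50%): y ≥ t and x < t → Attractive; y ≥ t and x ≥ t → One-dimensional;
y < t and x ≥ t → Must-be; both low → Indifferent. A coordinate exactly
on the threshold counts as high. At t = 50 the quadrant agrees with the
modal category on all 15 packaged attributes; a data-driven threshold
(e.g. the mean of Better/Worse) is possible through the API but is not
the default, since the fixed threshold is what the quadrant semantics
describe.

## Group comparison

Respondent-level categories are mapped to ordinal demand scores, default
M=5, O=4, A=3, I=2, R=1, Q=0 (descending demand intensity). The source
study does not state its coding, so printed Z values are treated as
approximate context only; under this default the package reproduces the
study's qualitative conclusion (all 30 comparisons non-significant, min
p ≈ 0.056) with Z within about 0.02 of the printed values. The encoding
is a parameter (`encoding=` / `--encoding`).

The test is a two-sided Wilcoxon/Mann–Whitney rank-sum with mid-ranks for
ties and tie-corrected variance

Var(W) = n_a·n_b/12 · [(N+1) − Σ(t³−t)/(N(N−1))],

no continuity correction by default (toggle available). For pooled
samples of N ≤ 12 the exact permutation null of the rank sum is
enumerated instead of the normal approximation. Two groups with all
observations identical return Z = 0, p = 1 with a warning. Q-classified
respondents are included by default (their counts are part of the
published group rows) and can be dropped; no multiplicity adjustment is
applied by default (15 unadjusted tests, as published), with Holm/BH
available via `adjust=`.

Null calibration: with both groups of 100 drawn from the same empirical
category mixture, 2,000 replicates give an empirical type-I error of
≈0.046 at α = 0.05 (recomputed by `analysis/04_simulator_checks.py` and
the test suite).

## Synthetic respondents

`generate_dataset` draws each respondent's category per attribute from a
`CategoryMixture` (probability vector over the six categories), then an
answer pair uniformly among that category's evaluation-table cells, so
generated pairs classify back to their generating category exactly.
Covariates are drawn independently from stated level proportions.
Randomness uses numpy's PCG64; the seed is recorded in dataset metadata.

What the generator emulates: the per-attribute category mixtures of the
study (its defaults, via `CategoryMixture.from_counts`, are the published
empirical mixtures at n = 348) and two-group covariate splits. What it
does not emulate: correlation between attributes within a respondent and
joint demographic structure — neither is reported by the study, and no
packaged statistic depends on them, but tests passing on generated data
say nothing about such dependence in real surveys.

`reconstruct_from_counts` rebuilds a dataset whose tabulation equals a
given count vector exactly, filling each category's quota in the fixed
order M, O, A, I, Q, R with the category's first table cell in row-major
order. The assignment of categories to respondent rows is therefore
deterministic and byte-stable; any assignment consistent with the counts
yields identical downstream statistics because everything depends only on
the tallies. `reconstruct_grouped` does the same per group for the
two-group tables.

## Survey screening

CSV schema: `respondent_id`, optional covariates (city, residence,
gender, age_band, education, living_condition), and `a{k}_f`/`a{k}_d`
answers as codes 1–5 or labels (case-insensitive). Rows with a missing or
unreadable answer are excluded as incomplete, with a row-level error
naming the cell. The study excluded three respondents for "questionable
answers" without stating the rule; the package's default rule excludes a
respondent when more than 50% (configurable) of their pairs classify as
Q, while attribute-level Q answers below that are retained — the
published tallies contain nonzero Q counts. The effective rate is
100·valid/received.

## Problem sizes and determinism

The statistical checks use 2,000 replicates (null calibration, n = 100
per group), 500 replicates (modal-category recovery at n = 348), 10,000
draws (sampler round-trip) and 200 random count vectors (reconstruction
round-trip); these sizes give Monte-Carlo error comfortably below the
asserted tolerances while keeping the suite fast. All simulations are
seeded; property-based tests run derandomized.

## Known limitations

- Attributes are simulated independently; respondent-level correlation
  across attributes is not modelled.
- The ordinal encoding behind the published Z statistics is unknown;
  only the qualitative non-significance conclusion is asserted.
- The tie-break priority and the questionable-respondent rule are
  documented package defaults, not reconstructions of the original
  authors' (unstated) choices.
- Instrument reliability (Cronbach's alpha, test–retest) is out of scope.
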