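"""Domain types for Kano-model survey analysis.

A Kano questionnaire asks, for each service attribute, a *functional*
question ("if this service were provided, how would you feel?") and a
*dysfunctional* question ("and if it were not?"), each answered on the
same five-level scale.  The pair of answers is looked up in the Kano
evaluation table and mapped to one of six quality categories:

=====  =========================================================
M      must-be: absence dissatisfies, presence is taken for granted
O      one-dimensional: satisfaction tracks provision linearly
A      attractive: delights when present, no penalty when absent
I      indifferent: no effect either way
R      reverse: provision actually decreases satisfaction
Q      questionable: contradictory answer pair
=====  =========================================================
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterator, Mapping

__all__ = [
    "LikertLevel",
    "KanoCategory",
    "ResponsePair",
    "AttributeCounts",
    "AttributeMetrics",
    "round_half_away",
]


class LikertLevel(enum.IntEnum):
    """Five-level answer scale; integer codes 1-5 in the printed order."""

    LIKE = 1        # "I like it that way"
    MUST_BE = 2     # "It must be that way"
    NEUTRAL = 3     # "I am neutral"
    LIVE_WITH = 4   # "I can live with it"
    DISLIKE = 5     # "I dislike it that way"

    @classmethod
    def coerce(cls, value: object) -> "LikertLevel":
        """Accept an integer code 1-5, a level name ('like', case-insensitive),
        or an existing level; anything else raises ValueError naming the value."""
        if isinstance(value, cls):
            return value
        if isinstance(value, str):
            key = value.strip().upper().replace(" ", "_")
            if key in cls.__members__:
                return cls[key]
            if key.lstrip("-").isdigit():
                value = int(key)
            else:
                raise ValueError(f"invalid Likert answer: {value!r}")
        try:
            return cls(int(value))  # type: ignore[arg-type]
        except (ValueError, TypeError):
            raise ValueError(f"invalid Likert answer: {value!r}") from None


class KanoCategory(str, enum.Enum):
    """The six Kano quality categories. Q never becomes a final category."""

    MUST_BE = "M"
    ONE_DIMENSIONAL = "O"
    ATTRACTIVE = "A"
    INDIFFERENT = "I"
    REVERSE = "R"
    QUESTIONABLE = "Q"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @classmethod
    def coerce(cls, value: object) -> "KanoCategory":
        if isinstance(value, cls):
            return value
        if isinstance(value, str):
            v = value.strip().upper()
            try:
                return cls(v)
            except ValueError:
                if v in cls.__members__:
                    return cls[v]
        raise ValueError(f"invalid Kano category: {value!r}")


#: priority used to break final-category ties: most to least demanding of provision
FINAL_CATEGORY_PRIORITY: tuple[KanoCategory, ...] = (
    KanoCategory.MUST_BE,
    KanoCategory.ONE_DIMENSIONAL,
    KanoCategory.ATTRACTIVE,
    KanoCategory.INDIFFERENT,
    KanoCategory.REVERSE,
)


@dataclass(frozen=True)
class ResponsePair:
    """One respondent's answers to one attribute's question pair."""

    functional: LikertLevel
    dysfunctional: LikertLevel

    def __post_init__(self) -> None:
        object.__setattr__(self, "functional", LikertLevel.coerce(self.functional))
        object.__setattr__(self, "dysfunctional", LikertLevel.coerce(self.dysfunctional))


@dataclass(frozen=True)
class AttributeCounts:
    """Per-attribute tallies of the six categories across respondents.

    ``n`` always equals ``m+o+a+i+r+q``; questionable (Q) and reverse (R)
    responses are retained in the tallies rather than dropped.
    """

    attribute_id: int
    m: int = 0
    o: int = 0
    a: int = 0
    i: int = 0
    r: int = 0
    q: int = 0

    def __post_init__(self) -> None:
        for name in "moairq":
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 0:
                raise ValueError(f"tally {name!r} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.m + self.o + self.a + self.i + self.r + self.q

    def __getitem__(self, category: KanoCategory | str) -> int:
        return getattr(self, KanoCategory.coerce(category).value.lower())

    def as_dict(self) -> dict[str, int]:
        return {c.value: self[c] for c in KanoCategory}

    def __iter__(self) -> Iterator[tuple[KanoCategory, int]]:
        for c in KanoCategory:
            yield c, self[c]

    @classmethod
    def from_mapping(cls, attribute_id: int, tallies: Mapping[object, int]) -> "AttributeCounts":
        kw = {KanoCategory.coerce(k).value.lower(): int(v) for k, v in tallies.items()}
        return cls(attribute_id=attribute_id, **kw)


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round with halves going away from zero (the convention of every
    printed percentage), instead of Python's banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class AttributeMetrics:
    """Derived per-attribute statistics.

    Percent fields are reported rounded to two decimals; the unrounded
    values are kept in ``raw`` for downstream computation.
    """

    attribute_id: int
    final_category: KanoCategory
    category_strength_pct: float
    total_strength_pct: float
    better_pct: float
    worse_pct: float
    raw: dict[str, float] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.final_category is KanoCategory.QUESTIONABLE:
            raise ValueError("Q can never be a final category")
        for name in ("category_strength_pct", "total_strength_pct", "better_pct", "worse_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} out of [0, 100]: {v}")
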