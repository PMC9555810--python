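"""Respondent-level survey container.

A :class:`SurveyDataset` holds one row per respondent with optional
grouping covariates (city, residence, gender, age band, education,
living condition) and, for each attribute ``k`` in the catalogue, the
functional answer ``a{k}_f`` and dysfunctional answer ``a{k}_d`` as
integer codes 1-5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .types import LikertLevel, ResponsePair

__all__ = ["AttributeCatalogue", "SurveyDataset", "COVARIATE_COLUMNS"]

#: covariates the survey schema recognises, in reporting order
COVARIATE_COLUMNS = (
    "city",
    "residence",
    "gender",
    "age_band",
    "education",
    "living_condition",
)


@dataclass(frozen=True)
class AttributeCatalogue:
    """Ordered list of (attribute_id, short label) for the surveyed services."""

    entries: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        ids = [i for i, _ in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("attribute ids must be unique")

    @property
    def ids(self) -> tuple[int, ...]:
        return tuple(i for i, _ in self.entries)

    def label(self, attribute_id: int) -> str:
        for i, lab in self.entries:
            if i == attribute_id:
                return lab
        raise KeyError(attribute_id)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def _answer_columns(attribute_ids: Iterable[int]) -> list[str]:
    cols: list[str] = []
    for k in attribute_ids:
        cols += [f"a{k}_f", f"a{k}_d"]
    return cols


@dataclass
class SurveyDataset:
    """Respondents x attributes matrix of answer pairs plus covariates.

    ``frame`` has one row per respondent: ``respondent_id``, any covariate
    columns, then ``a{k}_f`` / ``a{k}_d`` integer codes for every attribute
    in ``catalogue``.  ``metadata`` records provenance (source file or
    simulation seed).
    """

    frame: pd.DataFrame
    catalogue: AttributeCatalogue
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "respondent_id" not in self.frame.columns:
            raise ValueError("frame must have a respondent_id column")
        if self.frame["respondent_id"].duplicated().any():
            raise ValueError("respondent ids must be unique")
        missing = [c for c in _answer_columns(self.attribute_ids) if c not in self.frame.columns]
        if missing:
            raise ValueError(f"frame is missing answer columns: {missing}")
        for col in _answer_columns(self.attribute_ids):
            values = self.frame[col]
            if values.isna().any() or not values.isin([1, 2, 3, 4, 5]).all():
                bad = values[~values.isin([1, 2, 3, 4, 5])]
                raise ValueError(f"column {col} has invalid answer codes: {bad.tolist()[:5]}")

    @property
    def attribute_ids(self) -> tuple[int, ...]:
        return self.catalogue.ids

    @property
    def n_respondents(self) -> int:
        return len(self.frame)

    def pairs_for_attribute(self, attribute_id: int) -> list[ResponsePair]:
        f = self.frame[f"a{attribute_id}_f"]
        d = self.frame[f"a{attribute_id}_d"]
        return [
            ResponsePair(LikertLevel(int(x)), LikertLevel(int(y)))
            for x, y in zip(f, d)
        ]

    def covariate(self, name: str) -> pd.Series:
        if name not in self.frame.columns:
            raise KeyError(f"covariate {name!r} not present in dataset")
        return self.frame[name]

    def covariate_names(self) -> list[str]:
        return [c for c in COVARIATE_COLUMNS if c in self.frame.columns]

    def subset(self, mask: Sequence[bool]) -> "SurveyDataset":
        return SurveyDataset(
            frame=self.frame.loc[list(mask)].reset_index(drop=True),
            catalogue=self.catalogue,
            metadata=dict(self.metadata),
        )
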