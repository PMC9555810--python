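"""Survey CSV reading, validation and writing.

Schema: one row per respondent with ``respondent_id``, optional covariate
columns (city, residence, gender, age_band, education, living_condition)
and, for each attribute ``k``, columns ``a{k}_f`` and ``a{k}_d`` holding
the functional and dysfunctional answers as integer codes 1-5 or the
canonical labels (case-insensitive).

Validation mirrors the study's questionnaire screening: rows with any
missing or unreadable answer are excluded as incomplete, and respondents
whose answers are predominantly contradictory (more than a configurable
fraction of pairs classifying as questionable, default 50%) are excluded
as questionable.  Attribute-level Q answers below that threshold are
retained — they appear in the reported tallies.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .core import build_evaluation_table, classify_pair
from .dataset import COVARIATE_COLUMNS, AttributeCatalogue, SurveyDataset
from .types import KanoCategory, LikertLevel, ResponsePair, round_half_away

__all__ = ["ValidationReport", "read_survey_csv", "write_survey_csv"]

_ANSWER_RE = re.compile(r"^a(\d+)_(f|d)$")


@dataclass
class ValidationReport:
    """Questionnaire screening tallies, in the order screening is applied."""

    received: int
    excluded_incomplete: int
    excluded_questionable: int
    errors: list[str] = field(default_factory=list)

    @property
    def valid(self) -> int:
        return self.received - self.excluded_incomplete - self.excluded_questionable

    @property
    def effective_rate_pct(self) -> float:
        if self.received == 0:
            raise ValueError("no questionnaires received")
        return round_half_away(100.0 * self.valid / self.received)


def _attribute_ids_from_header(columns: list[str]) -> list[int]:
    ids = sorted({int(m.group(1)) for c in columns if (m := _ANSWER_RE.match(c))})
    if not ids:
        raise ValueError("no answer columns (a{k}_f / a{k}_d) found in header")
    return ids


def read_survey_csv(
    path,
    catalogue: AttributeCatalogue | None = None,
    *,
    questionable_fraction: float = 0.5,
) -> tuple[SurveyDataset, ValidationReport]:
    """Read and validate a survey CSV.

    Returns the dataset of valid respondents and a :class:`ValidationReport`
    counting exclusions.  Missing required columns are fatal; bad rows are
    collected as row-level errors and excluded.
    """
    raw = pd.read_csv(path, dtype=str)
    if "respondent_id" not in raw.columns:
        raise ValueError(f"{path}: missing required column respondent_id")
    attr_ids = (
        list(catalogue.ids) if catalogue is not None
        else _attribute_ids_from_header(list(raw.columns))
    )
    for k in attr_ids:
        for col in (f"a{k}_f", f"a{k}_d"):
            if col not in raw.columns:
                raise ValueError(f"{path}: missing required column {col}")

    table = build_evaluation_table()
    report = ValidationReport(received=len(raw), excluded_incomplete=0, excluded_questionable=0)

    kept_rows: list[dict] = []
    for idx, row in raw.iterrows():
        coded: dict[str, int] = {}
        problem = None
        for k in attr_ids:
            for col in (f"a{k}_f", f"a{k}_d"):
                value = row[col]
                if pd.isna(value) or str(value).strip() == "":
                    problem = f"row {idx + 2} ({row['respondent_id']}): missing answer in {col}"
                    break
                try:
                    coded[col] = int(LikertLevel.coerce(value))
                except ValueError:
                    problem = (
                        f"row {idx + 2} ({row['respondent_id']}): "
                        f"invalid answer {value!r} in column {col}"
                    )
                    break
            if problem:
                break
        if problem:
            report.excluded_incomplete += 1
            report.errors.append(problem)
            continue

        n_q = sum(
            classify_pair(
                ResponsePair(LikertLevel(coded[f"a{k}_f"]), LikertLevel(coded[f"a{k}_d"])),
                table,
            )
            is KanoCategory.QUESTIONABLE
            for k in attr_ids
        )
        if n_q / len(attr_ids) > questionable_fraction:
            report.excluded_questionable += 1
            report.errors.append(
                f"row {idx + 2} ({row['respondent_id']}): questionable answers "
                f"on {n_q}/{len(attr_ids)} attributes"
            )
            continue

        rec: dict = {"respondent_id": row["respondent_id"]}
        for cov in COVARIATE_COLUMNS:
            if cov in raw.columns:
                rec[cov] = row[cov]
        rec.update(coded)
        kept_rows.append(rec)

    if not kept_rows:
        raise ValueError(f"{path}: no valid respondents after screening")
    if catalogue is None:
        catalogue = AttributeCatalogue(tuple((k, f"attribute {k}") for k in attr_ids))
    dataset = SurveyDataset(
        frame=pd.DataFrame(kept_rows),
        catalogue=catalogue,
        metadata={"source": str(path)},
    )
    return dataset, report


def write_survey_csv(dataset: SurveyDataset, path) -> None:
    """Write a dataset in the survey CSV schema (UTF-8, comma-separated)."""
    cols = ["respondent_id"] + dataset.covariate_names()
    for k in dataset.attribute_ids:
        cols += [f"a{k}_f", f"a{k}_d"]
    dataset.frame.to_csv(path, columns=cols, index=False)
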