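"""Packaged study tables: attribute catalogue, per-attribute category counts,
per-group counts for the two group comparisons, and demographic marginals.

The original study surveyed 348 empty-nest elderly individuals with chronic
diseases across Yangzhou and Nantong (Jiangsu, China) about 15 telenursing
services.  The respondent-level data were not deposited, but the published
category tallies determine every downstream statistic, so these counts are
shipped verbatim and respondent-level datasets are rebuilt from them with
:func:`kanodemand.simulate.reconstruct_from_counts`.

Integrity is checked on every load: each attribute's tallies must sum to
348, each city row to 173 (Yangzhou) / 175 (Nantong), each residence row to
173 (rural) / 175 (urban), and the per-group rows must sum to the pooled
counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .dataset import AttributeCatalogue
from .types import AttributeCounts

__all__ = ["StudyFixtures", "load_study_fixtures", "N_RESPONDENTS", "GROUP_SIZES"]

N_RESPONDENTS = 348
#: group sizes: Yangzhou/rural pool 173 respondents, Nantong/urban 175
GROUP_SIZES = {"Yangzhou": 173, "Nantong": 175, "rural": 173, "urban": 175}


@dataclass(frozen=True)
class StudyFixtures:
    """Packaged study constants, verbatim from the published tables."""

    catalogue: AttributeCatalogue
    attribute_counts: dict[int, AttributeCounts]
    city_groups: dict[int, dict[str, AttributeCounts]]
    residence_groups: dict[int, dict[str, AttributeCounts]]
    demographics: pd.DataFrame  # columns: covariate, level, count


def _read_csv(name: str) -> pd.DataFrame:
    with resources.files("kanodemand.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def _counts_from_row(row: pd.Series) -> AttributeCounts:
    return AttributeCounts(
        attribute_id=int(row["attribute_id"]),
        m=int(row["M"]), o=int(row["O"]), a=int(row["A"]),
        i=int(row["I"]), q=int(row["Q"]), r=int(row["R"]),
    )


def _load_grouped(name: str, expected_sizes: dict[str, int]) -> dict[int, dict[str, AttributeCounts]]:
    df = _read_csv(name)
    out: dict[int, dict[str, AttributeCounts]] = {}
    for _, row in df.iterrows():
        k = int(row["attribute_id"])
        counts = _counts_from_row(row)
        if counts.n != expected_sizes[row["group"]]:
            raise ValueError(
                f"{name}: attribute {k} group {row['group']} sums to {counts.n}, "
                f"expected {expected_sizes[row['group']]}"
            )
        out.setdefault(k, {})[str(row["group"])] = counts
    return out


def load_study_fixtures() -> StudyFixtures:
    """Load and consistency-check all packaged study tables."""
    cat_df = _read_csv("attributes.csv")
    catalogue = AttributeCatalogue(
        tuple((int(r["attribute_id"]), str(r["label"])) for _, r in cat_df.iterrows())
    )
    if len(catalogue) != 15:
        raise ValueError("attribute catalogue must have 15 services")

    attribute_counts = {}
    for _, row in _read_csv("attribute_counts.csv").iterrows():
        counts = _counts_from_row(row)
        if counts.n != N_RESPONDENTS:
            raise ValueError(
                f"attribute_counts attribute {counts.attribute_id} sums to {counts.n}, "
                f"expected {N_RESPONDENTS}"
            )
        attribute_counts[counts.attribute_id] = counts

    city_groups = _load_grouped(
        "city_group_counts.csv", {"Yangzhou": 173, "Nantong": 175}
    )
    residence_groups = _load_grouped(
        "residence_group_counts.csv", {"rural": 173, "urban": 175}
    )

    for name, grouped in (("city_groups", city_groups), ("residence_groups", residence_groups)):
        for k, groups in grouped.items():
            pooled = {
                c: sum(g[c] for g in groups.values()) for c, _ in attribute_counts[k]
            }
            if pooled != attribute_counts[k].as_dict():
                raise ValueError(f"{name} attribute {k} group rows do not sum to pooled counts")

    demographics = _read_csv("demographics.csv")
    per_cov = demographics.groupby("covariate")["count"].sum()
    if not (per_cov == N_RESPONDENTS).all():
        raise ValueError("demographic marginals must each sum to 348")

    return StudyFixtures(
        catalogue=catalogue,
        attribute_counts=attribute_counts,
        city_groups=city_groups,
        residence_groups=residence_groups,
        demographics=demographics,
    )


def demographic_covariates() -> pd.DataFrame:
    """A synthetic 348-row covariate frame matching the published marginals.

    The city x residence cross-tabulation is reproduced exactly (87/88/86/87
    respondents in urban-Yangzhou/urban-Nantong/rural-Yangzhou/rural-Nantong);
    the remaining covariates are assigned deterministically to match their
    marginal counts only — the study does not report their joint structure.
    """
    fixtures = load_study_fixtures()
    cells = [
        ("Yangzhou", "urban", 87),
        ("Nantong", "urban", 88),
        ("Yangzhou", "rural", 86),
        ("Nantong", "rural", 87),
    ]
    city, residence = [], []
    for c, r, n in cells:
        city += [c] * n
        residence += [r] * n

    frame = pd.DataFrame({
        "respondent_id": [f"r{j:03d}" for j in range(1, N_RESPONDENTS + 1)],
        "city": city,
        "residence": residence,
    })
    demo = fixtures.demographics
    for covariate in ("gender", "age_band", "education", "living_condition"):
        rows = demo[demo["covariate"] == covariate]
        values: list[str] = []
        for _, row in rows.iterrows():
            values += [str(row["level"])] * int(row["count"])
        frame[covariate] = values
    return frame
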