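"""Synthetic survey respondents with controlled Kano-category structure.

Two generation modes:

* :func:`generate_dataset` draws each respondent's category for each
  attribute from a per-attribute :class:`CategoryMixture`, then picks an
  answer pair uniformly among the evaluation-table cells of that category,
  so the classified category of every generated pair is its generating
  category by construction.
* :func:`reconstruct_from_counts` deterministically rebuilds a
  respondent-level dataset whose tabulation reproduces a given category
  count vector exactly — used to turn the published count tables back into
  analyzable datasets.  Each category's quota is filled with its first cell
  in row-major table order; any assignment consistent with the counts gives
  identical downstream statistics, since all statistics depend only on the
  tallies.

Randomness comes from numpy's PCG64 generator; the seed is recorded in the
dataset metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import EvaluationTable, build_evaluation_table, classify_pair
from .dataset import AttributeCatalogue, SurveyDataset
from .types import AttributeCounts, KanoCategory, LikertLevel, ResponsePair

__all__ = [
    "CategoryMixture",
    "SimulationSpec",
    "cells_for_category",
    "sample_pair_for_category",
    "generate_dataset",
    "reconstruct_from_counts",
    "reconstruct_grouped",
]

#: category order used when filling reconstruction quotas (printed column order)
FILL_ORDER = tuple(KanoCategory(c) for c in "MOAIQR")


@dataclass(frozen=True)
class CategoryMixture:
    """Probability vector over the six categories for one attribute."""

    attribute_id: int
    probabilities: Mapping[KanoCategory, float]

    def __post_init__(self) -> None:
        probs = {KanoCategory.coerce(k): float(v) for k, v in self.probabilities.items()}
        missing = set(KanoCategory) - set(probs)
        probs.update({c: 0.0 for c in missing})
        if any(v < 0 for v in probs.values()):
            raise ValueError("mixture probabilities must be non-negative")
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError(f"mixture probabilities must sum to 1, got {sum(probs.values())}")
        object.__setattr__(self, "probabilities", probs)

    @classmethod
    def from_counts(cls, counts: AttributeCounts) -> "CategoryMixture":
        """Empirical mixture of a count vector (e.g. a published table row)."""
        return cls(
            attribute_id=counts.attribute_id,
            probabilities={c: v / counts.n for c, v in counts},
        )


@dataclass(frozen=True)
class SimulationSpec:
    """Everything needed to generate a dataset reproducibly."""

    n_respondents: int
    mixtures: Sequence[CategoryMixture]
    covariates: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_respondents <= 0:
            raise ValueError("n_respondents must be positive")
        if not self.mixtures:
            raise ValueError("at least one attribute mixture is required")
        for name, levels in self.covariates.items():
            total = sum(levels.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"covariate {name!r} proportions must sum to 1, got {total}")


def cells_for_category(
    category: KanoCategory, table: EvaluationTable | None = None
) -> list[tuple[LikertLevel, LikertLevel]]:
    """All evaluation-table cells mapping to ``category``, in row-major order."""
    if table is None:
        table = build_evaluation_table()
    category = KanoCategory.coerce(category)
    return [cell for cell, cat in table.items() if cat is category]


def sample_pair_for_category(
    category: KanoCategory,
    table: EvaluationTable | None = None,
    rng: np.random.Generator | None = None,
) -> ResponsePair:
    """Draw a pair uniformly among the cells of ``category``; the drawn pair
    always classifies back to ``category``."""
    if rng is None:
        rng = np.random.default_rng()
    cells = cells_for_category(category, table)
    f, d = cells[int(rng.integers(len(cells)))]
    return ResponsePair(f, d)


def _default_catalogue(n_attributes: int) -> AttributeCatalogue:
    return AttributeCatalogue(
        tuple((k, f"attribute {k}") for k in range(1, n_attributes + 1))
    )


def generate_dataset(
    spec: SimulationSpec, catalogue: AttributeCatalogue | None = None
) -> SurveyDataset:
    """Generate respondents with covariates and per-attribute answer pairs."""
    rng = np.random.default_rng(spec.seed)
    table = build_evaluation_table()
    n = spec.n_respondents

    data: dict[str, list] = {
        "respondent_id": [f"s{j:05d}" for j in range(1, n + 1)]
    }
    for name, levels in spec.covariates.items():
        labels = list(levels)
        probs = np.array([levels[l] for l in labels], dtype=float)
        data[name] = list(rng.choice(labels, size=n, p=probs / probs.sum()))

    categories = list(KanoCategory)
    cells_by_cat = {c: cells_for_category(c, table) for c in categories}
    for mix in spec.mixtures:
        p = np.array([mix.probabilities[c] for c in categories], dtype=float)
        drawn = rng.choice(len(categories), size=n, p=p / p.sum())
        f_col, d_col = [], []
        for idx in drawn:
            cells = cells_by_cat[categories[idx]]
            f, d = cells[int(rng.integers(len(cells)))]
            f_col.append(int(f))
            d_col.append(int(d))
        data[f"a{mix.attribute_id}_f"] = f_col
        data[f"a{mix.attribute_id}_d"] = d_col

    if catalogue is None:
        ids = [m.attribute_id for m in spec.mixtures]
        catalogue = AttributeCatalogue(tuple((k, f"attribute {k}") for k in ids))
    return SurveyDataset(
        frame=pd.DataFrame(data),
        catalogue=catalogue,
        metadata={"source": "simulation", "seed": spec.seed, "generator": "PCG64"},
    )


def _category_sequence(counts: AttributeCounts) -> list[KanoCategory]:
    seq: list[KanoCategory] = []
    for c in FILL_ORDER:
        seq += [c] * counts[c]
    return seq


def reconstruct_from_counts(
    counts: AttributeCounts | Sequence[AttributeCounts],
    catalogue: AttributeCatalogue | None = None,
    id_prefix: str = "r",
) -> SurveyDataset:
    """Deterministically rebuild a dataset whose tabulation equals ``counts``.

    Accepts a single attribute's counts or one count vector per attribute
    (all sharing the same total n).  Respondent ``j`` receives, for each
    attribute, the j-th category in the fixed fill order M, O, A, I, Q, R,
    answered with that category's first evaluation-table cell.
    """
    counts_list = [counts] if isinstance(counts, AttributeCounts) else list(counts)
    if not counts_list:
        raise ValueError("no count vectors given")
    n = counts_list[0].n
    if n == 0:
        raise ValueError("no respondents: all tallies are zero")
    if any(c.n != n for c in counts_list):
        raise ValueError("all attributes must have the same total n")

    table = build_evaluation_table()
    first_cell = {c: cells_for_category(c, table)[0] for c in KanoCategory}

    data: dict[str, list] = {
        "respondent_id": [f"{id_prefix}{j:05d}" for j in range(1, n + 1)]
    }
    for c in counts_list:
        seq = _category_sequence(c)
        cells = [first_cell[cat] for cat in seq]
        data[f"a{c.attribute_id}_f"] = [int(f) for f, _ in cells]
        data[f"a{c.attribute_id}_d"] = [int(d) for _, d in cells]

    if catalogue is None:
        catalogue = AttributeCatalogue(
            tuple((c.attribute_id, f"attribute {c.attribute_id}") for c in counts_list)
        )
    ds = SurveyDataset(
        frame=pd.DataFrame(data),
        catalogue=catalogue,
        metadata={"source": "reconstruction"},
    )
    # round-trip guard: the rebuilt dataset must tabulate back to the input
    from .core import tabulate_attribute

    for c in counts_list:
        got = tabulate_attribute(ds.pairs_for_attribute(c.attribute_id), c.attribute_id, table)
        if got.as_dict() != c.as_dict():
            raise AssertionError(f"reconstruction failed for attribute {c.attribute_id}")
    return ds


def reconstruct_grouped(
    rows: Mapping[int, Mapping[str, AttributeCounts]],
    covariate: str,
    catalogue: AttributeCatalogue | None = None,
) -> SurveyDataset:
    """Rebuild a two-group dataset from per-attribute, per-group count rows
    (the shape of the published group-comparison tables)."""
    groups = sorted({g for by_group in rows.values() for g in by_group})
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups, got {groups}")
    parts = []
    for g in groups:
        per_attr = [rows[k][g] for k in sorted(rows)]
        ds = reconstruct_from_counts(per_attr, catalogue=catalogue, id_prefix=f"{g}_")
        ds.frame[covariate] = g
        parts.append(ds.frame)
    frame = pd.concat(parts, ignore_index=True)
    if catalogue is None:
        catalogue = AttributeCatalogue(
            tuple((k, f"attribute {k}") for k in sorted(rows))
        )
    return SurveyDataset(
        frame=frame,
        catalogue=catalogue,
        metadata={"source": "reconstruction", "group_covariate": covariate},
    )
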