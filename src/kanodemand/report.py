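"""Descriptive summaries, Better-Worse quadrant plot and report writing."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .compare import ComparisonResult
from .dataset import SurveyDataset
from .types import AttributeCounts, AttributeMetrics, KanoCategory, round_half_away

__all__ = [
    "PlotPoint",
    "summarize_demographics",
    "sample_size_range",
    "betterworse_points",
    "plot_betterworse",
    "comparison_frame",
    "metrics_frame",
    "render_report",
]

#: quadrant label expected for each modal category (concordance check)
QUADRANT_FOR_CATEGORY = {
    KanoCategory.ATTRACTIVE: "Attractive",
    KanoCategory.ONE_DIMENSIONAL: "One-dimensional",
    KanoCategory.MUST_BE: "Must-be",
    KanoCategory.INDIFFERENT: "Indifferent",
}


@dataclass(frozen=True)
class PlotPoint:
    """One attribute's position on the Better-Worse plane."""

    attribute_id: int
    x: float  # worse (dissatisfaction) percent
    y: float  # better (satisfaction) percent
    quadrant: str


def summarize_demographics(dataset: SurveyDataset) -> pd.DataFrame:
    """Frequency table per covariate: level, count, percent of N."""
    if dataset.n_respondents == 0:
        raise ValueError("empty dataset")
    n = dataset.n_respondents
    rows = []
    for cov in dataset.covariate_names():
        counts = dataset.covariate(cov).value_counts()
        for level, count in counts.items():
            rows.append({
                "covariate": cov,
                "level": level,
                "count": int(count),
                "percent": round_half_away(100.0 * count / n),
            })
    return pd.DataFrame(rows, columns=["covariate", "level", "count", "percent"])


def sample_size_range(
    n_predictors: int,
    lower_multiplier: float = 10,
    upper_multiplier: float = 20,
    dropout_rate: float = 0.0,
) -> tuple[int, int]:
    """Cross-sectional sample-size rule of thumb: 10-20 respondents per
    predictor, inflated for anticipated dropout."""
    if n_predictors <= 0 or lower_multiplier <= 0 or upper_multiplier <= 0:
        raise ValueError("predictor count and multipliers must be positive")
    if not 0 <= dropout_rate < 1:
        raise ValueError(f"dropout rate must be in [0, 1), got {dropout_rate}")
    lo = math.ceil(n_predictors * lower_multiplier * (1 + dropout_rate))
    hi = math.ceil(n_predictors * upper_multiplier * (1 + dropout_rate))
    return lo, hi


def betterworse_points(
    metrics: Sequence[AttributeMetrics], threshold: float = 50.0
) -> list[PlotPoint]:
    """Place each attribute at (worse, better); label its quadrant.

    A coordinate on the threshold counts as high, so (50, 50) is
    one-dimensional.
    """
    if not metrics:
        raise ValueError("no metrics to plot")
    if not 0 < threshold < 100:
        raise ValueError(f"threshold must be in (0, 100), got {threshold}")
    points = []
    for m in metrics:
        x, y = m.worse_pct, m.better_pct
        if y >= threshold:
            quadrant = "One-dimensional" if x >= threshold else "Attractive"
        else:
            quadrant = "Must-be" if x >= threshold else "Indifferent"
        points.append(PlotPoint(m.attribute_id, x, y, quadrant))
    return points


def plot_betterworse(
    points: Sequence[PlotPoint], threshold: float = 50.0, path=None
) -> "plt.Figure":
    """Scatter the attributes on the Better-Worse plane with quadrant lines."""
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.scatter([p.x for p in points], [p.y for p in points], color="tab:blue", zorder=3)
    for p in points:
        ax.annotate(str(p.attribute_id), (p.x, p.y), textcoords="offset points",
                    xytext=(5, 3), fontsize=8)
    ax.axhline(threshold, color="grey", lw=0.8)
    ax.axvline(threshold, color="grey", lw=0.8)
    ax.set_xlim(0, 100)
    ax.set_ylim(0, 100)
    ax.set_xlabel("Worse (dissatisfaction) %")
    ax.set_ylabel("Better (satisfaction) %")
    pad = 2
    ax.text(pad, 100 - pad, "Attractive", va="top", fontsize=9, color="grey")
    ax.text(100 - pad, 100 - pad, "One-dimensional", va="top", ha="right", fontsize=9, color="grey")
    ax.text(100 - pad, pad, "Must-be", ha="right", fontsize=9, color="grey")
    ax.text(pad, pad, "Indifferent", fontsize=9, color="grey")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def metrics_frame(
    metrics: Sequence[AttributeMetrics],
    counts: Mapping[int, AttributeCounts] | None = None,
) -> pd.DataFrame:
    """Tidy per-attribute results table (category tallies included when given)."""
    rows = []
    for m in metrics:
        row: dict = {"attribute_id": m.attribute_id}
        if counts is not None:
            row.update(counts[m.attribute_id].as_dict())
        row.update({
            "final_category": m.final_category.value,
            "category_strength_pct": m.category_strength_pct,
            "total_strength_pct": m.total_strength_pct,
            "better_pct": m.better_pct,
            "worse_pct": m.worse_pct,
        })
        rows.append(row)
    return pd.DataFrame(rows)


def comparison_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Tidy group-comparison table: per-group category counts, Z and p."""
    rows = []
    for r in results:
        for g, counts in r.group_counts.items():
            row = {"attribute_id": r.attribute_id, "group": g}
            row.update(counts.as_dict())
            row["n"] = counts.n
            row["Z"] = round(r.z_statistic, 4)
            row["p"] = round(r.p_value, 4)
            rows.append(row)
    return pd.DataFrame(rows)


def render_report(
    metrics: Sequence[AttributeMetrics],
    comparisons: Sequence[ComparisonResult] | None,
    points: Sequence[PlotPoint] | None,
    out_dir,
    *,
    counts: Mapping[int, AttributeCounts] | None = None,
    config: dict | None = None,
) -> dict[str, Path]:
    """Write the results CSVs, the quadrant plot and a JSON run log.

    Returns the paths written, keyed by artifact name.  Identical inputs
    produce identical CSV content.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    log: dict = {"config": config or {}, "artifacts": [], "notes": []}

    p = out / "attribute_metrics.csv"
    metrics_frame(metrics, counts).to_csv(p, index=False)
    written["metrics"] = p

    if comparisons:
        p = out / "group_comparison.csv"
        comparison_frame(comparisons).to_csv(p, index=False)
        written["comparisons"] = p
    else:
        log["notes"].append("no group comparisons supplied; comparison file omitted")

    if points:
        threshold = float((config or {}).get("threshold", 50.0))
        p = out / "betterworse.png"
        plot_betterworse(points, threshold, p)
        written["plot"] = p

    import numpy, pandas, scipy

    import kanodemand

    log["versions"] = {
        "kanodemand": kanodemand.__version__,
        "numpy": numpy.__version__,
        "pandas": pandas.__version__,
        "scipy": scipy.__version__,
    }
    log["artifacts"] = {k: str(v) for k, v in written.items()}
    p = out / "run_log.json"
    p.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    written["log"] = p
    return written
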