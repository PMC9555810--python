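"""Classify the 15 telenursing services from the packaged category counts.

Rebuilds a 348-respondent dataset from the per-attribute tallies, runs the
full Kano pipeline and writes the per-attribute results table (final
category, category strength, total strength, Better, Worse) to
results/attribute_metrics.csv.
"""

from collections import Counter
from pathlib import Path

import kanodemand as kd
from kanodemand.report import metrics_frame

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    fixtures = kd.load_study_fixtures()
    dataset = kd.reconstruct_from_counts(
        list(fixtures.attribute_counts.values()), catalogue=fixtures.catalogue
    )
    metrics = kd.analyze_survey(dataset)

    OUT.mkdir(exist_ok=True)
    frame = metrics_frame(metrics, fixtures.attribute_counts)
    frame.to_csv(OUT / "attribute_metrics.csv", index=False)

    tally = Counter(m.final_category.value for m in metrics)
    print(f"analyzed {dataset.n_respondents} respondents x {len(metrics)} services")
    print("final categories:", dict(sorted(tally.items())))
    for m in metrics:
        label = fixtures.catalogue.label(m.attribute_id)
        print(
            f"  {m.attribute_id:>2} {m.final_category.value}  "
            f"strength {m.category_strength_pct:6.2f}%  total {m.total_strength_pct:6.2f}%  "
            f"better {m.better_pct:6.2f}%  worse {m.worse_pct:6.2f}%  {label[:50]}"
        )
    print(f"wrote {OUT / 'attribute_metrics.csv'}")


if __name__ == "__main__":
    main()
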