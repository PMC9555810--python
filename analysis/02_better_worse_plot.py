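"""Place every service on the Better-Worse plane and label its quadrant.

Writes the quadrant coordinates to results/betterworse_points.csv and the
scatter plot (threshold lines at 50%) to results/betterworse.png, and
reports whether each quadrant agrees with the modal Kano category.
"""

from pathlib import Path

import pandas as pd

import kanodemand as kd
from kanodemand.report import QUADRANT_FOR_CATEGORY

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    fixtures = kd.load_study_fixtures()
    dataset = kd.reconstruct_from_counts(
        list(fixtures.attribute_counts.values()), catalogue=fixtures.catalogue
    )
    metrics = kd.analyze_survey(dataset)
    points = kd.betterworse_points(metrics, threshold=50)

    OUT.mkdir(exist_ok=True)
    pd.DataFrame(
        [{"attribute_id": p.attribute_id, "worse_pct": p.x, "better_pct": p.y,
          "quadrant": p.quadrant} for p in points]
    ).to_csv(OUT / "betterworse_points.csv", index=False)
    kd.plot_betterworse(points, 50, OUT / "betterworse.png")

    agree = sum(
        p.quadrant == QUADRANT_FOR_CATEGORY[m.final_category]
        for p, m in zip(points, metrics)
    )
    print(f"quadrant vs modal category agreement: {agree}/{len(points)}")
    print(f"wrote {OUT / 'betterworse_points.csv'} and {OUT / 'betterworse.png'}")


if __name__ == "__main__":
    main()
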