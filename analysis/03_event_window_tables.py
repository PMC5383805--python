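#!/usr/bin/env python
"""Before/after event-window tables and the counterfactual contrast.

For each firearm-related query category: the cross-tab over website classes
(top-4 + residual + total) with before/after counts and percentages,
delta %, cumulative %; the advocacy-view table; and the delta contrast
against the event-agnostic bicycle control.
"""

from pathlib import Path

import pandas as pd

from querypulse import (
    EventWindow,
    advocacy_crosstab,
    build_crosstab,
    control_contrast,
)
from querypulse.io import read_classified

SCRATCH = Path("scratch")
TABLES = Path("results") / "tables"
CATEGORIES = ["gun_type", "shooting", "ammunition", "law_related"]


def main() -> None:
    TABLES.mkdir(parents=True, exist_ok=True)
    classified = read_classified(SCRATCH / "classified.csv")
    window = EventWindow(event_day=0, window_days=14)

    tabs = {c: build_crosstab(classified, c, window)
            for c in [*CATEGORIES, "control"]}
    for cat, tab in tabs.items():
        tab.to_dataframe().to_csv(TABLES / f"crosstab_{cat}.csv", index=False)

    print("total delta % (after vs before window):")
    for cat in [*CATEGORIES, "control"]:
        print(f"  {cat:12s} {tabs[cat].total.delta_pct:+.2f}%")

    contrast_frames = []
    for cat in CATEGORIES:
        rep = control_contrast(tabs[cat], tabs["control"])
        contrast_frames.append(rep.to_dataframe().assign(group=cat))
        print(f"  {cat:12s} contrast vs control: "
              f"{rep.total.contrast_points:+.2f} points "
              f"({'event-attributable' if rep.total.event_attributable else 'not attributable'})")
    pd.concat(contrast_frames, ignore_index=True).to_csv(
        TABLES / "control_contrast.csv", index=False)

    adv = advocacy_crosstab(classified, window, categories=CATEGORIES)
    pd.concat([t.to_dataframe() for t in adv.values()], ignore_index=True).to_csv(
        TABLES / "advocacy.csv", index=False)
    print("advocacy-view tables -> results/tables/advocacy.csv")


if __name__ == "__main__":
    main()
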