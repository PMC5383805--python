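#!/usr/bin/env python
"""Trend dynamics: daily series, pre-event spikes, return to baseline.

Builds per-day count series by query category and by TLD category, flags
pre-event spike days against the robust baseline (median + 3 MAD-sd), and
estimates when each category's traffic re-enters the pre-event baseline
band (mean + 2 sd, 3-day confirmation).
"""

import json
from pathlib import Path

import pandas as pd

from querypulse import (
    EventWindow,
    daily_series,
    detect_spikes,
    fit_baseline,
    return_to_baseline_day,
)
from querypulse.io import read_classified

SCRATCH = Path("scratch")
TRENDS = Path("results") / "trends"


def main() -> None:
    TRENDS.mkdir(parents=True, exist_ok=True)
    classified = read_classified(SCRATCH / "classified.csv")
    window = EventWindow(event_day=0, window_days=14)

    summary = {}
    frames = []
    for group_by in ("category", "tld_category"):
        for key, ser in daily_series(classified, group_by, window).items():
            fit_baseline(ser)
            frames.append(ser.to_frame().assign(group_by=group_by))
            summary[f"{group_by}:{key}"] = {
                "spikes": sorted(detect_spikes(ser)),
                "return_to_baseline_day": return_to_baseline_day(ser),
                "baseline_mean": round(ser.baseline_mean, 1),
                "baseline_sd": round(ser.baseline_sd, 1),
            }
    pd.concat(frames, ignore_index=True).to_csv(TRENDS / "daily_counts.csv",
                                                index=False)
    (TRENDS / "summary.json").write_text(json.dumps(summary, indent=2))

    print("trend summary (spike days / return day):")
    for key, s in summary.items():
        print(f"  {key:28s} spikes={s['spikes']} "
              f"return={s['return_to_baseline_day']}")
    print("per-day counts -> results/trends/daily_counts.csv")


if __name__ == "__main__":
    main()
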