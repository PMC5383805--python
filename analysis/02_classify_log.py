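#!/usr/bin/env python
"""Classify the simulated log's queries and clicked URLs.

Runs every record through the keyword taxonomy (token-prefix /
substring matching with most-specific-first priority) and the domain
registry (registrable domain → TLD category, content category, advocacy
view), then summarises the class distribution.
"""

from pathlib import Path

import pandas as pd

from querypulse import classify_log, default_registry, default_taxonomy
from querypulse.io import read_log, write_classified

SCRATCH = Path("scratch")
RESULTS = Path("results")


def main() -> None:
    log = read_log(SCRATCH / "log.jsonl")
    classified, n_unclassified, n_bad_urls = classify_log(
        log, default_taxonomy(), default_registry()
    )
    write_classified(classified, SCRATCH / "classified.csv")

    dist = (
        classified.groupby(["category", "class_label"]).size()
        .rename("n").reset_index()
        .sort_values(["category", "n"], ascending=[True, False])
    )
    dist.to_csv(RESULTS / "classification_summary.csv", index=False)

    print(f"classified {len(classified)} records -> scratch/classified.csv")
    print(f"unclassified queries: {n_unclassified}; unparseable URLs: {n_bad_urls}")
    print(dist.groupby("category")["n"].sum().to_string())


if __name__ == "__main__":
    main()
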