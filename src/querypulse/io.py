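"""Log and table serialisation: JSONL / CSV readers and writers."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

#: exported record fields (generator ground-truth category is not exported)
RECORD_FIELDS = ["day", "query", "clicked_url"]


def write_log(log: pd.DataFrame, path) -> None:
    """Write search records as JSONL (``.jsonl``) or CSV (anything else)."""
    path = Path(path)
    out = log[RECORD_FIELDS]
    if path.suffix == ".jsonl":
        with open(path, "w") as fh:
            for rec in out.itertuples(index=False):
                fh.write(json.dumps(
                    {"day": int(rec.day), "query": rec.query,
                     "clicked_url": rec.clicked_url}) + "\n")
    else:
        out.to_csv(path, index=False)


def read_log(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".jsonl":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    rows.append(json.loads(line))
        frame = pd.DataFrame(rows, columns=RECORD_FIELDS)
    else:
        frame = pd.read_csv(path)
    frame["day"] = frame["day"].astype(int)
    return frame


CLASSIFIED_COLUMNS = [
    "day", "query", "category", "domain", "tld_category",
    "content_category", "advocacy", "class_label",
]


def write_classified(classified: pd.DataFrame, path) -> None:
    classified[CLASSIFIED_COLUMNS].to_csv(path, index=False)


def read_classified(path) -> pd.DataFrame:
    frame = pd.read_csv(path, keep_default_na=False, na_values=[""])
    frame["day"] = frame["day"].astype(int)
    return frame
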