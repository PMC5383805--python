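"""Synthetic search-log generation and its analytic expectation oracle.

Counts per (category, day) are Poisson with mean
``baseline * event_multiplier_on(day) * spike(day)``; record content (query
text, clicked URL) is drawn i.i.d. from the profile's templates and domain
weights.  Each profile consumes its own child seed (``SeedSequence.spawn``
in fixed profile order), so the control stream is exactly invariant to any
change in the other categories' rate parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import GeneratorConfig

#: column order of a log frame; ``category`` is generator ground truth and is
#: dropped when records are exported.
LOG_COLUMNS = ["day", "query", "clicked_url", "category"]


@dataclass(frozen=True)
class SearchRecord:
    """One logged search event: day offset, raw query, clicked URL."""

    day: int
    query: str
    clicked_url: str


def generate_log(config: GeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw a full synthetic log as a DataFrame of search records.

    Parameters
    ----------
    config
        Validated generator specification.
    seed
        Overrides ``config.seed`` when given.

    Returns
    -------
    DataFrame with columns ``day, query, clicked_url, category``, ordered by
    profile then day.  Identical config and seed give byte-identical output.
    """
    config.validate()
    use_seed = config.seed if seed is None else seed
    children = np.random.SeedSequence(use_seed).spawn(len(config.all_profiles()))

    days_out: list[np.ndarray] = []
    queries_out: list[np.ndarray] = []
    urls_out: list[np.ndarray] = []
    cats_out: list[np.ndarray] = []

    for profile, child in zip(config.all_profiles(), children):
        rng = np.random.default_rng(child)
        templates = np.asarray(profile.query_templates, dtype=object)
        domains = np.asarray(list(profile.domain_weights.keys()), dtype=object)
        weights = np.asarray(list(profile.domain_weights.values()), dtype=float)
        weights = weights / weights.sum()  # kill 1e-9 slack so choice() accepts
        urls = np.asarray(
            [f"https://www.{d}/landing" for d in domains], dtype=object
        )
        for day in config.days():
            n = rng.poisson(config.rate(profile.name, day))
            if n == 0:
                continue
            qi = rng.integers(0, len(templates), size=n)
            ui = rng.choice(len(domains), size=n, p=weights)
            days_out.append(np.full(n, day, dtype=np.int64))
            queries_out.append(templates[qi])
            urls_out.append(urls[ui])
            cats_out.append(np.full(n, profile.name, dtype=object))

    if not days_out:
        return pd.DataFrame(columns=LOG_COLUMNS)
    return pd.DataFrame(
        {
            "day": np.concatenate(days_out),
            "query": np.concatenate(queries_out),
            "clicked_url": np.concatenate(urls_out),
            "category": np.concatenate(cats_out),
        }
    )


def expected_counts(config: GeneratorConfig) -> pd.DataFrame:
    """Deterministic per-(category, day) expected counts.

    Analytic oracle for :func:`generate_log`: returns exactly the Poisson
    means the generator samples from, with no randomness.
    """
    config.validate()
    rows = [
        (profile.name, day, config.rate(profile.name, day))
        for profile in config.all_profiles()
        for day in config.days()
    ]
    return pd.DataFrame(rows, columns=["category", "day", "expected_count"])


def records_from_frame(log: pd.DataFrame) -> list[SearchRecord]:
    """Materialise a log frame as typed records (drops ground-truth category)."""
    return [
        SearchRecord(int(d), q, u)
        for d, q, u in zip(log["day"], log["query"], log["clicked_url"])
    ]
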