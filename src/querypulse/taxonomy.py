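"""Keyword taxonomy: query normalisation, classification, related-query expansion.

Queries are matched against an ordered category → keyword-list mapping.
Single-word keywords match as a prefix of any whitespace token of the
normalised query (so "gun" catches "guns" and "gunsmith" without letting
"ammo" fire inside "mammogram"); multi-word keywords match as a contiguous
substring.  When several categories match, a fixed priority order picks one,
so every query contributes a single count downstream.
"""

from __future__ import annotations

import re
import unicodedata
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError

UNCLASSIFIED = "unclassified"

_PUNCT = re.compile(r"[\W_]+", re.UNICODE)


def normalize_query(query: str) -> str:
    """Lowercase, NFKC-fold, map punctuation to spaces, collapse whitespace.

    Idempotent: ``normalize_query(normalize_query(q)) == normalize_query(q)``.
    """
    text = unicodedata.normalize("NFKC", query).lower()
    return _PUNCT.sub(" ", text).strip()


@dataclass
class KeywordTaxonomy:
    """Ordered category → keyword mapping with a multi-match priority order."""

    categories: list[tuple[str, list[str]]]
    priority: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.priority:
            self.priority = [name for name, _ in self.categories]
        self.validate()

    def validate(self) -> None:
        names = [name for name, _ in self.categories]
        if len(set(names)) != len(names):
            raise ConfigError("taxonomy: category names must be unique")
        for name, keywords in self.categories:
            if not keywords:
                raise ConfigError(f"taxonomy: category '{name}' has no keywords")
            for kw in keywords:
                if not kw or kw != kw.strip() or kw != kw.lower():
                    raise ConfigError(
                        f"taxonomy: keyword {kw!r} in '{name}' must be "
                        "nonempty, trimmed and lowercase"
                    )
        if sorted(self.priority) != sorted(names):
            raise ConfigError("taxonomy: priority must be a permutation of category names")

    def keywords_for(self, name: str) -> list[str]:
        for cat, keywords in self.categories:
            if cat == name:
                return keywords
        raise KeyError(name)

    @classmethod
    def from_yaml(cls, path) -> "KeywordTaxonomy":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        cats = [(name, list(kws)) for name, kws in data["categories"].items()]
        return cls(categories=cats, priority=list(data.get("priority", [])))

    def to_yaml(self, path) -> None:
        data = {
            "categories": {name: list(kws) for name, kws in self.categories},
            "priority": list(self.priority),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _category_matches(keywords: list[str], normalized: str, tokens: list[str]) -> bool:
    for kw in keywords:
        if " " in kw:
            if kw in normalized:
                return True
        elif any(tok.startswith(kw) for tok in tokens):
            return True
    return False


def classify_query(query: str, taxonomy: KeywordTaxonomy) -> str | None:
    """Assign a query to the highest-priority matching category, or ``None``.

    Never raises on unclassifiable input.
    """
    normalized = normalize_query(query)
    tokens = normalized.split()
    by_name = dict(taxonomy.categories)
    for name in taxonomy.priority:
        if _category_matches(by_name[name], normalized, tokens):
            return name
    return None


def classify_queries(queries: pd.Series, taxonomy: KeywordTaxonomy) -> pd.Series:
    """Vectorised :func:`classify_query`: one lookup per distinct query.

    Unmatched queries map to :data:`UNCLASSIFIED`.
    """
    unique = pd.unique(queries)
    mapping = {
        q: (classify_query(q, taxonomy) or UNCLASSIFIED) for q in unique
    }
    return queries.map(mapping)


def expand_related_queries(
    seeds: set[str],
    log: pd.DataFrame,
    k: int = 10,
    rho_min: float = 0.8,
) -> set[str]:
    """Recursive related-query closure over the log's daily count series.

    Starting from the seed queries, each frontier query contributes its
    top-``k`` most correlated queries *not yet harvested* (Pearson
    correlation of per-day count series, ties broken lexicographically)
    whose correlation reaches ``rho_min``; the expansion iterates to a
    fixpoint and returns the closure including the seeds.  Ranking only
    unharvested candidates mirrors the recursive search for new related
    queries: without it a frontier query's strongest correlate is usually
    one already collected and the recursion would stall.  Constant series
    have correlation 0 by convention.

    This re-grounds the original recursive correlated-search harvesting on
    the log itself, which makes the procedure deterministic and hermetic;
    it emulates, rather than replays, a live trends service.
    """
    if log.empty:
        raise ValueError("expand_related_queries: log must be nonempty")
    if k < 1:
        raise ValueError("expand_related_queries: k must be >= 1")
    if not -1.0 <= rho_min <= 1.0:
        # rho_min > 1 is unattainable rather than invalid: no expansion.
        if rho_min > 1.0:
            return set(seeds)
        raise ValueError("expand_related_queries: rho_min must be >= -1")

    counts = (
        log.groupby(["query", "day"]).size().unstack(fill_value=0)
    )
    all_days = range(int(log["day"].min()), int(log["day"].max()) + 1)
    counts = counts.reindex(columns=all_days, fill_value=0)
    queries = list(counts.index)
    matrix = counts.to_numpy(dtype=float)

    sd = matrix.std(axis=1)
    centered = matrix - matrix.mean(axis=1, keepdims=True)
    denom = np.outer(sd, sd) * matrix.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, centered @ centered.T / denom, 0.0)
    index_of = {q: i for i, q in enumerate(queries)}

    missing = set(seeds) - set(queries)
    if missing:
        warnings.warn(
            f"seed queries absent from log ignored for expansion: {sorted(missing)}",
            stacklevel=2,
        )

    closure = set(seeds)
    frontier = sorted(set(seeds) & set(queries))
    while frontier:
        new: set[str] = set()
        for q in frontier:
            i = index_of[q]
            candidates = [
                (-corr[i, j], queries[j])
                for j in range(len(queries))
                if j != i and corr[i, j] >= rho_min
                and queries[j] not in closure and queries[j] not in new
            ]
            candidates.sort()
            new.update(other for _, other in candidates[:k])
        closure |= new
        frontier = sorted(new)
    return closure
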