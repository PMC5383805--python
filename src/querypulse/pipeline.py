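"""End-to-end orchestration: generate → classify → analyze → trend.

``run_pipeline`` is deterministic for a fixed seed, writes every table as
CSV plus a JSON summary, logs stages as line-delimited JSON, and returns a
:class:`RunManifest` whose counts equal recounts from the stage outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from .config import GeneratorConfig
from .defaults import CONTROL_CATEGORY
from .generator import generate_log
from .io import write_classified, write_log
from .taxonomy import KeywordTaxonomy, classify_queries, UNCLASSIFIED
from .trends import daily_series, detect_spikes, fit_baseline, return_to_baseline_day
from .urls import DomainRegistry, classify_urls
from .windows import EventWindow, advocacy_crosstab, build_crosstab, control_contrast


@dataclass
class RunManifest:
    """Provenance and conservation record for one pipeline run."""

    seed: int
    config_hash: str
    n_records: int
    n_unclassified_queries: int
    n_unparseable_urls: int
    category_totals: dict[str, int] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    stage_seconds: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def classify_log(
    log: pd.DataFrame,
    taxonomy: KeywordTaxonomy,
    registry: DomainRegistry,
) -> tuple[pd.DataFrame, int, int]:
    """Attach taxonomy category and URL classification to every record.

    Returns the classified frame plus tallies of unclassified queries and
    unparseable URLs.  The generator's ground-truth column, if present, is
    ignored: categories are re-derived from the query text.
    """
    categories = classify_queries(log["query"], taxonomy)
    url_cols, n_bad_urls = classify_urls(log["clicked_url"], registry)
    classified = pd.DataFrame({
        "day": log["day"].astype(int),
        "query": log["query"],
        "category": categories,
    }).join(url_cols)
    n_unclassified = int((categories == UNCLASSIFIED).sum())
    return classified, n_unclassified, n_bad_urls


def run_pipeline(
    config: GeneratorConfig,
    taxonomy: KeywordTaxonomy,
    registry: DomainRegistry,
    seed: int,
    outdir,
    top_k: int = 4,
    control_category: str = CONTROL_CATEGORY,
    write_raw_log: bool = False,
) -> RunManifest:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "pipeline_log.jsonl"
    stages: dict[str, float] = {}
    outputs: list[str] = []

    def _stage(name: str, started: float, **extra) -> None:
        stages[name] = round(time.perf_counter() - started, 4)
        with open(log_path, "a") as fh:
            fh.write(json.dumps({"stage": name, "seconds": stages[name],
                                 "seed": seed, **extra}) + "\n")

    def _write(frame: pd.DataFrame, name: str) -> None:
        path = outdir / name
        with open(path, "w") as fh:
            fh.write(f"# querypulse output; seed={seed}\n")
            frame.to_csv(fh, index=False)
        outputs.append(name)

    log_path.write_text("")
    config.validate()
    config_hash = hashlib.sha256(config.canonical_json().encode()).hexdigest()

    t = time.perf_counter()
    log = generate_log(config, seed=seed)
    _stage("generate", t, n_records=len(log))
    if write_raw_log:
        write_log(log, outdir / "log.jsonl")
        outputs.append("log.jsonl")

    t = time.perf_counter()
    classified, n_unclassified, n_bad_urls = classify_log(log, taxonomy, registry)
    _stage("classify", t, unclassified=n_unclassified, unparseable_urls=n_bad_urls)
    write_classified(classified, outdir / "classified.csv")
    outputs.append("classified.csv")

    t = time.perf_counter()
    window = EventWindow(event_day=config.event_day, window_days=config.window_days)
    target_categories = [name for name in taxonomy.priority
                         if name != control_category]
    crosstabs = {
        cat: build_crosstab(classified, cat, window, top_k=top_k)
        for cat in [*target_categories, control_category]
    }
    for cat, tab in crosstabs.items():
        _write(tab.to_dataframe(), f"crosstab_{cat}.csv")
    contrasts = {
        cat: control_contrast(crosstabs[cat], crosstabs[control_category])
        for cat in target_categories
    }
    for cat, rep in contrasts.items():
        _write(rep.to_dataframe(), f"contrast_{cat}.csv")
    advocacy = advocacy_crosstab(classified, window, categories=target_categories)
    adv_frames = [tab.to_dataframe() for tab in advocacy.values()]
    if adv_frames:
        _write(pd.concat(adv_frames, ignore_index=True), "advocacy.csv")
    _stage("analyze", t)

    t = time.perf_counter()
    trend_rows = []
    trend_summary = {}
    for group_by in ("tld_category", "advocacy", "category"):
        for key, series in daily_series(classified, group_by, window).items():
            fit_baseline(series)
            trend_rows.append(series.to_frame().assign(group_by=group_by))
            trend_summary[f"{group_by}:{key}"] = {
                "spikes": sorted(detect_spikes(series)),
                "return_to_baseline_day": return_to_baseline_day(series),
                "baseline_mean": series.baseline_mean,
                "baseline_sd": series.baseline_sd,
            }
    if trend_rows:
        _write(pd.concat(trend_rows, ignore_index=True), "trend_daily.csv")
    _stage("trend", t)

    category_totals = {
        cat: int(tab.total.n) for cat, tab in crosstabs.items()
    }
    summary = {
        "seed": seed,
        "config_hash": config_hash,
        "category_totals": category_totals,
        "total_delta_pct": {
            cat: crosstabs[cat].total.delta_pct for cat in crosstabs
        },
        "contrast_points_total": {
            cat: contrasts[cat].total.contrast_points for cat in contrasts
        },
        "trends": trend_summary,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    outputs.append("summary.json")

    manifest = RunManifest(
        seed=seed,
        config_hash=config_hash,
        n_records=len(log),
        n_unclassified_queries=n_unclassified,
        n_unparseable_urls=n_bad_urls,
        category_totals=category_totals,
        outputs=sorted(outputs),
        stage_seconds=stages,
    )
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest
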