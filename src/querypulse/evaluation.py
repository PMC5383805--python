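"""Recovery benchmarks: does the pipeline recover what the generator put in?

Each routine builds a small, fully specified study condition, runs the
*real* pipeline path (generate → classify → cross-tab / trend) across many
seeds, and measures how well a known ground-truth quantity is recovered.
They back both the test suite and the reproduction script.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import CategoryProfile, GeneratorConfig, Spike
from .defaults import default_registry, default_taxonomy
from .generator import generate_log
from .pipeline import classify_log
from .trends import daily_series, detect_spikes, return_to_baseline_day
from .windows import EventWindow, build_crosstab

_GUN_TEMPLATES = ["buy handgun online", "rifle reviews", "used shotgun for sale"]
_GUN_DOMAINS = {
    "armslockerusa.com": 0.45,
    "nationalnewswire.com": 0.25,
    "dailymixdigest.com": 0.20,
    "shootersalliance.org": 0.10,
}
_CONTROL_TEMPLATES = ["bicycle shop near me", "kids bike sale"]
_CONTROL_DOMAINS = {"bikebarn.com": 0.6, "dailymixdigest.com": 0.4}


def _benchmark_config(
    baseline: float,
    multiplier: float = 1.0,
    halflife: float = math.inf,
    spikes: list[tuple[int, str, float]] | None = None,
    control_baseline: float | None = None,
) -> GeneratorConfig:
    return GeneratorConfig(
        profiles=[
            CategoryProfile(
                name="gun_type",
                baseline_rate=baseline,
                event_multiplier=multiplier,
                decay_halflife_days=halflife,
                query_templates=_GUN_TEMPLATES,
                domain_weights=dict(_GUN_DOMAINS),
            )
        ],
        control_profile=CategoryProfile(
            name="control",
            baseline_rate=baseline if control_baseline is None else control_baseline,
            query_templates=_CONTROL_TEMPLATES,
            domain_weights=dict(_CONTROL_DOMAINS),
        ),
        spikes=[Spike(*s) for s in (spikes or [])],
    )


def _seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


@dataclass
class RoundTripResult:
    mean_target_delta_pct: float
    mean_control_delta_pct: float
    se_control_delta_pct: float
    n_seeds: int


def generator_roundtrip(
    seed: int,
    n_seeds: int = 100,
    baseline: float = 1000.0,
    multiplier: float = 2.0,
) -> RoundTripResult:
    """Frozen-step round trip: with a step multiplier m and no decay the
    analytic total delta % is exactly 100 (m − 1); the control's is 0.

    Runs the full generate → classify → cross-tab path per seed and averages
    the recovered total deltas.
    """
    taxonomy, registry = default_taxonomy(), default_registry()
    cfg = _benchmark_config(baseline=baseline, multiplier=multiplier)
    window = EventWindow(event_day=cfg.event_day, window_days=cfg.window_days)
    target, control = [], []
    for s in _seeds(seed, n_seeds):
        log = generate_log(cfg, seed=int(s))
        classified, *_ = classify_log(log, taxonomy, registry)
        target.append(build_crosstab(classified, "gun_type", window).total.delta_pct)
        control.append(build_crosstab(classified, "control", window).total.delta_pct)
    control_arr = np.asarray(control, dtype=float)
    return RoundTripResult(
        mean_target_delta_pct=float(np.mean(target)),
        mean_control_delta_pct=float(control_arr.mean()),
        se_control_delta_pct=float(control_arr.std(ddof=1) / math.sqrt(n_seeds)),
        n_seeds=n_seeds,
    )


def oracle_equivalence(seed: int, n_logs: int = 10, baseline: float = 40.0) -> int:
    """Cross-tab and trend counts vs a plain filter-and-count recount.

    Returns the number of discrepancies over ``n_logs`` random logs (0 when
    the vectorised pipeline agrees everywhere with the brute-force oracle).
    """
    from .trends import brute_force_daily_counts
    from .windows import brute_force_window_counts

    taxonomy, registry = default_taxonomy(), default_registry()
    cfg = _benchmark_config(baseline=baseline, multiplier=3.0, halflife=4.0,
                            spikes=[(-6, "gun_type", 2.0)])
    window = EventWindow(event_day=cfg.event_day, window_days=cfg.window_days)
    mismatches = 0
    for s in _seeds(seed, n_logs):
        log = generate_log(cfg, seed=int(s))
        classified, *_ = classify_log(log, taxonomy, registry)
        for category in ("gun_type", "control"):
            tab = build_crosstab(classified, category, window)
            b, a = brute_force_window_counts(classified, category, window)
            if (tab.total.before_n, tab.total.after_n) != (b, a):
                mismatches += 1
            if sum(r.n for r in tab.rows) != tab.total.n:
                mismatches += 1
        for key, ser in daily_series(classified, "category", window).items():
            oracle = brute_force_daily_counts(classified, "category", key, window)
            got = {int(d): int(c) for d, c in zip(ser.days, ser.counts)}
            if got != oracle:
                mismatches += 1
    return mismatches


@dataclass
class SpikeRecoveryResult:
    exact_rate: float
    n_seeds: int


def spike_recovery(
    seed: int,
    n_seeds: int = 100,
    baseline: float = 1000.0,
    spike_multiplier: float = 3.0,
    k: float = 3.0,
) -> SpikeRecoveryResult:
    """Fraction of seeds on which detect_spikes returns exactly the injected
    pre-event spike days {−6, −11} (×3 surges at a low-noise baseline)."""
    taxonomy, registry = default_taxonomy(), default_registry()
    cfg = _benchmark_config(
        baseline=baseline,
        spikes=[(-6, "gun_type", spike_multiplier), (-11, "gun_type", spike_multiplier)],
        control_baseline=5.0,
    )
    window = EventWindow(event_day=cfg.event_day, window_days=cfg.window_days)
    hits = 0
    for s in _seeds(seed, n_seeds):
        log = generate_log(cfg, seed=int(s))
        classified, *_ = classify_log(log, taxonomy, registry)
        ser = daily_series(classified, "category", window)["gun_type"]
        if detect_spikes(ser, k=k) == {-6, -11}:
            hits += 1
    return SpikeRecoveryResult(exact_rate=hits / n_seeds, n_seeds=n_seeds)


@dataclass
class ReturnDayResult:
    in_band_rate: float
    median_day: float
    crossing_day: float
    halflife_days: float
    n_seeds: int


def return_day_recovery(
    seed: int,
    n_seeds: int = 100,
    baseline: float = 2000.0,
    multiplier: float = 24.0,
    target_day: float = 10.0,
    band: tuple[int, int] = (8, 12),
) -> ReturnDayResult:
    """Return-day estimation with the decay tuned analytically to cross the
    baseline + 2·√baseline band exactly at ``target_day``.

    The expected rate is baseline · (1 + (m−1) 2^(−d/h)); solving
    (m−1)·baseline·2^(−d/h) = 2√baseline for d = target_day fixes
    h = target_day / log2((m−1)√baseline / 2).  Reports the fraction of
    seeds whose estimated return day falls inside ``band``.
    """
    halflife = target_day / math.log2((multiplier - 1) * math.sqrt(baseline) / 2)
    taxonomy, registry = default_taxonomy(), default_registry()
    cfg = _benchmark_config(baseline=baseline, multiplier=multiplier,
                            halflife=halflife, control_baseline=5.0)
    window = EventWindow(event_day=cfg.event_day, window_days=cfg.window_days)
    days = []
    for s in _seeds(seed, n_seeds):
        log = generate_log(cfg, seed=int(s))
        classified, *_ = classify_log(log, taxonomy, registry)
        ser = daily_series(classified, "category", window)["gun_type"]
        days.append(return_to_baseline_day(ser))
    in_band = [d for d in days if d is not None and band[0] <= d <= band[1]]
    found = [d for d in days if d is not None]
    return ReturnDayResult(
        in_band_rate=len(in_band) / n_seeds,
        median_day=float(np.median(found)) if found else float("nan"),
        crossing_day=target_day,
        halflife_days=halflife,
        n_seeds=n_seeds,
    )
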