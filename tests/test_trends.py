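"""Daily trend series, spike detection, return-to-baseline estimation."""

import math

import numpy as np
import pytest

from querypulse import (
    EventWindow,
    TrendSeries,
    classify_log,
    daily_series,
    default_registry,
    default_taxonomy,
    detect_spikes,
    expected_counts,
    fit_baseline,
    generate_log,
    return_to_baseline_day,
)
from querypulse.trends import brute_force_daily_counts

from conftest import small_config

WINDOW = EventWindow(event_day=0, window_days=14)


def _series(counts, days=None, event_day=0):
    counts = np.asarray(counts, dtype=float)
    if days is None:
        days = np.arange(-14, len(counts) - 14)
    return TrendSeries(key="s", days=np.asarray(days), counts=counts,
                       event_day=event_day)


@pytest.fixture(scope="module")
def classified():
    cfg = small_config(baseline=60, multiplier=4.0, halflife=3.0,
                       spikes=[(-6, "gun_type", 3.0)], seed=13)
    log = generate_log(cfg)
    out, *_ = classify_log(log, default_taxonomy(), default_registry())
    return out


def test_daily_series_zero_filled_and_conserved(classified):
    series = daily_series(classified, "category", WINDOW)
    for cat, ser in series.items():
        assert list(ser.days) == list(range(-14, 14))
        assert ser.counts.sum() == (classified["category"] == cat).sum()


def test_daily_series_empty_input_is_empty():
    import pandas as pd

    frame = pd.DataFrame(columns=["day", "category", "tld_category",
                                  "advocacy", "class_label",
                                  "content_category", "domain", "query"])
    assert daily_series(frame, "category", WINDOW) == {}


def test_daily_series_matches_brute_force_recount(classified):
    for group_by in ("category", "tld_category"):
        series = daily_series(classified, group_by, WINDOW)
        for key, ser in series.items():
            oracle = brute_force_daily_counts(classified, group_by, key, WINDOW)
            assert {int(d): int(c) for d, c in zip(ser.days, ser.counts)} == oracle


def test_detect_spikes_flat_series_is_empty():
    assert detect_spikes(_series([100.0] * 28)) == set()


def test_detect_spikes_single_outlier():
    counts = [100.0] * 28
    counts[14 - 3] = 100000.0  # day -3
    assert detect_spikes(_series(counts)) == {-3}


def test_detect_spikes_requires_five_pre_event_days():
    ser = _series([1.0] * 6, days=np.arange(-4, 2))
    with pytest.raises(ValueError, match="pre-event"):
        detect_spikes(ser)


@pytest.mark.parametrize("scale", [0.5, 3.0, 1000.0])
def test_detect_spikes_invariant_to_uniform_scaling(scale):
    rng = np.random.default_rng(3)
    counts = rng.poisson(500, size=28).astype(float)
    counts[14 - 6] *= 4
    counts[14 - 11] *= 4
    base = detect_spikes(_series(counts))
    scaled = detect_spikes(_series(counts * scale))
    assert base == scaled == {-6, -11}


def test_detect_spikes_recovers_injected_fixture_spikes():
    """Low-noise generator run with x3 spikes at days -6 and -11."""
    cfg = small_config(baseline=2000, multiplier=1.0,
                       spikes=[(-6, "gun_type", 3.0), (-11, "gun_type", 3.0)],
                       seed=2)
    log = generate_log(cfg)
    classified, *_ = classify_log(log, default_taxonomy(), default_registry())
    ser = daily_series(classified, "category", WINDOW)["gun_type"]
    assert detect_spikes(ser, k=3.0) == {-6, -11}


def test_baseline_excludes_spikes():
    counts = np.full(28, 200.0)
    counts[[14 - 6, 14 - 11]] = 2000.0
    counts += np.tile([1.0, -1.0], 14)  # tiny jitter so MAD > 0
    ser = fit_baseline(_series(counts))
    assert ser.baseline_mean == pytest.approx(200.0, abs=1.5)
    # jitter MAD ~ 1.5, so the Poisson floor sqrt(median) sets the band sd
    assert ser.baseline_sd == pytest.approx(math.sqrt(ser.baseline_mean), rel=0.01)


def test_return_day_none_when_never_returning():
    counts = np.concatenate([np.full(14, 100.0), np.full(14, 300.0)])
    ser = _series(counts)
    ser.counts[:14] += np.tile([1.0, -1.0], 7)
    assert return_to_baseline_day(ser) is None  # step with no decay


def test_return_day_on_analytic_decay_series():
    """On the noise-free expectation series with pinned baseline stats, the
    return day equals the analytic threshold-crossing day."""
    B, m, h = 1000.0, 4.0, 1.5
    cfg = small_config(baseline=B, multiplier=m, halflife=h)
    exp = expected_counts(cfg)
    gun = exp[exp["category"] == "gun_type"]
    ser = TrendSeries(key="gun_type", days=gun["day"].to_numpy(),
                      counts=gun["expected_count"].to_numpy())
    ser.baseline_mean = B
    ser.baseline_sd = math.sqrt(B)
    # rate <= B + 2 sqrt(B)  <=>  d >= h*log2((m-1)*sqrt(B)/2)
    crossing = h * math.log2((m - 1) * math.sqrt(B) / 2)
    assert return_to_baseline_day(ser) == math.ceil(crossing)


def test_return_day_monotone_in_multiplier():
    """Larger event multiplier, same halflife: return day never earlier
    (checked on the analytic expectation series)."""
    B, h = 1000.0, 1.2
    days = []
    for m in (1.5, 3.0, 8.0, 20.0):
        cfg = small_config(baseline=B, multiplier=m, halflife=h)
        exp = expected_counts(cfg)
        gun = exp[exp["category"] == "gun_type"]
        ser = TrendSeries(key="g", days=gun["day"].to_numpy(),
                          counts=gun["expected_count"].to_numpy())
        ser.baseline_mean = B
        ser.baseline_sd = math.sqrt(B)
        days.append(return_to_baseline_day(ser))
    assert all(d is not None for d in days)
    assert days == sorted(days)
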