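"""Synthetic-log generator: determinism, analytic rates, stream isolation."""

import math

import numpy as np
import pandas as pd
import pytest

from querypulse import (
    ConfigError,
    classify_query,
    expected_counts,
    extract_domain,
    generate_log,
)
from querypulse.config import CategoryProfile, Spike

from conftest import small_config


def test_same_seed_gives_byte_identical_logs():
    cfg = small_config(seed=7)
    pd.testing.assert_frame_equal(generate_log(cfg), generate_log(cfg))


def test_different_seeds_differ():
    cfg = small_config()
    assert not generate_log(cfg, seed=1).equals(generate_log(cfg, seed=2))


def test_expected_counts_flat_when_multiplier_one():
    cfg = small_config(baseline=50, multiplier=1.0)
    exp = expected_counts(cfg)
    assert (exp["expected_count"] == 50.0).all()


def test_expected_counts_spike_day_is_scaled_and_neighbors_untouched():
    cfg = small_config(baseline=100, multiplier=1.0, control_baseline=100,
                       spikes=[(-6, "gun_type", 3.0)])
    exp = expected_counts(cfg).set_index(["category", "day"])["expected_count"]
    assert exp[("gun_type", -6)] == pytest.approx(300.0)
    assert exp[("gun_type", -5)] == pytest.approx(100.0)
    assert exp[("gun_type", -7)] == pytest.approx(100.0)
    assert exp[("control", -6)] == pytest.approx(100.0)


def test_expected_counts_halflife_decay_hand_value():
    # excess (5-1) halves once over 3 days: 1 + 4/2 = 3x baseline at day +3
    cfg = small_config(baseline=80, multiplier=5.0, halflife=3.0)
    exp = expected_counts(cfg).set_index(["category", "day"])["expected_count"]
    assert exp[("gun_type", 3)] == pytest.approx(80 * 3.0)
    assert exp[("gun_type", 0)] == pytest.approx(80 * 5.0)
    assert exp[("gun_type", -1)] == pytest.approx(80.0)


def test_monte_carlo_means_match_expected_counts():
    """Per-(category, day) empirical means agree with the analytic Poisson
    means within 3 standard errors over 200 seeds."""
    cfg = small_config(baseline=30, multiplier=2.5, halflife=4.0,
                       control_baseline=20, window_days=5,
                       spikes=[(-3, "gun_type", 2.0)])
    n_seeds = 200
    totals = {}
    for seed in range(n_seeds):
        log = generate_log(cfg, seed=seed)
        counts = log.groupby(["category", "day"]).size()
        for key, c in counts.items():
            totals[key] = totals.get(key, 0) + c
    exp = expected_counts(cfg).set_index(["category", "day"])["expected_count"]
    for key, mu in exp.items():
        mean = totals.get(key, 0) / n_seeds
        se = math.sqrt(mu / n_seeds)
        assert abs(mean - mu) <= 3 * se, (key, mean, mu)


def test_step_multiplier_doubles_after_window_counts():
    """baseline 100/day, multiplier 2, no decay: observed total delta is
    100% within 3-sigma Poisson sampling error."""
    cfg = small_config(baseline=100, multiplier=2.0, halflife=math.inf)
    log = generate_log(cfg, seed=11)
    gun = log[log["category"] == "gun_type"]
    before = int((gun["day"] < 0).sum())
    after = int((gun["day"] >= 0).sum())
    delta = 100.0 * (after - before) / before
    # sd of the delta ratio ~ 100*2*sqrt(1/1400 + 1/2800) ~ 6.6
    assert abs(delta - 100.0) < 3 * 6.6


def test_control_stream_invariant_to_other_multipliers():
    """Control records are byte-identical whatever the event effect on the
    firearm categories (per-profile child seeds)."""
    quiet = generate_log(small_config(multiplier=1.0), seed=5)
    loud = generate_log(small_config(multiplier=9.0, spikes=[(-6, "gun_type", 3.0)]),
                        seed=5)
    pd.testing.assert_frame_equal(
        quiet[quiet["category"] == "control"].reset_index(drop=True),
        loud[loud["category"] == "control"].reset_index(drop=True),
    )


def test_record_invariants_hold_on_default_fixture(fixture_config, taxonomy):
    log = generate_log(fixture_config, seed=3)
    lo, hi = fixture_config.first_day(), fixture_config.last_day()
    assert log["day"].between(lo, hi).all()
    for url in log["clicked_url"].unique():
        assert "." in extract_domain(url)
    # every emitted query classifies back into its generating category
    for cat, q in log[["category", "query"]].drop_duplicates().itertuples(index=False):
        assert classify_query(q, taxonomy) == cat


@pytest.mark.parametrize(
    "mutate, field",
    [
        (lambda c: setattr(c.profiles[0], "baseline_rate", -1), "baseline_rate"),
        (lambda c: setattr(c.profiles[0], "decay_halflife_days", 0), "decay_halflife_days"),
        (lambda c: setattr(c.profiles[0], "event_multiplier", -0.5), "event_multiplier"),
        (lambda c: c.profiles[0].domain_weights.update({"armslockerusa.com": 0.9}),
         "domain_weights"),
        (lambda c: setattr(c.profiles[0], "query_templates", []), "query_templates"),
        (lambda c: setattr(c.control_profile, "event_multiplier", 2.0),
         "event_multiplier"),
        (lambda c: setattr(c, "window_days", 0), "window_days"),
        (lambda c: setattr(c, "spikes", [Spike(-6, "nope", 2.0)]), "nope"),
    ],
)
def test_invalid_config_errors_name_the_field(mutate, field):
    cfg = small_config()
    mutate(cfg)
    with pytest.raises(ConfigError, match=field):
        generate_log(cfg)


def test_empty_templates_rejected_even_at_zero_rate():
    profile = CategoryProfile(
        name="x", baseline_rate=0.0, query_templates=[], domain_weights={"a.com": 1.0}
    )
    with pytest.raises(ConfigError, match="query_templates"):
        profile.validate()
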