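# querypulse

Event-window analysis of web search-query logs, built around the
infodemiology question: *how does a population's information-seeking change
around a major societal event?*  The concrete case it models is
firearm-related search behaviour around the 2012-12-14 Sandy Hook school
shooting: raw queries are classified into keyword categories (gun type,
ammunition, law related, shooting — plus an event-agnostic "bicycle"
control), each clicked URL is reduced to its registrable domain and
assigned a TLD category, a content category and an advocacy view, and the
volumes in paired 14-day windows flanking the event are contrasted.

The original Yahoo! search logs are proprietary and were never deposited.
The package therefore ships two complementary data paths:

* a **synthetic log generator** with the statistical structure the analysis
  assumes — per-category daily Poisson counts, a step-plus-geometric-decay
  event effect from day 0, isolated pre-event spikes, clicked-URL draws
  over a domain registry, and a control topic untouched by the event; and
* the original study's **printed summary counts keyed in as inputs**, so
  the arithmetic surface (delta %, cumulative %, shares, advocacy
  reconstruction) can be replayed exactly against the published numbers.

## Model and statistics

Day indices are offsets from the event (day 0 = event day); the before
window is days −14…−1 and the after window days 0…+13.  For category *c*
on day *d* the generator draws

    N(c, d) ~ Poisson( λ_c · m(c, d) · s(c, d) )

where λ_c is the baseline rate (queries/day),
`m(c,d) = 1 + (M_c − 1)·2^(−d/h_c)` for d ≥ 0 (step multiplier M_c whose
excess halves every h_c days) and s(c,d) is an isolated spike multiplier.
The analysis layer reports, per website class (content category × TLD):

* **delta %** = 100 · (after − before) / before — the relative-change
  statistic;
* **cumulative %** — running share of the category's volume down the listed
  class rows;
* a descriptive **counterfactual contrast**: category delta minus control
  delta, in percentage points.

Trend analysis estimates a robust pre-event baseline (median and MAD-based
sd of pre-event days, spike days excluded), flags pre-event spikes
(count > median + 3·MAD-sd), and finds the return-to-baseline day: the
first post-event day opening 3 consecutive observed days at or below
baseline + 2 sd.

## Worked example

The numbered drivers under `analysis/` run the whole study on the packaged
fixture (generate → classify → tables → trends → published-table replay),
writing tables under `results/` and bulky intermediates under `scratch/`:

```
$ python analysis/01_simulate_search_log.py
generated 106923 records (seed 42) -> scratch/log.jsonl
...
$ python analysis/03_event_window_tables.py
total delta % (after vs before window):
  gun_type     +50.01%
  shooting     +332.28%
  ammunition   +161.86%
  law_related  +531.11%
  control      -1.84%
  gun_type     contrast vs control: +51.85 points (event-attributable)
...
$ python analysis/04_trend_dynamics.py
trend summary (spike days / return day):
  category:gun_type            spikes=[-11, -6] return=10
  ...
```

Reading: firearm categories jump by +50 % to +530 % across the event while
the bicycle control moves by −2 %, so the change is event-attributable, not
seasonal; the generator's injected pre-event spikes at days −6 and −11 are
recovered, and gun-type traffic re-enters its pre-event baseline band
around day 10.  These realised deltas track the published study's totals
(+50.06, +333.71, +155.14, +535.47, control −8.64) because the fixture's
multipliers encode exactly those effect sizes.

The same stages are available as a CLI
(`querypulse generate|classify|analyze|trend|run`), e.g.:

```
querypulse run --seed 42 --out out/
```

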