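# Methods

## Problem and scope

The package analyses search-log records — (day offset, raw query, clicked
URL) triples — around a single societal event, for the firearm-search case
around 2012-12-14.  It answers three descriptive questions: how did query
volume per keyword category change from the 14 days before the event to the
14 days after; how did the mix of visited website classes (content × TLD)
and advocacy views shift; and what were the trend dynamics (pre-event
spikes, post-event decay back to baseline).  No inferential statistics are
computed: the original analysis reported none, and the contrasts here are
deliberately descriptive.

The raw logs behind the original study are proprietary.  Two substitutes
make the pipeline testable end to end: a synthetic-log generator encoding
the statistical structure the analysis assumes, and the printed summary
counts keyed in as inputs for exact arithmetic replay.

## Day and window conventions

Days are integer offsets from the event; with window length W = 14 the
study range is −14…+13, before = [−14, −1], after = [0, +13].  The event
day belongs to the after window (the day count 14+14 over a 28-day range
forces the event day into exactly one window; putting the day of the event
itself with the "after" period is the natural reading for an event-response
analysis, and it is a config-level choice).  Calendar dates are never used:
the original study's stated start date is itself inconsistent (a
"November 31"), and offsets sidestep the ambiguity.

## Synthetic-log generator

Per category c and day d, the record count is Poisson with mean
λ_c · m(c,d) · s(c,d):

* λ_c — baseline queries/day.  The default fixture scales the study's
  per-category daily volumes by 1/100 (gun type ≈ 1204/day, shooting ≈ 454,
  ammunition ≈ 341, law related ≈ 21, control ≈ 214) so a full log
  generates in well under a second while keeping the real category mix.
* m(c,d) = 1 for d < 0 and 1 + (M_c − 1)·2^(−d/h) for d ≥ 0 — a step of
  size M_c whose excess halves every h days.  Geometric decay is the
  simplest monotone model consistent with the observed return to baseline
  "after approximately 10 days"; h is a free parameter, not a claim about
  the true process.  The fixture uses h = 1.8 days with multipliers chosen
  so each category's *expected* 14-day delta % equals the published total
  deltas (+50.06, +333.71, +155.14, +535.47), accounting for the extra
  before-window mass the spikes contribute:
  M = 1 + (R·14.85 − 14)/3.1141, with R the target after/before ratio,
  14.85 = 14 + 0.5 + 0.35 the spike-inflated before mass, and
  3.1141 = Σ_{d=0..13} 2^(−d/1.8).
* s(c,d) — isolated spike multipliers; the fixture injects ×1.5 at day −6
  and ×1.35 at day −11 for the firearm categories, mirroring the smaller
  pre-event peaks in the observed traffic.  The control profile has
  M fixed at 1 and no spikes: it is event-agnostic by construction.

Record content is drawn i.i.d.: the query from the profile's templates
(each template embeds its category's keywords, so classification recovers
the generating category exactly), the clicked URL from the profile's
domain weights over a small illustrative registry.

Randomness: one integer seed; each profile consumes its own child stream
(`SeedSequence.spawn` in fixed profile order).  This makes the control
category's records *byte-identical* under any change to the other
categories' parameters — a stronger form of the control-independence
requirement — and output deterministic for a fixed seed.

What the generator does **not** emulate: users and sessions (records are
i.i.d. given the day), query novelty (a fixed template pool), domain
long tails (a ~20-domain registry vs millions of real domains, where ~30 %
of the original observations were unclassifiable), day-of-week seasonality,
and any trend in the control beyond flat noise.  Passing tests therefore
show the *pipeline arithmetic and estimators* are correct under the assumed
count model, not that the model captures real search behaviour.

## Query taxonomy

Normalisation: NFKC fold, lowercase, punctuation → spaces, whitespace
collapse (idempotent).  Matching: single-word keywords match as a prefix of
any token ("gun" catches "guns" and "gunsmith" but cannot fire inside
"mammogram"); multi-word keywords ("brady act", "second amendment") match
as contiguous substrings.  Multi-category matches resolve by a fixed
most-specific-first priority (law related > shooting > ammunition >
gun type > control) so each query contributes one count, which is what
makes the category shares sum to 100 %.

Related-query expansion re-grounds the original recursive
correlated-search harvesting (which used a live trends service) on the log
itself: each frontier query contributes its top-k most-correlated
*not-yet-harvested* queries by Pearson correlation of daily count series
(ties broken lexicographically, constant series correlate 0), iterated to
a fixpoint.  Ranking only unharvested candidates mirrors "repeat until no
new searches appear"; without it the strongest correlate of a frontier
query is typically one already collected and the recursion stalls.  This
is an emulation of the original procedure, not a replication.

## URL classification

The registrable domain (one label + public suffix, subdomains stripped) is
extracted against a frozen public-suffix snapshot shipped with the package;
a live suffix list would drift and break hermetic tests.  Multi-part
suffixes (co.uk, state.us) are preserved; unknown TLDs fall back to
treating the final label as the suffix; hosts that are bare suffixes, IP
literals or dotless names yield a classification error record that is kept
(as "other content, .other") so totals stay conserved, and tallied.

TLD categories follow ordered suffix rules — state.us → government before
the generic country rule, then gov/mil → government, com → commercial,
org → noncommercial, edu → educational institution, fallback other — so
rule order is significant and fixed.  Content category and advocacy view
are exact registry lookups with "other"/none fallbacks, mirroring the
original study's manual categorisation; the shipped registry is an
invented, user-replaceable illustration (the original lists were never
published).

## Event-window tables

Cross-tabs list the top-4 website classes by volume, an aggregate residual
row, and the total; cumulative % runs down that order and reaches 100 on
the total row.  delta % is undefined (reported missing, never ±∞) when the
before count is 0.  All arithmetic is full precision; percentages are
rounded half-away-from-zero to 2 decimals only at reporting.

Advocacy tables printed in the original study carry only each row's n and
before/after shares; deltas are recovered by integer-count reconstruction
(before_n = round(n·before %), after_n = n − before_n), which is what
reproduces the printed 660.58 % for the laws/gun-control row (pure
percent-ratio arithmetic would give 660.59).  Two large rows (n ≈ 40k–59k)
cannot be recovered this way: at that size a 2-decimal share no longer
pins down the integer split, and one printed delta (153.53) is in fact
inconsistent with its own printed before-share.  One printed cumulative
value (62.28 in the shooting category) is likewise inconsistent with its
own row counts and its successor entry; the keyed-in fixture carries the
arithmetically consistent 63.28.

The counterfactual contrast reports target delta minus control delta per
class (falling back to the control total, flagged, when the control lacks
a class) and calls a change event-attributable when the target delta
exceeds the control's.  This is a descriptive flag, not a test.

## Trend analysis

Per-day series are exact zero-filled counts per grouping key.  The
pre-event baseline is robust — median, and 1.4826·MAD as the sd — because
the pre-event window itself contains the spikes the analysis is meant to
find, which would bias a plain mean.  Spike days are pre-event days
exceeding median + k·MAD-sd (k = 3 default); the detector is invariant
under uniform rescaling of the series, and an all-constant series yields
no spikes.  The baseline statistics are then re-estimated from the
spike-free pre-event days.

Two numerical choices in the return-to-baseline estimator deserve note:

* **Poisson floor on the band sd.**  A MAD over ~a dozen days collapses
  toward zero with non-negligible probability, shrinking the baseline band
  to nothing and making "return" undetectable in pure noise.  Daily counts
  are at least Poisson-dispersed, so the band sd is floored at
  √baseline_mean.  The spike detector does *not* use the floor — it must
  stay scale-invariant.
* **Right-censored confirmation.**  The return day is the first post-event
  day opening `consecutive` (default 3) days at or below
  baseline + 2 sd.  Near the end of the window the confirmation run is
  censored: a day qualifies when every *observed* day of its run is in
  band, since unobserved days cannot refute re-entry.  This is the usual
  end-of-observation convention; it makes estimates within
  `consecutive − 1` days of the window edge slightly optimistic.

The default of 3 confirmation days treats the narrative "returned after
approximately 10 days" as a sustained re-entry, not a single quiet day.

## Recovery benchmarks and problem sizes

`querypulse.evaluation` runs the full generate → classify → analyse path
per seed under small, fully specified conditions: a 100-seed frozen-step
round trip (baseline 1000/day, multiplier 2 — analytic delta exactly
+100 %), brute-force count-oracle agreement on 10 logs (baseline 40/day),
100-seed spike recovery (baseline 1000/day, ×3 spikes at −6/−11), and
100-seed return-day recovery with the decay tuned analytically to cross
baseline + 2√baseline at day 10 (baseline 2000/day, multiplier 24, giving
h = 10/log2(23·√2000/2) ≈ 1.11 d).  The steep decay is chosen because the
crossing-day error from baseline-sd misestimation scales as
h·log2(σ/σ̂): flatter decays smear the crossing and make the day-10 target
unrecoverable at this window length.  These sizes keep the whole benchmark
suite under a minute while leaving Poisson noise small relative to the
effects being recovered.

## Known limitations

* Registry lookups only; no page content, no ML classification, no
  session/user structure (all future-work territory for the original
  study as well).
* The related-query expansion is an in-log emulation of an external
  trends service and will not reproduce the original 247-query set.
* Return-day estimates within 2 days of the window edge lean optimistic
  (censoring), and under heavy multipliers a category may genuinely not
  return within the 14-day after window (reported as missing).
* The two advocacy rows noted above are irrecoverable from the printed
  precision; they are excluded from replay, not approximated.
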