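"""Before/after event-window cross-tabulations.

The study window is a pair of equal, contiguous, disjoint day ranges flanking
the event: before = [event − W, event − 1], after = [event, event + W − 1]
(the event day opens the after window).  For each query category the module
builds a cross-tab over (content, TLD) website classes with before/after
counts and percentages, the relative-change statistic
``delta % = 100 (after − before) / before``, and the running cumulative share
of the category's volume — plus advocacy-view tables and a descriptive
contrast against an event-agnostic control category.

All arithmetic is done at full precision; percentages are rounded
half-away-from-zero to 2 decimals only at reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

BEFORE = "before"
AFTER = "after"
EXCLUDED = "excluded"

RESIDUAL_LABEL = "residual classes"
TOTAL_LABEL = "total"


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (so 0.005 → 0.01 and −0.005 → −0.01)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class EventWindow:
    """Paired 14-day (by default) periods flanking the event day."""

    event_day: int = 0
    window_days: int = 14

    def __post_init__(self) -> None:
        if self.window_days < 1:
            raise ValueError("window_days must be >= 1")

    @property
    def before_days(self) -> range:
        return range(self.event_day - self.window_days, self.event_day)

    @property
    def after_days(self) -> range:
        return range(self.event_day, self.event_day + self.window_days)

    def assign(self, day: int) -> str:
        if self.event_day - self.window_days <= day < self.event_day:
            return BEFORE
        if self.event_day <= day < self.event_day + self.window_days:
            return AFTER
        return EXCLUDED


def assign_window(day: int, window: EventWindow) -> str:
    """``before`` / ``after`` / ``excluded`` for one day offset."""
    return window.assign(day)


def delta_percent(before_n: float, after_n: float) -> float | None:
    """Relative change 100 (after − before)/before; ``None`` when before is 0."""
    if before_n == 0:
        return None
    return 100.0 * (after_n - before_n) / before_n


def cumulative_percent(row_ns: Sequence[float], category_total_n: float) -> list[float]:
    """Running share of the category total over rows in listed order."""
    if category_total_n <= 0:
        return [0.0 for _ in row_ns]
    acc = 0.0
    out = []
    for n in row_ns:
        acc += n
        out.append(100.0 * acc / category_total_n)
    return out


def category_share(category_n: float, total_n: float) -> float:
    """Percentage share of one category in the overall volume."""
    if total_n <= 0:
        return 0.0
    return 100.0 * category_n / total_n


def reconstructed_delta_percent(n: int, before_pct: float) -> float:
    """Delta % recovered from a printed (n, before %) pair.

    Reconstructs integer window counts (``before_n = round(n × before %)``,
    ``after_n = n − before_n``) and takes the delta of those, which is how
    summary tables that print only shares remain arithmetically consistent
    with their underlying integer counts.
    """
    before_n = int(round_half_away(n * before_pct / 100.0, 0))
    after_n = n - before_n
    d = delta_percent(before_n, after_n)
    return float("nan") if d is None else round_half_away(d)


@dataclass(frozen=True)
class CrossTabRow:
    """One website-class row of a before/after cross-tab (reported, rounded)."""

    label: str
    n: int
    before_n: int
    before_pct: float
    after_n: int
    after_pct: float
    delta_pct: float | None
    cumulative_pct: float


@dataclass
class CrossTab:
    """Per-category cross-tab mirroring a before/after summary table."""

    group: str
    rows: list[CrossTabRow] = field(default_factory=list)
    total: CrossTabRow | None = None

    def to_dataframe(self) -> pd.DataFrame:
        rows = [*self.rows] + ([self.total] if self.total is not None else [])
        frame = pd.DataFrame(
            [
                {
                    "group": self.group,
                    "class_label": r.label,
                    "n": r.n,
                    "before_n": r.before_n,
                    "before_pct": r.before_pct,
                    "after_n": r.after_n,
                    "after_pct": r.after_pct,
                    "delta_pct": r.delta_pct,
                    "cumulative_pct": r.cumulative_pct,
                }
                for r in rows
            ]
        )
        if len(frame):
            frame["delta_pct"] = frame["delta_pct"].astype(float)
        return frame

    def row(self, label: str) -> CrossTabRow:
        for r in self.rows:
            if r.label == label:
                return r
        raise KeyError(label)


def _make_row(label: str, before_n: int, after_n: int,
              cumulative: float | None) -> CrossTabRow:
    n = before_n + after_n
    before_pct = 100.0 * before_n / n if n else 0.0
    d = delta_percent(before_n, after_n)
    return CrossTabRow(
        label=label,
        n=n,
        before_n=before_n,
        before_pct=round_half_away(before_pct),
        after_n=after_n,
        after_pct=round_half_away(100.0 - before_pct) if n else 0.0,
        delta_pct=None if d is None else round_half_away(d),
        cumulative_pct=round_half_away(cumulative) if cumulative is not None else 0.0,
    )


def crosstab_from_counts(
    group: str, labelled_counts: Iterable[tuple[str, int, int]]
) -> CrossTab:
    """Build a cross-tab directly from (label, before_n, after_n) rows.

    Used both for reporting and to replay printed summary tables whose
    integer counts are keyed in as inputs.
    """
    rows_in = list(labelled_counts)
    total_n = sum(b + a for _, b, a in rows_in)
    cumulative = cumulative_percent([b + a for _, b, a in rows_in], total_n)
    rows = [
        _make_row(label, b, a, c)
        for (label, b, a), c in zip(rows_in, cumulative)
    ]
    total = _make_row(
        TOTAL_LABEL,
        sum(b for _, b, _ in rows_in),
        sum(a for _, _, a in rows_in),
        100.0 if total_n else None,
    )
    return CrossTab(group=group, rows=rows, total=total)


def build_crosstab(
    classified: pd.DataFrame,
    category: str,
    window: EventWindow,
    top_k: int = 4,
) -> CrossTab:
    """Cross-tab of website classes for one query category.

    Rows are the ``top_k`` most-visited (content, TLD) classes, then one
    aggregate residual row covering the remaining classes, then the total;
    cumulative % runs down the listed order and reaches 100 on the total.
    Records outside the window are excluded; an empty category yields an
    empty cross-tab with a zero total.
    """
    sub = classified[classified["category"] == category]
    if not sub.empty:
        in_window = sub["day"].map(window.assign)
        sub = sub.assign(window=in_window)
        sub = sub[sub["window"] != EXCLUDED]
    if sub.empty:
        return CrossTab(group=category, rows=[],
                        total=_make_row(TOTAL_LABEL, 0, 0, None))

    pivot = (
        sub.groupby(["class_label", "window"]).size().unstack(fill_value=0)
        .reindex(columns=[BEFORE, AFTER], fill_value=0)
    )
    pivot["n"] = pivot[BEFORE] + pivot[AFTER]
    pivot = pivot.sort_values(["n", "class_label"],
                              ascending=[False, True],
                              kind="mergesort")

    named = pivot.iloc[:top_k]
    rest = pivot.iloc[top_k:]
    labelled = [
        (str(label), int(row[BEFORE]), int(row[AFTER]))
        for label, row in named.iterrows()
    ]
    if len(rest):
        labelled.append(
            (RESIDUAL_LABEL, int(rest[BEFORE].sum()), int(rest[AFTER].sum()))
        )
    return crosstab_from_counts(category, labelled)


# --- advocacy tables -------------------------------------------------------

@dataclass(frozen=True)
class AdvocacyRow:
    """One advocacy-view row: volume, share of the category's advocacy
    traffic, before/after shares, delta %."""

    view: str
    n: int
    share_pct: float
    before_pct: float
    after_pct: float
    delta_pct: float | None


@dataclass
class AdvocacyTable:
    group: str
    rows: list[AdvocacyRow]
    total: AdvocacyRow

    def row(self, view: str) -> AdvocacyRow:
        for r in self.rows:
            if r.view == view:
                return r
        raise KeyError(view)

    def to_dataframe(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            [
                {
                    "group": self.group, "view": r.view, "n": r.n,
                    "share_pct": r.share_pct, "before_pct": r.before_pct,
                    "after_pct": r.after_pct, "delta_pct": r.delta_pct,
                }
                for r in [*self.rows, self.total]
            ]
        )
        frame["delta_pct"] = frame["delta_pct"].astype(float)
        return frame


def _advocacy_row(view: str, before_n: int, after_n: int, group_n: int) -> AdvocacyRow:
    n = before_n + after_n
    d = delta_percent(before_n, after_n)
    return AdvocacyRow(
        view=view,
        n=n,
        share_pct=round_half_away(100.0 * n / group_n) if group_n else 0.0,
        before_pct=round_half_away(100.0 * before_n / n) if n else 0.0,
        after_pct=round_half_away(100.0 * after_n / n) if n else 0.0,
        delta_pct=None if d is None else round_half_away(d),
    )


def advocacy_crosstab(
    classified: pd.DataFrame,
    window: EventWindow,
    categories: Sequence[str] | None = None,
) -> dict[str, AdvocacyTable]:
    """Per-category before/after tables over advocacy views.

    Only records whose clicked domain carries an advocacy view contribute.
    """
    sub = classified[classified["advocacy"].notna()].copy()
    sub["window"] = sub["day"].map(window.assign)
    sub = sub[sub["window"] != EXCLUDED]
    if categories is None:
        categories = sorted(sub["category"].unique())

    out: dict[str, AdvocacyTable] = {}
    for category in categories:
        cat = sub[sub["category"] == category]
        group_n = len(cat)
        rows = []
        totals = {BEFORE: 0, AFTER: 0}
        for view in ("gun_rights", "gun_control"):
            v = cat[cat["advocacy"] == view]
            b = int((v["window"] == BEFORE).sum())
            a = int((v["window"] == AFTER).sum())
            totals[BEFORE] += b
            totals[AFTER] += a
            rows.append(_advocacy_row(view, b, a, group_n))
        total = _advocacy_row(TOTAL_LABEL, totals[BEFORE], totals[AFTER], group_n)
        out[category] = AdvocacyTable(group=category, rows=rows, total=total)
    return out


# --- counterfactual contrast ----------------------------------------------

@dataclass(frozen=True)
class ContrastRow:
    label: str
    target_delta_pct: float | None
    control_delta_pct: float | None
    contrast_points: float | None
    used_control_total: bool
    event_attributable: bool


@dataclass
class ContrastReport:
    """Target-minus-control delta contrasts, per class and on totals.

    Positive contrast points flag change beyond what the event-agnostic
    control moved over the same window (descriptive, no inference).
    """

    target_group: str
    control_group: str
    rows: list[ContrastRow]
    total: ContrastRow
    warnings: list[str] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "class_label": r.label,
                    "target_delta_pct": r.target_delta_pct,
                    "control_delta_pct": r.control_delta_pct,
                    "contrast_points": r.contrast_points,
                    "used_control_total": r.used_control_total,
                    "event_attributable": r.event_attributable,
                }
                for r in [*self.rows, self.total]
            ]
        )


def _contrast(label: str, target_d: float | None, control_d: float | None,
              used_total: bool) -> ContrastRow:
    if target_d is None or control_d is None:
        points = None
        attributable = False
    else:
        points = round_half_away(target_d - control_d)
        attributable = target_d > control_d
    return ContrastRow(label, target_d, control_d, points, used_total, attributable)


def control_contrast(target: CrossTab, control: CrossTab) -> ContrastReport:
    """Compare a category's deltas to the control's, class by class.

    Classes absent from the control fall back to the control total delta
    (flagged and warned).
    """
    control_by_label = {r.label: r for r in control.rows}
    control_total_d = control.total.delta_pct if control.total else None
    warnings: list[str] = []
    rows = []
    for r in target.rows:
        if r.label in control_by_label:
            rows.append(_contrast(r.label, r.delta_pct,
                                  control_by_label[r.label].delta_pct, False))
        else:
            warnings.append(
                f"class {r.label!r} missing from control '{control.group}'; "
                "contrast uses control total"
            )
            rows.append(_contrast(r.label, r.delta_pct, control_total_d, True))
    total = _contrast(
        TOTAL_LABEL,
        target.total.delta_pct if target.total else None,
        control_total_d,
        False,
    )
    return ContrastReport(
        target_group=target.group,
        control_group=control.group,
        rows=rows,
        total=total,
        warnings=warnings,
    )


def brute_force_window_counts(
    records: pd.DataFrame, category: str, window: EventWindow
) -> tuple[int, int]:
    """Independent plain-loop recount of (before_n, after_n) for a category.

    Deliberately avoids the cross-tab machinery; used as an oracle in tests
    and cross-checks.
    """
    before = after = 0
    for day, cat in zip(records["day"].tolist(), records["category"].tolist()):
        if cat != category:
            continue
        w = window.assign(int(day))
        if w == BEFORE:
            before += 1
        elif w == AFTER:
            after += 1
    return before, after
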