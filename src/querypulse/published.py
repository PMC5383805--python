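"""Keyed-in summary tables from the original Yahoo! search-log study.

The raw 2012 search logs behind the original firearm-search event-window
analysis are proprietary and were never deposited; what survives are the
printed summary tables.  Their integer counts and shares are keyed in here
as *inputs*, so the package's arithmetic (delta %, cumulative %, category
shares, advocacy-table reconstruction) can be replayed against the printed
percentages.

``TABLE2`` rows carry exact (before, after) integer counts per website
class.  Listed rows do not exhaust a category's total (the source listed
only the most-visited classes), so :func:`table2_crosstab` appends the
implied residual row before the total — exactly the cross-tab structure the
package reports.

``TABLE3`` prints only each advocacy row's n and before/after shares; deltas
are recovered by integer-count reconstruction
(:func:`querypulse.windows.reconstructed_delta_percent`).  Two rows are
arithmetically irrecoverable from the printed precision — see
:data:`TABLE3_IRRECOVERABLE`.
"""

from __future__ import annotations

from .windows import CrossTab, crosstab_from_counts

#: Table of category totals (overall distribution of classified queries).
TABLE1_CATEGORY = {
    "gun_type": 3_370_523,
    "shooting": 1_270_122,
    "ammunition": 954_363,
    "law_related": 58_580,
}
TABLE1_FIREARM_TOTAL = 5_653_588
TABLE1_CONTROL_TOTAL = 597_859

TABLE1_TLD = {
    "commercial": 4_976_990,
    "noncommercial": 374_863,
    "government": 59_939,
    "educational_institution": 9_419,
    "other": 232_377,
}

TABLE1_CONTENT = {
    "retail": 1_714_504,
    "news": 1_321_706,
    "educational": 1_148_897,
    "showbiz": 118_174,
    "other": 1_350_307,
}

TABLE1_ADVOCACY = {"gun_rights": 45_848, "gun_control": 20_733}
TABLE1_ADVOCACY_TOTAL = 66_581

#: Before/after website-class counts per query category; each entry is
#: (class label, before_n, after_n).  ``total`` is the printed category
#: total (listed rows deliberately do not sum to it).
TABLE2: dict[str, dict] = {
    "gun_type": {
        "rows": [
            ("retail content, .com", 370_002, 595_793),
            ("news content, .com", 340_883, 254_806),
            ("educational content, .com", 196_435, 363_860),
            ("educational content, .org", 46_886, 138_093),
            ("other content, .com", 293_009, 481_025),
        ],
        "total": (1_345_833, 2_019_526),
    },
    "shooting": {
        "rows": [
            ("news content, .com", 51_678, 596_555),
            ("educational content, .com", 26_941, 67_209),
            ("educational content, .org", 7_911, 46_919),
            ("showbiz content, .com", 15_732, 28_403),
            ("other content, .com", 98_564, 221_328),
        ],
        "total": (236_050, 1_023_767),
    },
    "ammunition": {
        "rows": [
            ("retail content, .com", 163_272, 445_974),
            ("educational content, .com", 31_256, 64_431),
            ("news content, .com", 10_849, 50_176),
            ("other content, .com", 36_104, 64_607),
        ],
        "total": (268_670, 685_488),
    },
    "law_related": {
        "rows": [
            ("educational content, .org", 2_817, 22_612),
            ("educational content, .com", 1_823, 10_650),
            ("educational content, .edu", 431, 2_991),
            ("news content, .com", 383, 2_280),
            ("other content, .com", 1_502, 7_476),
        ],
        "total": (7_965, 50_615),
    },
    "control": {
        "rows": [
            ("retail content, .com", 75_551, 66_658),
            ("educational content, .com", 45_550, 42_414),
            ("other content, .com", 137_068, 129_152),
            ("other content, .other", 12_254, 11_351),
            ("other content, .org", 10_233, 9_724),
        ],
        "total": (308_603, 281_927),
    },
}

#: Printed delta % per Table-2 row label and total, for verification.
TABLE2_PRINTED_DELTA = {
    "gun_type": {
        "retail content, .com": 61.02,
        "news content, .com": -25.25,
        "educational content, .com": 85.23,
        "educational content, .org": 194.53,
        "other content, .com": 64.17,
        "total": 50.06,
    },
    "shooting": {
        "news content, .com": 1054.37,
        "educational content, .com": 149.47,
        "educational content, .org": 493.09,
        "showbiz content, .com": 80.54,
        "other content, .com": 124.55,
        "total": 333.71,
    },
    "ammunition": {
        "retail content, .com": 173.15,
        "educational content, .com": 106.14,
        "news content, .com": 362.49,
        "other content, .com": 78.95,
        "total": 155.14,
    },
    "law_related": {
        "educational content, .org": 702.70,
        "educational content, .com": 484.20,
        "educational content, .edu": 593.97,
        "news content, .com": 495.30,
        "other content, .com": 397.74,
        "total": 535.47,
    },
    "control": {
        "retail content, .com": -11.77,
        "educational content, .com": -6.88,
        "other content, .com": -5.78,
        "other content, .other": -7.37,
        "other content, .org": -4.97,
        "total": -8.64,
    },
}

#: Printed cumulative % per Table-2 listed row, in listed order.  The
#: shooting-category third entry was printed as 62.28, which is inconsistent
#: with the row counts AND with the next printed entry (66.78 = 63.28 + the
#: showbiz row's 3.50 share); the arithmetically consistent 63.28 is kept.
TABLE2_PRINTED_CUMULATIVE = {
    "gun_type": [28.70, 46.40, 63.05, 68.54, 91.54],
    "shooting": [51.45, 58.93, 63.28, 66.78, 92.18],
    "ammunition": [63.85, 73.88, 80.28, 90.83],
    "law_related": [43.41, 64.70, 70.54, 75.09, 90.41],
    "control": [24.08, 38.98, 84.06, 88.06, 91.44],
}

#: Advocacy-view rows: (category, view) → (n, before %, after %, printed delta %).
TABLE3 = {
    ("gun_type", "gun_rights"): (40_069, 28.29, 71.71, 153.53),
    ("gun_type", "gun_control"): (18_929, 14.97, 85.03, 467.93),
    ("gun_type", "total"): (58_998, 24.01, 75.99, 216.42),
    ("shooting", "gun_rights"): (2_490, 39.04, 60.96, 56.17),
    ("shooting", "gun_control"): (455, 17.58, 82.42, 368.75),
    ("shooting", "total"): (2_945, 35.72, 64.28, 79.94),
    ("ammunition", "gun_rights"): (2_316, 36.44, 63.56, 74.41),
    ("ammunition", "gun_control"): (170, 20.59, 79.41, 285.71),
    ("ammunition", "total"): (2_486, 35.36, 64.64, 82.82),
    ("law_related", "gun_rights"): (973, 21.69, 78.31, 261.14),
    ("law_related", "gun_control"): (1_179, 11.62, 88.38, 660.58),
    ("law_related", "total"): (2_152, 16.17, 83.83, 418.39),
}

#: Rows whose printed delta cannot be recovered from the printed (n, share):
#: at n ≈ 40k–59k a 2-decimal share no longer pins down the integer split,
#: and the printed 153.53 is in fact inconsistent with its own printed
#: 28.29 % before share (which implies 153.47–153.50).  These rows were
#: evidently computed from unrounded counts that were never published.
TABLE3_IRRECOVERABLE = {("gun_type", "gun_rights"), ("gun_type", "total")}


def table2_crosstab(category: str) -> CrossTab:
    """Replay one category's printed table through the cross-tab machinery.

    The residual (unlisted classes) row is derived from the printed total so
    that counts conserve and cumulative % reaches 100.
    """
    entry = TABLE2[category]
    rows = list(entry["rows"])
    total_b, total_a = entry["total"]
    resid_b = total_b - sum(b for _, b, _ in rows)
    resid_a = total_a - sum(a for _, _, a in rows)
    return crosstab_from_counts(category, rows + [("residual classes", resid_b, resid_a)])
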