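"""Published cohort summary tables for the FVIIa variant MAPPs study.

These are the printed per-donor summary cells for an 11-donor MAPPs cohort
run against four FVIIa constructs — wild type (WT), the immunogenic
engineered analog Vatreptacog alfa (VA), and two deimmunized analogs (DI-1,
DI-2). They are inputs for the downstream statistics this package computes
(cluster cohort frequencies, cluster-based responder rates, donor-level
aggregation) and for regression tests of those statistics.

``None`` marks a cell with no data: the donor yielded no peptides for that
construct, which is different from an observed 0 percent.
"""

from __future__ import annotations

DONORS = tuple(f"D{i}" for i in range(1, 12))

CONSTRUCT_IDS = ("WT", "VA", "DI-1", "DI-2")

#: Mutation-region ("cluster 8") percentage of each donor's eluate, one row
#: per construct. Values are integer percentages as printed; None = the donor
#: yielded no peptides for that construct (blank cell).
CLUSTER8_WITHIN_DONOR_PCT: dict[str, dict[str, int | None]] = {
    "WT": dict(zip(DONORS, (6, 0, 19, 0, 0, 0, 0, 0, 0, 0, 0))),
    "VA": dict(zip(DONORS, (58, 38, 54, 5, 7, None, 24, 3, 6, None, 29))),
    "DI-1": dict(zip(DONORS, (48, 0, 48, 5, 0, 0, 33, 0, 0, 0, 40))),
    "DI-2": dict(zip(DONORS, (30, 29, 73, 2, 0, 0, 14, 0, 2, 13, 30))),
}

#: Printed cluster locations and spanning sequences for the mutation-region
#: cluster of each construct (coordinates as printed, mature numbering).
CLUSTER8_LOCATION: dict[str, tuple[int, int, str]] = {
    "WT": (291, 315, "DRGATALELMVLNVPRLMTQDCLQQ"),
    "VA": (289, 316, "LLDRGATALVLQVLNVPRLMTQDCLQQS"),
    "DI-1": (283, 312, "VSGWGQLLDRGATALVLQVLDVPRLMTQDC"),
    "DI-2": (290, 320, "LDRGATALVLQVLEVPRLMTQDCLQQSRKVG"),
}

#: Per donor x construct peptide yield summary:
#: (total, unique, mean length, min length, max length).
DONOR_CONSTRUCT_SUMMARY: dict[tuple[str, str], tuple[int, int, int, int, int]] = {
    ("D1", "DI-1"): (29, 29, 16, 13, 19),
    ("D1", "DI-2"): (20, 20, 17, 14, 24),
    ("D1", "VA"): (26, 25, 17, 13, 26),
    ("D1", "WT"): (18, 18, 17, 14, 19),
    ("D2", "DI-1"): (14, 12, 16, 13, 22),
    ("D2", "DI-2"): (14, 11, 16, 13, 18),
    ("D2", "VA"): (21, 17, 17, 14, 24),
    ("D2", "WT"): (15, 14, 17, 14, 23),
    ("D3", "DI-1"): (25, 24, 16, 13, 19),
    ("D3", "DI-2"): (33, 30, 17, 13, 24),
    ("D3", "VA"): (35, 31, 17, 13, 24),
    ("D3", "WT"): (27, 25, 18, 14, 25),
    ("D4", "DI-1"): (74, 69, 18, 12, 25),
    ("D4", "DI-2"): (66, 64, 18, 13, 25),
    ("D4", "VA"): (59, 58, 18, 13, 25),
    ("D4", "WT"): (71, 69, 18, 12, 25),
    ("D5", "DI-1"): (40, 38, 17, 13, 22),
    ("D5", "DI-2"): (44, 42, 17, 12, 22),
    ("D5", "VA"): (45, 43, 17, 12, 24),
    ("D5", "WT"): (50, 47, 17, 12, 22),
    ("D6", "DI-1"): (41, 37, 16, 13, 21),
    ("D6", "DI-2"): (38, 33, 16, 13, 21),
    ("D6", "VA"): (39, 34, 16, 12, 21),
    ("D6", "WT"): (46, 39, 16, 12, 21),
    ("D7", "DI-1"): (75, 68, 17, 10, 25),
    ("D7", "DI-2"): (49, 48, 16, 10, 25),
    ("D7", "VA"): (54, 52, 17, 10, 25),
    ("D7", "WT"): (44, 43, 17, 10, 25),
    ("D8", "DI-1"): (25, 23, 17, 13, 23),
    ("D8", "DI-2"): (31, 29, 17, 13, 25),
    ("D8", "VA"): (32, 29, 18, 13, 25),
    ("D8", "WT"): (33, 29, 17, 13, 23),
    ("D9", "DI-1"): (52, 50, 17, 13, 25),
    ("D9", "DI-2"): (50, 48, 18, 13, 25),
    ("D9", "VA"): (49, 47, 17, 13, 25),
    ("D9", "WT"): (55, 52, 18, 11, 25),
    ("D10", "DI-1"): (9, 6, 18, 16, 20),
    ("D10", "DI-2"): (23, 21, 17, 13, 20),
    ("D10", "VA"): (10, 7, 18, 14, 20),
    ("D10", "WT"): (17, 16, 16, 14, 20),
    ("D11", "DI-1"): (43, 40, 16, 11, 20),
    ("D11", "DI-2"): (43, 40, 16, 13, 26),
    ("D11", "VA"): (35, 33, 17, 13, 26),
    ("D11", "WT"): (31, 29, 17, 13, 25),
}

#: Per-donor summary pooled over the four constructs:
#: (total, unique, mean length, min length, max length).
DONOR_SUMMARY: dict[str, tuple[int, int, int, int, int]] = {
    "D1": (93, 55, 17, 13, 26),
    "D2": (64, 31, 17, 13, 24),
    "D3": (120, 74, 17, 13, 25),
    "D4": (270, 80, 18, 12, 25),
    "D5": (179, 55, 17, 12, 24),
    "D6": (164, 43, 16, 12, 21),
    "D7": (222, 96, 17, 10, 25),
    "D8": (121, 37, 17, 13, 25),
    "D9": (206, 60, 18, 11, 25),
    "D10": (59, 24, 17, 13, 20),
    "D11": (152, 72, 16, 11, 26),
}

#: T-cell proliferation cohort: 50 donors; number called responders (day-8
#: SI > 2) per construct. "Almost all" responded to VA; the printed rates
#: are 0% (WT), 2% (DI-1) and 0% (DI-2).
TCELL_COHORT_SIZE = 50
TCELL_RESPONDER_COUNTS: dict[str, int] = {"WT": 0, "DI-1": 1, "DI-2": 0}


def within_donor_pct(construct_id: str) -> dict[str, float | None]:
    """Within-donor mutation-cluster percentages, keyed by donor."""
    row = CLUSTER8_WITHIN_DONOR_PCT[construct_id]
    return {d: (None if v is None else float(v)) for d, v in row.items()}


def presence_pattern(construct_id: str) -> dict[str, bool]:
    """Donor -> presents-the-cluster flags derived from the printed cells.

    A donor presents the cluster when its within-donor percentage is present
    and > 0; blank cells (no peptides at all) are non-presenting.
    """
    return {
        d: (v is not None and v > 0)
        for d, v in CLUSTER8_WITHIN_DONOR_PCT[construct_id].items()
    }
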