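"""Recompute the published downstream statistics from the printed tables.

The study's printed per-donor summary cells are themselves inputs: feeding
them through the package's statistics reproduces every derived number —
cluster cohort frequencies, cluster-based responder rates, donor-level
aggregation, and the T-cell responder percentages. Writes
results/published/published_statistics.tsv.
"""

from pathlib import Path

import pandas as pd

from mappskit.mapps import (
    DonorConstructSummary,
    cluster_frequency,
    cluster_responder_rate,
    percent_inhibition,
    summarize_donor,
)
from mappskit.reference_tables import (
    CONSTRUCT_IDS,
    DONOR_CONSTRUCT_SUMMARY,
    DONORS,
    TCELL_COHORT_SIZE,
    TCELL_RESPONDER_COUNTS,
    presence_pattern,
    within_donor_pct,
)
from mappskit.rounding import round_half_away

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out = RESULTS / "published"
    out.mkdir(parents=True, exist_ok=True)
    rows = []

    for cid in CONSTRUCT_IDS:
        freq = cluster_frequency(presence_pattern(cid), len(DONORS))
        rows.append({"statistic": f"cluster_cohort_frequency_{cid}",
                     "value": round_half_away(freq), "exact": freq})
        print(f"{cid}: mutation-region cluster presented by "
              f"{round_half_away(freq)}% of the 11-donor cohort")

    va = within_donor_pct("VA")
    for variant in ("DI-1", "DI-2"):
        rate, n_eval = cluster_responder_rate(va, within_donor_pct(variant))
        rows.append({"statistic": f"cluster_responder_rate_{variant}",
                     "value": round_half_away(rate), "exact": rate})
        print(f"{variant}: {round_half_away(rate)}% of {n_eval} evaluable donors "
              "show a cluster-frequency decrease vs VA")
        inh = {d: percent_inhibition(va[d], within_donor_pct(variant)[d]) for d in va}
        mean_inh = pd.Series({d: v for d, v in inh.items() if v is not None}).mean()
        rows.append({"statistic": f"mean_pct_inhibition_{variant}",
                     "value": round(mean_inh, 1), "exact": mean_inh})

    for donor in DONORS:
        summaries = [
            DonorConstructSummary(d, cid, t, u, float(m), mn, mx)
            for (d, cid), (t, u, m, mn, mx) in DONOR_CONSTRUCT_SUMMARY.items()
            if d == donor
        ]
        row = summarize_donor(summaries)
        rows.append({"statistic": f"donor_total_{donor}", "value": row.total_peptides,
                     "exact": row.total_peptides})
    d1 = next(r for r in rows if r["statistic"] == "donor_total_D1")
    print(f"D1 aggregates to {d1['value']} peptides across the four constructs")

    for cid, count in TCELL_RESPONDER_COUNTS.items():
        pct = 100.0 * count / TCELL_COHORT_SIZE
        rows.append({"statistic": f"tcell_pct_responders_{cid}",
                     "value": round_half_away(pct), "exact": pct})
        print(f"T-cell assay: {round_half_away(pct)}% of {TCELL_COHORT_SIZE} donors "
              f"respond to {cid}")

    pd.DataFrame(rows).to_csv(out / "published_statistics.tsv", sep="\t", index=False)
    print(f"wrote {out / 'published_statistics.tsv'}")


if __name__ == "__main__":
    main()
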