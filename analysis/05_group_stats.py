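"""Run the group-pooling decision pipeline over every simulated endpoint.

For each endpoint and day: Shapiro-Wilk gate, three-way NAC comparison
(ANOVA/Kruskal-Wallis), pool-to-gNAC decision, and the final gNAC-vs-CONT
(or NAC30-vs-CONT) test — the same decision structure as the source study's
result tables.  Also aggregates the simulated rater scores.  Writes
results/analysis/morphometry_stats.csv, planimetry_stats.csv,
scores_summary.csv.
"""

from pathlib import Path

import pandas as pd

from scarkit import morphometry as mm
from scarkit import scoring, stats
from scarkit.reference import MEASUREMENTS

IN = Path("results/analysis/inputs")
OUT = Path("results/analysis")


def main() -> None:
    # morphometry endpoints: the ten measurements plus the eight indices
    table = pd.read_csv(IN / "measurements.csv")
    per_sample, _ = mm.index_table(table)
    merged = table.merge(per_sample, on=["animal", "group", "day"])
    endpoints = list(MEASUREMENTS) + ["SCI", "DCI", "WSI", "GCI", "GHI",
                                      "RHI", "MRI", "GRI"]
    morpho_stats = stats.run_table(merged, endpoints)
    morpho_stats.to_csv(OUT / "morphometry_stats.csv", index=False)
    pooled = morpho_stats.pooled.mean()
    print(f"morphometry: {len(morpho_stats)} endpoint-days, "
          f"{pooled:.0%} pooled to gNAC")
    sig = morpho_stats[(morpho_stats.gnac_vs_cont_p <= 0.05)
                       | (morpho_stats.nac30_vs_cont_p <= 0.05)]
    print(f"nominally significant final comparisons: {len(sig)} "
          f"(expected ~{0.05 * len(morpho_stats):.0f} under the null)")

    # planimetry endpoints per day
    records = pd.read_csv(IN / "planimetry_records.csv")
    rows = []
    for day, day_df in records.groupby("day"):
        for col in ("area_mm2", "length_mm", "width_mm"):
            sub = day_df[["group", col]].rename(columns={col: "value"})
            rows.append(stats.run_endpoint(sub, endpoint=col, day=int(day)).to_row())
    plani_stats = pd.DataFrame(rows)
    plani_stats.to_csv(OUT / "planimetry_stats.csv", index=False)
    early = plani_stats[(plani_stats.day <= 4) & (plani_stats.endpoint == "area_mm2")]
    print("\nearly scar-area comparisons (the injected NAC30 effect):")
    print(early[["day", "branch", "pooled", "three_group_p",
                 "gnac_vs_cont_p", "nac30_vs_cont_p"]]
          .to_string(index=False, float_format="%.3f"))

    scores = pd.read_csv(IN / "scores.csv")
    scoring.aggregate_scores(scores).to_csv(OUT / "scores_summary.csv", index=False)
    print(f"\naggregated {len(scores)} rater scores")


if __name__ == "__main__":
    main()
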