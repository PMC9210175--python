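#!/usr/bin/env python
"""Summarise gender gaps, severity patterns and policy prioritisation.

Reads the table bundle produced by 02_run_pipeline.py (regenerating it if
absent) and reports: the largest male and female gaps per severity class,
the tally of severity patterns across the 32 indicators, and how the three
targeting approaches (closest to inclusion, farthest from inclusion,
largest disability gap) rank the nine domains.
"""

import subprocess
import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
TABLES = ROOT / "results" / "tables"
RESULTS = ROOT / "results"


def main() -> None:
    if not (TABLES / "gender_gaps.csv").exists():
        subprocess.run([sys.executable, str(ROOT / "analysis" / "02_run_pipeline.py")], check=True)

    gaps = pd.read_csv(TABLES / "gender_gaps.csv")
    patterns = pd.read_csv(TABLES / "severity_patterns.csv")
    rankings = pd.read_csv(TABLES / "priority_rankings.csv")

    domain_gaps = gaps[gaps["metric"] == "inclusion_pct"]
    rows = []
    for cls, grp in domain_gaps.groupby("severity_class"):
        worst_f = grp.loc[grp["gap"].idxmax()]
        worst_m = grp.loc[grp["gap"].idxmin()]
        rows.append({"severity_class": cls, "worse_gender": "female",
                     "unit_id": worst_f["unit_id"], "gap_points": round(worst_f["gap"], 1)})
        rows.append({"severity_class": cls, "worse_gender": "male",
                     "unit_id": worst_m["unit_id"], "gap_points": round(-worst_m["gap"], 1)})
    largest = pd.DataFrame(rows)
    largest.to_csv(RESULTS / "largest_gender_gaps.csv", index=False)
    print("largest domain-level inclusion gaps by severity class:")
    print(largest.to_string(index=False))

    tally = patterns["pattern"].value_counts()
    tally.rename_axis("pattern").rename("n_indicators").to_csv(
        RESULTS / "pattern_tally.csv"
    )
    print("\nseverity-pattern tally over the 32 indicators:")
    print(tally.to_string())

    print("\ntop-three domains per targeting approach:")
    top = rankings[rankings["rank"] <= 3].pivot(
        index="rank", columns="approach", values="domain_id"
    )
    top.to_csv(RESULTS / "priority_top3.csv")
    print(top.to_string())


if __name__ == "__main__":
    main()
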