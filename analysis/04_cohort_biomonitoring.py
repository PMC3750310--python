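#!/usr/bin/env python
"""Synthetic cohort and internal-dose (biomonitoring) statistics.

Generates a 207-participant synthetic cohort with the survey's demographic
and exposure structure, then runs the biomonitoring analyses: urinary and
blood cadmium contrasts by sex and smoking status (Mann-Whitney U) and the
external-internal dose correlations (UCd-age, BCd-total exposure,
BCd-tobacco intake among smokers).

Writes results/cohort/cohort.csv and biostats.json.
"""

import json
from pathlib import Path

from cadexpo.pipeline import run_pipeline

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main() -> None:
    run_pipeline(["synth-cohort", "biostats"], OUT, seed=42)
    report = json.loads((OUT / "biostats.json").read_text())
    bcd = report["comparisons"]["bcd_by_smoking"]
    print(
        f"BCd smokers vs non-smokers: means {bcd['means'][0]:.2f} vs "
        f"{bcd['means'][1]:.2f} ug/L, U={bcd['U']:.0f}, p={bcd['p_value']:.2g}"
    )
    for name, corr in report["correlations"].items():
        print(f"corr {name}: r={corr['r']:.2f} (p={corr['p_value']:.3g}, n={corr['n']})")
    print(
        "\nBlood cadmium tracks recent exposure (clear smoking contrast and a "
        "moderate correlation with total exposure); urinary cadmium rises "
        "weakly with age, reflecting cumulative body burden."
    )


if __name__ == "__main__":
    main()
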