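#!/usr/bin/env python
"""Summarize detection variability across demographic and diagnostic strata.

Reads the completed comparison run (02) and prints, per feature set, the
AUROC gap between the best- and worst-detected subgroups along with the
count of subgroups above the 0.90 / 0.95 bars — the fairness-audit analog
showing that hybrid structured+text detection shrinks subgroup gaps left
by codes and chief concerns alone.
"""

from pathlib import Path

import pandas as pd

RUN = Path("results/experiment")


def main() -> None:
    if not (RUN / "subgroup_gaps.csv").exists():
        raise SystemExit("run analysis/02_compare_feature_sets.py first")
    gaps = pd.read_csv(RUN / "subgroup_gaps.csv")
    print("subgroup AUROC gaps (max - min stratum AUROC):")
    print(gaps.to_string(index=False))

    demo = pd.read_csv(RUN / "subgroup_demographic.csv")
    worst = (
        demo[demo["feature_set"] == "ICD_CC"]
        .dropna(subset=["auroc"])
        .nsmallest(3, "auroc")[["family", "stratum", "n_positive", "auroc"]]
    )
    print("\nworst-detected demographic strata under ICD/CC alone:")
    print(worst.to_string(index=False))

    hybrid = demo[demo["feature_set"] == "ACS_LLM"].dropna(subset=["auroc"])
    merged = worst.merge(
        hybrid[["family", "stratum", "auroc"]],
        on=["family", "stratum"],
        suffixes=("_icd_cc", "_hybrid"),
    )
    merged["improvement"] = merged["auroc_hybrid"] - merged["auroc_icd_cc"]
    print("\nhybrid (aCS + Likert text) recovery on those strata:")
    print(merged.to_string(index=False))


if __name__ == "__main__":
    main()
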