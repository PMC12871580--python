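#!/usr/bin/env python
"""Render figure analogs from the comparison run.

Produces the pairwise AUROC-difference heatmap with DeLong significance
stars, the stratified-performance heatmaps (demographic and diagnostic),
and the per-feature-set mean ROC plot under results/experiment/.
"""

from pathlib import Path

from sitbdetect.experiment import render_reports

RUN = Path("results/experiment")


def main() -> None:
    if not (RUN / "manifest.json").exists():
        raise SystemExit("run analysis/02_compare_feature_sets.py first")
    for path in render_reports(RUN):
        print(f"wrote {path}")


if __name__ == "__main__":
    main()
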