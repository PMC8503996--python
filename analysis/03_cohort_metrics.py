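"""Simulate the patient cohorts (16 non-contrast chest, 12 contrast chest,
23 contrast abdomen), extract ROI metrics, and compare reconstructions with
repeated-measures ANOVA + Bonferroni pairwise tests.

Expected pattern: high-strength DLR cuts group-mean noise by roughly a
third versus the ASIR-V 50 baseline in every protocol (adjusted p well
below 0.05), with attenuation essentially unchanged.
"""

from pathlib import Path

import pandas as pd

from ctiq.pipeline import (RunConfig, compare_metrics,
                           percent_changes_from_summary,
                           simulate_cohort_metrics)
from ctiq.roi_metrics import summarize_metrics

RESULTS = Path("results")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cfg = RunConfig(seed=1)
    tables = [simulate_cohort_metrics(cfg, proto) for proto in cfg.cohort_sizes]
    metrics = pd.concat(tables, ignore_index=True)
    summary = (metrics.groupby("protocol", group_keys=True)
               .apply(summarize_metrics, include_groups=False)
               .reset_index(level=0).reset_index(drop=True))
    stats = compare_metrics(metrics, cfg.baseline)
    pct = percent_changes_from_summary(summary, cfg.baseline)

    metrics.to_csv(RESULTS / "metric_table.csv", index=False)
    summary.to_csv(RESULTS / "metric_group_summary.csv", index=False)
    stats.to_csv(RESULTS / "metric_stats.csv", index=False)
    pct.to_csv(RESULTS / "percent_changes.csv", index=False)

    noise = summary[summary.metric == "noise"].pivot(
        index="protocol", columns="reconstruction_id", values="mean").round(1)
    print("group-mean noise (HU):")
    print(noise.to_string())
    print("\nDLR-H vs baseline:")
    print(pct[pct.metric == "noise"].to_string(index=False))
    sig = stats[(stats.test == "paired_t") & (stats.metric == "noise")]
    print("\nnoise comparisons (Bonferroni-adjusted p):")
    print(sig[["protocol", "comparison", "p_adjusted", "direction"]].to_string(index=False))


if __name__ == "__main__":
    main()
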