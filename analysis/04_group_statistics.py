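#!/usr/bin/env python
"""Condition comparisons: summaries, one-way ANOVA and Tukey HSD.

Reads the per-cell results of 02, summarizes polar-chromosome counts per
condition (mean, SD, 95% CIs of both), then runs one-way ANOVA followed by
pairwise two-sided Tukey HSD across conditions, writing the tidy
comparisons table with significance stars.

Run after 02:  python analysis/04_group_statistics.py
"""

from pathlib import Path

import pandas as pd

from spindlekin import io as skio
from spindlekin.stats import (comparisons_table, one_way_anova,
                              summarize_group, tukey_hsd)

OUT = Path("results")


def main() -> None:
    per_cell = pd.read_csv(OUT / "per_cell_results.csv")
    groups, labels, rows = [], [], []
    for label, sub in per_cell.groupby("condition_label"):
        vals = sub["polar_count"].dropna().to_numpy(float)
        s = summarize_group(vals)
        rows.append({
            "condition_label": label, "n": s.n, "mean": s.mean, "sd": s.sd,
            "ci95_mean_lo": s.ci95_mean[0], "ci95_mean_hi": s.ci95_mean[1],
            "ci95_sd_lo": s.ci95_sd[0], "ci95_sd_hi": s.ci95_sd[1],
        })
        groups.append(vals)
        labels.append(str(label))
    summary = pd.DataFrame(rows)
    summary.to_csv(OUT / "polar_count_summary.csv", index=False,
                   float_format=skio.FLOAT_FORMAT)

    anova = one_way_anova(groups)
    print(f"one-way ANOVA on polar counts: F({anova.df_between},"
          f"{anova.df_within}) = {anova.f_statistic:.2f}, "
          f"p = {anova.p_value:.3g}")
    comps = comparisons_table(tukey_hsd(groups, labels))
    comps.to_csv(OUT / "polar_count_comparisons.csv", index=False,
                 float_format=skio.FLOAT_FORMAT)
    for _, r in comps.iterrows():
        print(f"  {r.group_a} vs {r.group_b}: diff {r['diff']:+.2f}, "
              f"q = {r.q:.2f}, p_adj = {r.p_adj:.3g} {r.stars}")
    print(f"tables -> {OUT}/polar_count_summary.csv, "
          f"polar_count_comparisons.csv")


if __name__ == "__main__":
    main()
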