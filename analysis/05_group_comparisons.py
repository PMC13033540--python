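#!/usr/bin/env python
"""Pairwise group comparisons and morphometric variance testing.

On the retained reference-cohort measurements: animal-level site means
(sides pooled), all pairwise Wilcoxon rank-sum tests per site with
Bonferroni correction (m = 6) and significance labels.  A synthetic
morphometric-ratio table then illustrates Levene's variance test at
the three shell locations.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

import shellbmd as sb
from shellbmd.io import pool_paired_sites
from shellbmd.synthetic import REFERENCE_ANIMAL_GROUPS, reference_cohort_config

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

config = reference_cohort_config(pixels_per_roi=1000, seed=0)
measurements, _ = sb.generate_cohort(config)
side_results = pool_paired_sites(measurements)
_, retained = sb.apply_exclusions(measurements, list(config.missing_sites), side_results)

comparisons = sb.compare_groups_per_site(retained, REFERENCE_ANIMAL_GROUPS, bonferroni_m=6)
frame = sb.comparisons_to_frame(comparisons)
frame.to_csv(OUT / "group_comparisons.csv", index=False)
print(frame.to_string(index=False))

sel = frame[(frame.group_a == 0) & (frame.group_b == 3)]
print()
print(
    "Finding: healthy vs severe (0 vs 3) is significant at every site "
    f"(max adjusted p = {sel.adj_p.max():.4g} <= 0.05); adjacent severity "
    "grades overlap, mirroring the weaker separation of mild disease."
)

# morphometric ratios: synthetic landmark sets per animal, group-dependent
# shoulder variance inflation to illustrate the variance-equality test
rng = np.random.default_rng(1)
ratio_rows = []
for animal_id, group in REFERENCE_ANIMAL_GROUPS.items():
    shoulder_sd = 0.04 + 0.05 * (group == 3)   # severe shells deform more variably
    ratio_rows.append(
        {
            "animal_id": animal_id,
            "group": group,
            "gular_hw": rng.normal(0.55, 0.04),
            "shoulder_hw": rng.normal(0.62, shoulder_sd),
            "total_hw": rng.normal(0.52, 0.04),
        }
    )
ratios = pd.DataFrame(ratio_rows)
ratios.to_csv(OUT / "morphometric_ratios.csv", index=False)

levene_report = {}
for col in ("gular_hw", "shoulder_hw", "total_hw"):
    groups = [ratios[ratios.group == g][col].to_numpy() for g in range(4)]
    stat, p = sb.levene_test(groups, center="mean")
    levene_report[col] = {"statistic": round(stat, 4), "p": round(p, 4)}
(OUT / "morphometry_levene.json").write_text(json.dumps(levene_report, indent=2))
print()
print("Levene variance-equality on synthetic H/W ratios:", json.dumps(levene_report))
print(f"Wrote group_comparisons.csv, morphometric_ratios.csv, morphometry_levene.json under {OUT}")
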