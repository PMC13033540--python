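#!/usr/bin/env python
"""Map one synthetic subject per severity group and extract ROI stats.

Builds a shell-like subject for each group (0 healthy .. 3 severe),
decomposes its spectral pair with the phantom-fitted model, rasterizes
the five ROIs (gular, scapula L/R, ilium L/R) on the BMD map and
summarizes each pixel population, comparing the mapped ROI mean with
the generator's ground truth.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import shellbmd as sb

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

spec = sb.default_phantom_spec()
v50, v200, _ = sb.build_phantom_pair(spec, noise_sd=0.0)
model = sb.fit_calibration(sb.measure_insert_vois(v50, v200, spec))

dists = sb.default_distributions()
rows = []
for group in range(4):
    s50, s200, truth, rois = sb.build_shell_subject(group, dists, seed=100 + group)
    bmd = sb.compute_bmd_map(s50, s200, model)
    for roi in rois:
        values = sb.extract_roi_values(roi, bmd)
        stats = sb.summarize_roi(values, bmd.voxel_volume_mm3())
        truth_vals = sb.extract_roi_values(roi, truth)
        rows.append(
            {
                "group": group,
                "site": roi.site,
                "side": roi.side,
                "mapped_mean": round(stats.mean, 2),
                "truth_mean": round(float(truth_vals.mean()), 2),
                "mapped_sd": round(stats.sd, 2),
                "pixel_count": stats.pixel_count,
                "total_volume_mm3": stats.total_volume_mm3,
            }
        )

frame = pd.DataFrame(rows)
frame.to_csv(OUT / "subject_roi_stats.csv", index=False)
print(frame.to_string(index=False))

err = np.abs(frame.mapped_mean - frame.truth_mean).max()
by_group = frame.groupby("group").mapped_mean.mean().round(1)
print()
print(
    f"Finding: mapped ROI means equal ground truth (max |error| {err:.2g} "
    "mgHA/cm^3, noise-free); subject-level mean BMD falls monotonically "
    f"with severity: {by_group.to_dict()}."
)
print(f"Wrote {OUT / 'subject_roi_stats.csv'}")
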