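#!/usr/bin/env python
"""Calibrate on the synthetic phantom and verify insert recovery.

Builds the default four-insert hydroxyapatite phantom (100/200/400/800
mgHA/cm^3) noise-free, measures shrunken insert VOIs at both energies,
fits the per-energy calibration lines, maps the phantom itself, and
reports the recovered density per insert.  A second pass with 15 HU
Gaussian noise shows the calibration's robustness.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import shellbmd as sb

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

spec = sb.default_phantom_spec()
basis = sb.default_basis()

rows = []
for noise_sd in (0.0, 15.0):
    v50, v200, truth = sb.build_phantom_pair(spec, basis, noise_sd=noise_sd, seed=0)
    samples = sb.measure_insert_vois(v50, v200, spec)
    model = sb.fit_calibration(samples)
    bmd = sb.compute_bmd_map(v50, v200, model)
    for density in spec.insert_densities:
        recovered = bmd.voxels[truth == density].mean()
        rows.append(
            {
                "noise_sd_hu": noise_sd,
                "insert_density": density,
                "recovered_mean_bmd": round(float(recovered), 4),
                "relative_error": round(float(abs(recovered - density) / density), 8),
                "slope_50": round(model.slope_50, 6),
                "slope_200": round(model.slope_200, 6),
                "r2_50": round(model.fit_r2_pair[0], 8),
            }
        )

frame = pd.DataFrame(rows)
frame.to_csv(OUT / "phantom_recovery.csv", index=False)
print(frame.to_string(index=False))

noise_free = frame[frame.noise_sd_hu == 0.0]
print()
print(
    "Finding: noise-free recovery is exact to machine precision "
    f"(max relative error {noise_free.relative_error.max():.1e}); with 15 HU "
    "noise the insert means stay within "
    f"{(frame[frame.noise_sd_hu == 15.0].relative_error.max() * 100):.2f}% of truth."
)
print(f"Wrote {OUT / 'phantom_recovery.csv'}")
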