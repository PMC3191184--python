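"""Bootstrap CIs over cells, per-culture SEs and densitometry normalization.

Simulates per-cell Pearson coefficients for one channel pair, reports the
mean with a 95% percentile-bootstrap CI (cells are the resampling unit),
summarizes percent colocalization as mean (SE) over independent cultures,
and normalizes a developmental western-blot series to its loading control.
"""

import numpy as np

from punctacoloc import DensitometryProfile, bootstrap_ci, densitometry_normalize, per_culture_se

rng = np.random.default_rng(7)

# 38 cells' Pearson coefficients for one staining pair
per_cell_rr = rng.normal(0.63, 0.12, size=38).clip(-1, 1)
ci = bootstrap_ci(per_cell_rr, level=0.95, n_reps=10_000, seed=1)
print(f"Pearson Rr over 38 cells: {ci}  (mean and 95% bootstrap CI)")

# percent colocalization from 3 independent cultures (cells nested in culture)
percents = np.r_[rng.normal(72, 6, 8), rng.normal(78, 6, 10), rng.normal(75, 6, 9)]
cultures = np.r_[["c1"] * 8, ["c2"] * 10, ["c3"] * 9]
mean, se = per_culture_se(percents, cultures)
print(f"% colocalization: {mean:.1f} ({se:.1f})  (mean and SE over 3 cultures)")

# band intensities across postnatal days, normalized to the loading control
profile = DensitometryProfile(
    timepoints=["P2", "P5", "P10", "P15", "P21", "P60"],
    band_intensity=[9.1, 8.7, 8.2, 5.0, 3.1, 2.4],
    control_intensity=[4.0, 4.1, 3.9, 4.0, 4.2, 4.1],
)
levels = densitometry_normalize(profile)
for tp, lvl in zip(profile.timepoints, levels):
    print(f"  {tp:>3}: {lvl:6.1f}% of {profile.timepoints[0]} level")
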