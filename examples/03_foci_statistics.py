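"""Quantify nuclear foci: shape factor and intensity CV under dispersal.

Generates synthetic nuclei bearing near-circular elliptical foci, segments
them, measures their circularity (4*pi*A/P^2), and then emulates formamide
disassembly by spreading the same integrated signal over larger, dimmer foci
and watching the nuclear intensity coefficient of variation fall.
"""

import numpy as np

from txfactory.foci_image_stats import (
    intensity_cv,
    measure_foci,
    segment_foci,
    treatment_comparison,
)
from txfactory.synthetic_data import (
    ImageGenParams,
    generate_dispersal_series,
    generate_nucleus_images,
)

images = generate_nucleus_images(ImageGenParams(n_images=30, seed=9))
sfs = []
for im in images:
    labels = segment_foci(im.image, im.mask)
    sfs.extend(measure_foci(im.image, labels)["shape_factor"].dropna())
print(f"{len(sfs)} foci segmented from {len(images)} nuclei: "
      f"shape factor {np.mean(sfs):.3f} +/- {np.std(sfs):.3f}")
print("  -> values near 1 mean near-circular foci, i.e. microspheres")

series = generate_dispersal_series(ImageGenParams(n_images=1, noise_sd=0.0, seed=11))
print("dispersal series (same integrated signal, foci spread wider):")
for factor, im in series:
    print(f"  spread x{factor:.1f}: intensity CV = {intensity_cv(im.image, im.mask).cv:.3f}")
print("  -> CV (SD/mean over the nucleus) drops as staining becomes diffuse")

control = [(im.image, im.mask) for im in generate_nucleus_images(ImageGenParams(n_images=25, seed=13))]
treated = [
    (im.image, im.mask)
    for i in range(25)
    for _, im in generate_dispersal_series(ImageGenParams(n_images=1, seed=100 + i), spread_factors=(2.5,))
]
summary, pairs = treatment_comparison(
    {"control": control, "formamide": treated}, min_cells_per_group=25
)
print(summary.to_string(index=False))
row = pairs.iloc[0]
print(f"CV difference control - formamide: {row.cv_diff:.3f} "
      f"[bootstrap 95% CI {row.ci_low:.3f}, {row.ci_high:.3f}]")
print("  -> the treated group's foci are disassembled: its CV is clearly lower")
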