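"""From dot annotations to the three supervision rasters.

Builds a density map, a 64x64-patch local count map and a pseudo foreground
mask for a small hand-made annotation set, and prints their totals: the
density map integrates to (approximately) the dot count, the local count map
redistributes exactly that mass over patches, and the mask covers the pixels
a counting model should attend to.
"""

import numpy as np

from badacount import (
    DotAnnotationSet,
    downsample_mask,
    make_density_map,
    make_foreground_mask,
    make_local_count_map,
)
from badacount.targets import default_threshold

dots = DotAnnotationSet(
    "field_001",
    [(40.0, 30.0), (90.0, 70.0), (100.0, 100.0), (31.0, 99.0)],
    image_size=(128, 128),
)
sigma = 4.0

density = make_density_map(dots, sigma=sigma)
counts = make_local_count_map(density, 64, 64)
mask = make_foreground_mask(density, default_threshold(sigma))
mask_lo = downsample_mask(mask, 8)

print(f"dots:                {len(dots)}")
print(f"density map total:   {density.total:.4f}   (~= dot count)")
print(f"local count map:\n{np.round(counts.values, 3)}")
print(f"local count total:   {counts.total:.4f}   (mass conserved)")
print(f"foreground pixels:   {int(mask.values.sum())} of {mask.values.size}")
print(f"1/8-scale mask cells: {int(mask_lo.values.sum())} of {mask_lo.values.size}")
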