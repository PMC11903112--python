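"""Round trip a synthetic cohort through label-mask rasterization.

Simulates nuclei, rasterizes them into integer label masks at
0.25 μm/pixel (the mask ingest path for segmentations that arrive as
images rather than polygons), re-extracts boundaries via marching
squares, and compares the re-measured areas with the generating ones.
"""

import numpy as np

from lobmorph import (
    polygon_area,
    rasterize_cohort,
    read_label_mask,
    simulate_cohort,
    spec_for_variant,
)

shapes, _, _ = simulate_cohort([spec_for_variant("pILC")], 1, seed=31,
                               nuclei_per_case=80)
truth = {s.nucleus_id: polygon_area(s.vertices) for s in shapes}

tiles, placement = rasterize_cohort(shapes, pixel_size=0.25, tile_size=512)
errors = []
for t_i, tile in enumerate(tiles):
    sub = placement[placement.tile == t_i]
    lab2id = dict(zip(sub.label, sub.nucleus_id))
    for s in read_label_mask(tile, 0.25):
        lab = int(s.nucleus_id.split("_")[1])
        a_true = truth[lab2id[lab]]
        errors.append(abs(polygon_area(s.vertices) - a_true) / a_true)

errors = np.array(errors)
print(f"{len(shapes)} nuclei rasterized into {len(tiles)} tile(s)")
print(f"area recovery error: median {np.median(errors):.2%}, "
      f"max {errors.max():.2%}")
print("\nSub-pixel marching-squares contours keep the mask round trip "
      "within a few percent; polygon input avoids this bias entirely.")
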