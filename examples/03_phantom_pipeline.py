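"""End-to-end run on a synthetic phantom acquisition.

Builds the organ phantom, simulates a positive-mode FT-ICR-like
acquisition over it (Gaussian peaks, ppm jitter, adducts, isotopes,
matrix clusters), and runs the full pipeline: picking, alignment, KMD
filtering, matrix flagging, series chaining, collapsing, annotation.
Finishes with a spatial check: the silk-gland acylcarnitine's ion
image should be confined to the silk glands.
"""

from kmdmsi import (
    PhantomSpec,
    build_phantom,
    ion_mz,
    run_pipeline,
    simulate_dataset,
)
from kmdmsi.imaging import ion_image, region_enrichment

phantom = build_phantom(PhantomSpec(height=32, width=32))
dataset, truth = simulate_dataset(phantom, seed=1)
result = run_pipeline(dataset)

print("pipeline stage counts:")
for key, value in result.summary.items():
    print(f"  {key:20s} {value}")

target = ion_mz("C13H25NO4", "[M+H]+")  # hexanoylcarnitine
img = ion_image(result.matrix, target, ppm_window=3.0)
frac = region_enrichment(img, phantom.region_masks["silk_glands"])
print(f"\nhexanoylcarnitine [M+H]+ at m/z {target:.4f}:")
print(f"  fraction of image intensity inside the silk glands: {frac:.3f}")
print(
    "\nCounts trace the workflow: picked centroids -> consensus bins -> "
    "lipid-window points -> CH2 series and collapsed adduct families; the "
    "enrichment near 1.0 shows the planted metabolite maps to its organ."
)
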