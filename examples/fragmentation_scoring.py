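"""Mitochondrial fragmentation dose response.

Renders wells whose cells switch from tubular (granulated) to punctate
(fragmented) mitochondria with increasing probability — the phenotype of
electron-transport-chain poisoning — and scores the detected objects by
area and form factor.
"""

import numpy as np

from mitoflux import (
    SimConfig, WellSpec, build_cell_rois, classify_fragmentation,
    detect_mito_objects, render_well_image, segment_nuclei,
)

print(f"{'frag_prob':>9} {'objects':>8} {'fragmented fraction':>20}")
for i, fp in enumerate((0.1, 0.5, 0.9)):
    spec = WellSpec("C4", n_cells=10000, frag_prob=fp)
    cfg = SimConfig(seed=14 + i, wells=[spec], image_size_px=(512, 512),
                    field_fraction=0.004)
    img, truth = render_well_image(spec, cfg)
    seg = segment_nuclei(img)
    rois = build_cell_rois(seg, img)
    objs = detect_mito_objects(img, rois)
    res = classify_fragmentation(objs)
    print(f"{fp:>9.1f} {len(objs):>8d} {res.fragmentation_fraction:>20.3f}")
print("-> the well-level fragmented fraction rises monotonically with the")
print("   simulated fragmentation probability; per-cell fractions are also")
print("   available via classify_fragmentation(...).per_cell_fraction.")
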