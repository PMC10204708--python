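"""Segment a synthetic root image and measure its diameter distribution.

Builds a single early-storage (type III) root on the blue imaging-box
background, runs the full pipeline (blueness segmentation, iterative ridge
detection, orientation-corrected classification) and compares the predicted
per-class constituent lengths with the generator's analytic ground truth.
"""

import numpy as np

from rootridge import CameraCalibration, analyze_frame
from rootridge.synthetic import generate_single_root

MM_PER_PX = 0.4

img, truth, root = generate_single_root("III", MM_PER_PX, seed=11)
print(f"rendered a type-III root: {root.length_mm:.0f} mm long, "
      f"max diameter {root.max_diameter_mm:.1f} mm, image {img.shape[:2]}")

res = analyze_frame(img, CameraCalibration(mm_per_px=MM_PER_PX))

print("\nconstituent length per diameter class (mm):")
print("  class      range     truth  predicted")
ranges = ["<2 mm   ", "2-6 mm  ", "6-20 mm ", ">20 mm  "]
for c, (t, p) in enumerate(zip(truth.class_lengths(), res.distribution.length_mm)):
    print(f"  {c + 1}      {ranges[c]}  {t:7.1f}  {p:9.1f}")
print(f"  total             {truth.total_length_mm:7.1f}"
      f"  {res.distribution.total_length_mm:9.1f}")
print("\nEach row is the total centerline length whose local diameter falls"
      "\nin that class; agreement within a few mm shows the ridge detector"
      "\nrecovers both the centerline and the local widths.")
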