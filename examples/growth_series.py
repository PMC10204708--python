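"""Track diameter-class dynamics across a simulated growth series.

Simulates an 80-root cassava system growing from week 2 to week 13,
analyzes one stratified 17-root subset per sampled week, and prints the
per-class percentage fractions over time — the signature of secondary
thickening: class 1 (fibrous) declines while classes 2-4 rise in turn.
"""

import numpy as np

from rootridge import CameraCalibration, analyze_frame
from rootridge.classify import growth_dynamics
from rootridge.synthetic import generate_time_series

MM_PER_PX = 0.6
cal = CameraCalibration(mm_per_px=MM_PER_PX)

per_week = {}
for scene in generate_time_series(
    seed=5, mm_per_px=MM_PER_PX, weeks=(3, 6, 9, 12), n_subsets=2
):
    res = analyze_frame(scene.image, cal)
    per_week.setdefault(scene.week, []).append(res.distribution)

table = growth_dynamics(per_week)
print("median percentage of total root length per diameter class:\n")
print("  week   class1   class2   class3   class4")
for week, grp in table.groupby("week"):
    med = grp.sort_values("diameter_class")["median_pct"].values
    print("  {:4g}  ".format(week) + "  ".join(f"{m:7.1f}" for m in med))
print("\nClass 1 (<2 mm, fibrous) shrinks as roots thicken into transition"
      "\n(2-6 mm), early-storage (6-20 mm) and storage (>20 mm) classes.")
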