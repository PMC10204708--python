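"""Simulation-based validation experiments at desk scale.

Three studies of increasing complexity compare the pipeline's per-class
constituent lengths against the generator's analytic ground truth:

1. *Single roots*, rendered at a resolution where even fibrous (type I)
   roots span at least 3 px, all four classes pooled.
2. *One-root-type systems* at video-box resolution (class-1 diameters at or
   below ~3 px), types II-IV.
3. *A 12-week growth series* (weeks 2-13) of stratified 17-root subsets of
   an 80-root system at video-box resolution, classes 2-4.

Each returns a long table of (scene, class, true_mm, pred_mm) pairs plus the
pooled regression report.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import DiameterClassScheme
from .imaging import CameraCalibration
from .pipeline import analyze_frame
from .synthetic import (
    TYPE_ORDER,
    generate_root_system,
    generate_single_root,
    generate_time_series,
)
from .validation import RegressionReport, regression_stats

#: resolution (mm/px) at which type-I roots span >= 3 px
HIGH_RES_MM_PER_PX = 0.3
#: video-box-like resolution: class-1 diameters are <= ~3.3 px
VIDEO_RES_MM_PER_PX = 0.6


def _predict(image, mm_per_px, max_diameter_mm, scheme):
    cal = CameraCalibration(mm_per_px=mm_per_px)
    res = analyze_frame(image, cal, max_diameter_mm=max_diameter_mm, scheme=scheme)
    return res.distribution.length_mm


def _max_diameter_for(types) -> float:
    # plan the iteration ladder for the largest class present in the study
    return 45.0 if "IV" in types else (20.0 if "III" in types else 6.0)


def run_single_root_study(
    seed: int,
    n_per_type: int = 50,
    types: tuple[str, ...] = TYPE_ORDER,
    mm_per_px: float = HIGH_RES_MM_PER_PX,
    scheme: DiameterClassScheme = DiameterClassScheme(),
) -> tuple[pd.DataFrame, RegressionReport]:
    """Per-class lengths of ``n_per_type`` single roots per type, pooled."""
    ss = np.random.SeedSequence([seed, 101])
    scene_seeds = ss.generate_state(len(types) * n_per_type)
    rows = []
    k = 0
    for rtype in types:
        for i in range(n_per_type):
            img, truth, _ = generate_single_root(
                rtype, mm_per_px, int(scene_seeds[k] % 2**31)
            )
            k += 1
            pred = _predict(img, mm_per_px, _max_diameter_for(types), scheme)
            true = truth.class_lengths(scheme)
            for c in range(scheme.n_classes):
                rows.append(
                    {
                        "scene": f"{rtype}-{i}",
                        "root_type": rtype,
                        "diameter_class": c + 1,
                        "true_mm": true[c],
                        "pred_mm": pred[c],
                    }
                )
    df = pd.DataFrame(rows)
    report = regression_stats(df["pred_mm"], df["true_mm"])
    return df, report


#: one-type system sizes: transition roots are numerous, storage roots are
#: few (cassava carries 3-10 storage roots per plant)
SYSTEM_SIZES = {"II": 16, "III": 10, "IV": 6}


def run_one_type_system_study(
    seed: int,
    types: tuple[str, ...] = ("II", "III", "IV"),
    n_systems: int = 5,
    n_roots: dict[str, int] | None = None,
    mm_per_px: float = VIDEO_RES_MM_PER_PX,
    scheme: DiameterClassScheme = DiameterClassScheme(),
) -> tuple[pd.DataFrame, RegressionReport]:
    """One-root-type systems with a shared basal anchor, types II-IV."""
    if n_roots is None:
        n_roots = SYSTEM_SIZES
    ss = np.random.SeedSequence([seed, 202])
    scene_seeds = ss.generate_state(len(types) * n_systems)
    rows = []
    k = 0
    for rtype in types:
        for i in range(n_systems):
            img, truth, _ = generate_root_system(
                n_roots[rtype], rtype, mm_per_px, int(scene_seeds[k] % 2**31)
            )
            k += 1
            pred = _predict(img, mm_per_px, _max_diameter_for(types), scheme)
            true = truth.class_lengths(scheme)
            for c in range(scheme.n_classes):
                rows.append(
                    {
                        "scene": f"{rtype}-sys{i}",
                        "root_type": rtype,
                        "diameter_class": c + 1,
                        "true_mm": true[c],
                        "pred_mm": pred[c],
                    }
                )
    df = pd.DataFrame(rows)
    report = regression_stats(df["pred_mm"], df["true_mm"])
    return df, report


def run_time_series_study(
    seed: int,
    n_subsets: int = 5,
    subset_size: int = 17,
    n_roots: int = 80,
    weeks: tuple[float, ...] = tuple(range(2, 14)),
    classes: tuple[int, ...] = (2, 3, 4),
    mm_per_px: float = VIDEO_RES_MM_PER_PX,
    scheme: DiameterClassScheme = DiameterClassScheme(),
) -> tuple[pd.DataFrame, RegressionReport]:
    """Weekly stratified-subset scenes; regression restricted to ``classes``."""
    rows = []
    for scene in generate_time_series(
        seed,
        mm_per_px=mm_per_px,
        weeks=weeks,
        n_roots=n_roots,
        n_subsets=n_subsets,
        subset_size=subset_size,
    ):
        pred = _predict(scene.image, mm_per_px, 45.0, scheme)
        true = scene.truth.class_lengths(scheme)
        for c in range(scheme.n_classes):
            rows.append(
                {
                    "scene": f"w{scene.week:g}-s{scene.subset}",
                    "week": scene.week,
                    "diameter_class": c + 1,
                    "true_mm": true[c],
                    "pred_mm": pred[c],
                }
            )
    df = pd.DataFrame(rows)
    sel = df[df["diameter_class"].isin(classes)]
    report = regression_stats(sel["pred_mm"], sel["true_mm"])
    return df, report


def diagonal_undermeasurement_pct() -> float:
    """Percentage by which raw pixel counting under-measures a 45° segment.

    A step between 8-adjacent diagonal pixels covers √2 pixel spacings of
    metric length, so counting pixels underestimates by 100·(1 − 1/√2) ≈ 29%.
    """
    return 100.0 * (1.0 - 1.0 / np.sqrt(2.0))
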