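"""Diameter-class statistics: binning, multi-view aggregation, growth dynamics.

The core output statistic is the *constituent length* per diameter class:
the total metric centerline length whose local diameter falls into each
class.  The cassava scheme is class 1: <2 mm (fibrous), class 2: 2-6 mm
(transition), class 3: 6-20 mm (early storage), class 4: >20 mm (storage);
a root's type is defined by the highest class it contains.  Class intervals
are half-open [lo, hi), so a diameter of exactly 2.0 mm belongs to class 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imaging import CameraCalibration
from .iterate import WidthMap


@dataclass(frozen=True)
class DiameterClassScheme:
    """Ordered class boundaries in mm; n_classes = len(boundaries) + 1."""

    boundaries_mm: tuple[float, ...] = (2.0, 6.0, 20.0)

    def __post_init__(self) -> None:
        b = self.boundaries_mm
        if any(x <= 0 for x in b) or any(y <= x for x, y in zip(b, b[1:])):
            raise ValueError("boundaries must be positive and strictly increasing")

    @property
    def n_classes(self) -> int:
        return len(self.boundaries_mm) + 1

    def classify(self, diameters_mm: np.ndarray) -> np.ndarray:
        """0-based class index per diameter; intervals are [lo, hi)."""
        return np.searchsorted(self.boundaries_mm, diameters_mm, side="right")


@dataclass
class DiameterDistribution:
    """Constituent length per diameter class, absolute (mm) and percent."""

    length_mm: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def total_length_mm(self) -> float:
        return float(self.length_mm.sum())

    @property
    def fraction_pct(self) -> np.ndarray:
        tot = self.total_length_mm
        if tot <= 0:
            return np.full(self.length_mm.size, np.nan)
        return 100.0 * self.length_mm / tot

    @property
    def empty(self) -> bool:
        return self.total_length_mm <= 0


@dataclass
class FineHistogram:
    """Probability of root diameter at 1-mm resolution (length-weighted)."""

    edges_mm: np.ndarray
    prob: np.ndarray


def classify_widths(
    widthmap: WidthMap,
    cal: CameraCalibration,
    scheme: DiameterClassScheme = DiameterClassScheme(),
) -> tuple[DiameterDistribution, FineHistogram]:
    """Bin per-pixel widths into class constituent lengths.

    Each centerline pixel contributes its orientation-corrected metric
    length (``length_weight * mm_per_px``) to the class containing its
    diameter.  An empty width map yields an all-zero distribution with
    undefined (NaN) fractions.
    """
    n = scheme.n_classes
    if len(widthmap) == 0:
        dist = DiameterDistribution(length_mm=np.zeros(n))
        hist = FineHistogram(edges_mm=np.arange(2.0), prob=np.zeros(1))
        return dist, hist

    diam = widthmap.width_mm(cal.mm_per_px)
    seg_len = widthmap.length_mm(cal.mm_per_px)

    cls = scheme.classify(diam)
    length_mm = np.bincount(cls, weights=seg_len, minlength=n)
    dist = DiameterDistribution(length_mm=length_mm)

    top = max(float(np.ceil(diam.max() + 1e-9)), 1.0)
    edges = np.arange(0.0, top + 1.0)
    counts, _ = np.histogram(diam, bins=edges, weights=seg_len)
    total = counts.sum()
    prob = counts / total if total > 0 else counts
    hist = FineHistogram(edges_mm=edges, prob=prob)
    return dist, hist


def rebin_fine_histogram(
    hist: FineHistogram, scheme: DiameterClassScheme = DiameterClassScheme()
) -> np.ndarray:
    """Merge the 1-mm histogram into class fractions (percent)."""
    centers = 0.5 * (hist.edges_mm[:-1] + hist.edges_mm[1:])
    cls = scheme.classify(centers)
    return 100.0 * np.bincount(cls, weights=hist.prob, minlength=scheme.n_classes)


def aggregate_frames(
    distributions: list[DiameterDistribution],
    mode: str = "mean",
    percentile: float = 95.0,
) -> DiameterDistribution:
    """Aggregate per-frame distributions over the perspectives of a rotation.

    ``mean`` averages the per-class *percentage fractions* over frames
    (frames with no detected roots are excluded and counted); ``max`` and
    ``percentile`` take the per-class maximum / p-th percentile of the
    absolute lengths, favouring the perspectives that display each class
    most fully.
    """
    if not distributions:
        raise ValueError("aggregate_frames requires at least one distribution")
    n = distributions[0].length_mm.size
    if any(d.length_mm.size != n for d in distributions):
        raise ValueError("distributions use different class schemes")

    if mode == "mean":
        nonempty = [d for d in distributions if not d.empty]
        n_excluded = len(distributions) - len(nonempty)
        if not nonempty:
            out = DiameterDistribution(length_mm=np.zeros(n))
            out.provenance["n_excluded_empty"] = n_excluded
            return out
        fr = np.mean([d.fraction_pct for d in nonempty], axis=0)
        mean_total = np.mean([d.total_length_mm for d in nonempty])
        out = DiameterDistribution(length_mm=fr / 100.0 * mean_total)
        out.provenance.update(
            n_frames=len(nonempty), n_excluded_empty=n_excluded, mode="mean"
        )
        return out

    lengths = np.array([d.length_mm for d in distributions])
    if mode == "max":
        agg = lengths.max(axis=0)
    elif mode == "percentile":
        agg = np.percentile(lengths, percentile, axis=0)
    else:
        raise ValueError(f"unknown aggregation mode: {mode}")
    out = DiameterDistribution(length_mm=agg)
    out.provenance.update(n_frames=len(distributions), mode=mode)
    return out


def growth_dynamics(
    per_plant: dict[int, list[DiameterDistribution]],
) -> pd.DataFrame:
    """Box-plot statistics of class fractions per week.

    ``per_plant`` maps week -> list of per-plant (or per-frame) diameter
    distributions.  Returns a long table with one row per (week, class):
    median, quartiles (linear interpolation), Tukey 1.5*IQR whiskers and the
    number of outliers beyond them.
    """
    rows = []
    for week in sorted(per_plant):
        dists = [d for d in per_plant[week] if not d.empty]
        if not dists:
            continue
        fr = np.array([d.fraction_pct for d in dists])
        n_classes = fr.shape[1]
        for c in range(n_classes):
            vals = fr[:, c]
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            iqr = q3 - q1
            lo_fence = q1 - 1.5 * iqr
            hi_fence = q3 + 1.5 * iqr
            inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
            rows.append(
                {
                    "week": week,
                    "diameter_class": c + 1,
                    "n": vals.size,
                    "median_pct": med,
                    "q1_pct": q1,
                    "q3_pct": q3,
                    "whisker_low_pct": inside.min() if inside.size else np.nan,
                    "whisker_high_pct": inside.max() if inside.size else np.nan,
                    "n_outliers": int(((vals < lo_fence) | (vals > hi_fence)).sum()),
                }
            )
    return pd.DataFrame(rows)


#: centerline overlay colors by class: purple (fibrous), green (transition),
#: blue (early storage), red (storage)
CLASS_COLORS_RGB = ((160, 32, 240), (0, 200, 0), (0, 80, 255), (255, 0, 0))


def overlay_classes(
    image: np.ndarray,
    widthmap: WidthMap,
    cal: CameraCalibration,
    scheme: DiameterClassScheme = DiameterClassScheme(),
) -> np.ndarray:
    """RGB copy of the frame with centerline pixels colored by class."""
    out = np.asarray(image).copy()
    if out.ndim == 2:
        out = np.stack([out] * 3, axis=-1)
    if len(widthmap) == 0:
        return out
    cls = scheme.classify(widthmap.width_mm(cal.mm_per_px))
    colors = np.asarray(CLASS_COLORS_RGB, dtype=out.dtype)
    out[widthmap.rows, widthmap.cols] = colors[np.clip(cls, 0, len(colors) - 1)]
    return out


def plant_summary(
    distribution: DiameterDistribution,
    plant_id: str,
    week: int | float | None = None,
    n_frames: int | None = None,
) -> dict:
    """JSON-ready per-plant summary of a (possibly aggregated) distribution."""
    return {
        "plant_id": plant_id,
        "week": week,
        "length_mm": [round(float(v), 3) for v in distribution.length_mm],
        "fraction_pct": [
            None if np.isnan(v) else round(float(v), 3)
            for v in distribution.fraction_pct
        ],
        "total_length_mm": round(distribution.total_length_mm, 3),
        "n_frames": n_frames,
    }


def widthmap_to_frame(
    widthmap: WidthMap,
    cal: CameraCalibration,
    scheme: DiameterClassScheme = DiameterClassScheme(),
    frame_index: int | None = None,
) -> pd.DataFrame:
    """Long-format per-pixel table (row, col, width, length weight, class)."""
    diam = widthmap.width_mm(cal.mm_per_px)
    df = pd.DataFrame(
        {
            "row": widthmap.rows,
            "col": widthmap.cols,
            "width_px": widthmap.width_px,
            "width_mm": diam,
            "length_weight": widthmap.length_weight,
            "diameter_class": scheme.classify(diam) + 1,
        }
    )
    if frame_index is not None:
        df.insert(0, "frame", frame_index)
    return df
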