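"""End-to-end analysis: frame -> masks -> widths -> diameter distribution."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import (
    DiameterClassScheme,
    DiameterDistribution,
    FineHistogram,
    classify_widths,
)
from .imaging import CameraCalibration, Frame, to_gray
from .iterate import (
    IterationPlan,
    WidthMap,
    corrected_lengths,
    forward_plan,
    orientation_correction,
    postprocess_centerlines,
    run_iterations,
    transfer_widths,
)
from .segmentation import MaskSet, SegmentationParams, segment_root_system


@dataclass
class FrameResult:
    """Everything the pipeline derives from one frame."""

    distribution: DiameterDistribution
    fine_histogram: FineHistogram
    widthmap: WidthMap
    skeleton: np.ndarray
    masks: MaskSet


def analyze_frame(
    frame: Frame | np.ndarray,
    cal: CameraCalibration,
    plan: IterationPlan | None = None,
    seg_params: SegmentationParams | None = None,
    scheme: DiameterClassScheme = DiameterClassScheme(),
    max_diameter_mm: float = 45.0,
    h: float = 50.0,
) -> FrameResult:
    """Run segmentation, iterative ridge analysis and classification.

    When no iteration plan is given, a forward plan is built for diameters up
    to ``max_diameter_mm`` at the frame's resolution.  ``seg_params`` default
    to the still-image settings (no blur mask, 16-px fragment filter).
    """
    if not isinstance(frame, Frame):
        frame = Frame(pixels=frame)
    if seg_params is None:
        seg_params = SegmentationParams(use_blur_mask=False, T_F=16)
    if plan is None:
        plan = forward_plan(max_diameter_px=max_diameter_mm / cal.mm_per_px, h=h)

    masks = segment_root_system(frame, seg_params)
    gray = to_gray(frame) * masks.RS

    raw_map, centerline, _ = run_iterations(gray, masks.RS, plan)
    skeleton = postprocess_centerlines(centerline, masks.RS)
    widthmap = transfer_widths(skeleton, raw_map)
    segments = orientation_correction(skeleton)
    widthmap = corrected_lengths(widthmap, segments)

    distribution, fine = classify_widths(widthmap, cal, scheme)
    return FrameResult(
        distribution=distribution,
        fine_histogram=fine,
        widthmap=widthmap,
        skeleton=skeleton,
        masks=masks,
    )
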