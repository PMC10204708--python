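"""Validation metrics and the perspective-shortening model.

Pipeline predictions are judged against analytic ground truth with per-class
signed errors, a predicted-vs-true regression (R² about the truth and RMSE
normalized by the standard deviation of the truth), and binary-mask overlap
metrics.  A pinhole/orthographic model quantifies how much the projected
length of a root section shrinks with its inclination to the image plane,
including the averaging effect of the full rotation in the video box.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import DiameterDistribution
from .imaging import CameraCalibration
from .synthetic import GroundTruth


@dataclass
class RegressionReport:
    """Fit quality of predicted vs. true values."""

    r2: float
    nrmse: float
    n: int
    slope: float
    intercept: float


@dataclass
class MaskComparison:
    iou: float
    area_true: int
    area_pred: int
    area_error_pct: float
    both_empty: bool = False


@dataclass
class ClassErrors:
    """Per-class signed prediction errors (mm and % of truth)."""

    error_mm: np.ndarray
    error_pct: np.ndarray       # NaN where truth is 0
    phantom: np.ndarray         # truth 0 but prediction > 0


def compare_class_lengths(
    pred: DiameterDistribution, truth: GroundTruth | np.ndarray
) -> ClassErrors:
    """Signed per-class errors; classes predicted without truth are flagged."""
    t = truth.class_lengths() if isinstance(truth, GroundTruth) else np.asarray(truth)
    p = pred.length_mm
    if p.size != t.size:
        raise ValueError("prediction and truth use different class schemes")
    err = p - t
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(t > 0, 100.0 * err / t, np.nan)
    phantom = (t <= 0) & (p > 0)
    return ClassErrors(error_mm=err, error_pct=pct, phantom=phantom)


def regression_stats(pred, truth) -> RegressionReport:
    """R² = 1 − SSE/SST about the truth; nRMSE = RMSE / population std(truth)."""
    p = np.asarray(pred, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape or p.ndim != 1 or p.size < 2:
        raise ValueError("pred and truth must be equal-length 1D with n >= 2")
    std = t.std()  # population (n) denominator
    if std <= 0:
        raise ValueError("truth has zero variance")
    sse = float(np.sum((p - t) ** 2))
    sst = float(np.sum((t - t.mean()) ** 2))
    rmse = float(np.sqrt(sse / t.size))
    slope, intercept = np.polyfit(t, p, 1)
    return RegressionReport(
        r2=1.0 - sse / sst,
        nrmse=rmse / std,
        n=t.size,
        slope=float(slope),
        intercept=float(intercept),
    )


def mask_metrics(true_mask: np.ndarray, pred_mask: np.ndarray) -> MaskComparison:
    """IoU and relative area error of two binary masks."""
    a = np.asarray(true_mask, dtype=bool)
    b = np.asarray(pred_mask, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a shape")
    area_true = int(a.sum())
    area_pred = int(b.sum())
    union = int((a | b).sum())
    if union == 0:
        return MaskComparison(
            iou=1.0, area_true=0, area_pred=0, area_error_pct=0.0, both_empty=True
        )
    iou = int((a & b).sum()) / union
    err = (
        100.0 * abs(area_pred - area_true) / area_true if area_true > 0 else np.inf
    )
    return MaskComparison(
        iou=iou, area_true=area_true, area_pred=area_pred, area_error_pct=err
    )


@dataclass
class PerspectiveModel:
    """Projection geometry of the rotating-root setup.

    The rotation axis is vertical and parallel to the image plane.  A root
    section of unit length at inclination α (0° horizontal, 90° parallel to
    the axis) sweeps around the axis; its projected length depends on the
    rotation angle θ.  Without ``focal_length_px`` the orthographic limit is
    used; with it, a pinhole camera at ``axis_distance_mm`` foreshortens
    additionally with depth.
    """

    camera: CameraCalibration = CameraCalibration(mm_per_px=0.5)
    rotation_averaging: bool = True
    n_theta: int = 720
    segment_length_mm: float = 100.0

    def projected_ratio(self, inclination_rad: float, theta: np.ndarray) -> np.ndarray:
        a = inclination_rad
        # unit direction: horizontal component rotates, vertical is preserved
        dx = np.cos(a) * np.cos(theta)
        dy = np.sin(a) * np.ones_like(theta)
        dz = np.cos(a) * np.sin(theta)  # depth toward the camera
        if self.camera.focal_length_px is None:
            return np.hypot(dx, dy)
        f = self.camera.focal_length_px
        L = self.segment_length_mm
        d0 = self.camera.axis_distance_mm
        # segment centered on the axis; project both endpoints
        x1, y1, z1 = -0.5 * L * dx, -0.5 * L * dy, d0 - 0.5 * L * dz
        x2, y2, z2 = 0.5 * L * dx, 0.5 * L * dy, d0 + 0.5 * L * dz
        u1, v1 = f * x1 / z1, f * y1 / z1
        u2, v2 = f * x2 / z2, f * y2 / z2
        proj = np.hypot(u2 - u1, v2 - v1)
        return proj / (f * L / d0)


def perspective_shortening(
    inclination_deg: float, model: PerspectiveModel | None = None
) -> float:
    """Percentage length shortening of a root section at the given inclination.

    Returns 100·(1 − projected/true), averaged over a full rotation when the
    model's ``rotation_averaging`` is on, else the worst case over rotation.
    """
    if model is None:
        model = PerspectiveModel()
    if not 0.0 <= inclination_deg <= 90.0:
        raise ValueError("inclination must lie in [0, 90] degrees")
    a = np.deg2rad(inclination_deg)
    theta = np.linspace(0.0, 2.0 * np.pi, model.n_theta, endpoint=False)
    ratios = model.projected_ratio(a, theta)
    ratio = float(ratios.mean()) if model.rotation_averaging else float(ratios.min())
    return 100.0 * (1.0 - ratio)
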