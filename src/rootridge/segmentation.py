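"""Root-system segmentation against the blue imaging-box background.

The root-system mask ``RS`` is the logical AND of four binary masks —
foreground ``F`` (low normalized blueness), stem ``S`` (stem pixels zeroed,
supplied externally), label ``L`` (user-provided rectangles such as QR labels
zeroed) and blur ``C`` (motion-blurred roots lack sharp Canny edges and are
zeroed) — followed by optional morphological erosion and small-fragment
removal:

    M = F ∧ S ∧ L ∧ C,   RS = remove_small(erode(M, θ), T_F)

Blueness is the color index β = 3B − 2.4G − R, normalized per frame to
β′ = 255·β/max(β); background pixels have high β′, roots low.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import feature, morphology

from .imaging import Frame


@dataclass(frozen=True)
class LabelRegion:
    """Axis-aligned exclusion rectangle (x, y, w, h), 0-based, origin top-left."""

    x: int
    y: int
    w: int
    h: int


@dataclass
class SegmentationParams:
    """User-set thresholds of the mask-fusion stage.

    Canny thresholds and the blur-mask dilation radius are calibration
    details of the acquisition setup; the defaults retain a sharp synthetic
    bar entirely.  ``use_blur_mask=False`` bypasses ``C`` for still images,
    where there is no rotation motion to blur anything.
    """

    T_beta: float = 128.0
    canny_low: float = 50.0
    canny_high: float = 150.0
    blur_dilation_px: int = 5
    theta_px: int = 0
    T_F: int = 0
    use_blur_mask: bool = True
    stem_source: str | Path | None = None
    label_regions: list[LabelRegion] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 <= self.T_beta <= 255:
            raise ValueError("T_beta must lie in [0, 255]")
        if not self.canny_low < self.canny_high:
            raise ValueError("canny_low must be < canny_high")
        if min(self.theta_px, self.T_F, self.blur_dilation_px) < 0:
            raise ValueError("theta_px, T_F and blur_dilation_px must be >= 0")


@dataclass
class BluenessMap:
    """Signed blueness β and its per-frame normalization β′ in [0, 255]."""

    beta: np.ndarray
    beta_norm: np.ndarray
    degenerate: bool = False


@dataclass
class MaskSet:
    """All masks of the fusion stage; 1 = keep (root candidate), 0 = remove."""

    F: np.ndarray
    S: np.ndarray
    L: np.ndarray
    C: np.ndarray
    M: np.ndarray
    RS: np.ndarray


def compute_blueness(frame: Frame | np.ndarray) -> BluenessMap:
    """β = 3B − 2.4G − R per pixel, normalized to β′ = 255·β/max(β).

    If max(β) ≤ 0 there is no blue background to key on; β′ is defined as 0
    everywhere (fail-open: the whole frame becomes foreground for any
    T_beta > 0) and a warning is emitted.
    """
    px = frame.pixels if isinstance(frame, Frame) else np.asarray(frame)
    r = px[:, :, 0].astype(np.float64)
    g = px[:, :, 1].astype(np.float64)
    b = px[:, :, 2].astype(np.float64)
    beta = 3.0 * b - 2.4 * g - r
    bmax = beta.max()
    if bmax > 0:
        beta_norm = 255.0 * beta / bmax
        degenerate = False
    else:
        warnings.warn(
            "max blueness <= 0 (no blue background); treating whole frame "
            "as foreground",
            stacklevel=2,
        )
        beta_norm = np.zeros_like(beta)
        degenerate = True
    return BluenessMap(beta=beta, beta_norm=beta_norm, degenerate=degenerate)


def segment_foreground(bl: BluenessMap, T_beta: float) -> np.ndarray:
    """Foreground mask F: pixels whose normalized blueness is below T_beta."""
    return bl.beta_norm < T_beta


def compute_blur_mask(
    gray: np.ndarray,
    canny_low: float = 50.0,
    canny_high: float = 150.0,
    blur_dilation_px: int = 5,
) -> np.ndarray:
    """Blur mask C: 1 within ``blur_dilation_px`` of a Canny edge.

    Motion-blurred roots have no discernible edges, so they (and the flat
    background) stay 0 and are removed by the mask fusion.
    """
    g = np.asarray(gray, dtype=np.float64)
    edges = feature.canny(
        g, sigma=1.0, low_threshold=canny_low, high_threshold=canny_high
    )
    if blur_dilation_px > 0:
        edges = morphology.dilation(edges, morphology.disk(blur_dilation_px))
    return edges


def build_label_mask(
    shape: tuple[int, int], label_regions: list[LabelRegion]
) -> np.ndarray:
    """Label mask L: 1 everywhere except inside the listed rectangles."""
    L = np.ones(shape, dtype=bool)
    h, w = shape
    for reg in label_regions:
        x0 = max(0, reg.x)
        y0 = max(0, reg.y)
        x1 = min(w, reg.x + reg.w)
        y1 = min(h, reg.y + reg.h)
        if x1 > x0 and y1 > y0:
            L[y0:y1, x0:x1] = False
    return L


def get_stem_mask(
    frame_shape: tuple[int, int],
    stem_source: str | Path | np.ndarray | None = None,
) -> np.ndarray:
    """Stem mask S: stem pixels 0, everything else 1.

    ``stem_source`` may be ``None`` (no stem; all ones), a binary array with
    stem pixels nonzero, or a path to a single-channel image with stem pixels
    nonzero.  The input convention (1 = stem) is inverted here.
    """
    if stem_source is None:
        return np.ones(frame_shape, dtype=bool)
    if isinstance(stem_source, (str, Path)):
        import imageio.v3 as iio

        stem = np.asarray(iio.imread(stem_source))
        if stem.ndim == 3:
            stem = stem[:, :, 0]
    else:
        stem = np.asarray(stem_source)
    if stem.shape != tuple(frame_shape):
        raise ValueError(
            f"stem mask shape {stem.shape} does not match frame {frame_shape}"
        )
    stem = stem.astype(bool)
    if not stem.any():
        warnings.warn("stem mask is empty; using all-ones S", stacklevel=2)
    return ~stem


def combine_masks(
    F: np.ndarray, S: np.ndarray, L: np.ndarray, C: np.ndarray
) -> np.ndarray:
    """M = F ∧ S ∧ L ∧ C (pointwise logical AND)."""
    for name, m in (("S", S), ("L", L), ("C", C)):
        if m.shape != F.shape:
            raise ValueError(f"mask {name} shape {m.shape} != F shape {F.shape}")
    return F.astype(bool) & S.astype(bool) & L.astype(bool) & C.astype(bool)


def refine_root_mask(M: np.ndarray, theta_px: int = 0, T_F: int = 0) -> np.ndarray:
    """RS: erode M with a disk of radius θ, then drop 8-connected fragments < T_F px."""
    RS = M.astype(bool)
    if theta_px > 0:
        RS = morphology.erosion(RS, morphology.disk(theta_px))
    if T_F > 0:
        # fragments with area < T_F are removed (max_size is inclusive)
        RS = morphology.remove_small_objects(RS, max_size=T_F - 1, connectivity=2)
    return RS


def segment_root_system(
    frame: Frame,
    params: SegmentationParams,
    gray: np.ndarray | None = None,
) -> MaskSet:
    """Run the full mask-fusion stage on one frame and return every mask."""
    from .imaging import to_gray

    bl = compute_blueness(frame)
    F = segment_foreground(bl, params.T_beta)
    S = get_stem_mask(frame.shape, params.stem_source)
    L = build_label_mask(frame.shape, params.label_regions)
    if params.use_blur_mask:
        if gray is None:
            gray = to_gray(frame)
        C = compute_blur_mask(
            gray, params.canny_low, params.canny_high, params.blur_dilation_px
        )
    else:
        C = np.ones(frame.shape, dtype=bool)
    M = combine_masks(F, S, L, C)
    RS = refine_root_mask(M, params.theta_px, params.T_F)
    return MaskSet(F=F, S=S, L=L, C=C, M=M, RS=RS)


def save_masks(masks: MaskSet, directory: str | Path, prefix: str = "") -> None:
    """Write every stage mask as an 8-bit PNG for debugging."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in ("F", "S", "L", "C", "M", "RS"):
        mask = getattr(masks, name)
        iio.imwrite(
            directory / f"{prefix}{name}.png",
            (mask.astype(np.uint8) * 255),
        )
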