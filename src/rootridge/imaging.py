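"""Image/video loading, acquisition metadata and pixel-to-metric conversion.

Root systems are imaged either as single stills or as a full rotation in a
video box: the root hangs from a turntable and frames are captured roughly
every 2 degrees, so a full rotation yields about 180 frames.  All downstream
measurements are made in pixels and converted to millimetres with the metric
scale at the rotation-axis plane (``mm_per_px``).
"""

from __future__ import annotations

import logging
import tomllib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

#: Rec.601 luma weights used for the grayscale conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

_IMAGE_SUFFIXES = {".tif", ".tiff", ".png", ".jpg", ".jpeg"}
_VIDEO_SUFFIXES = {".mov", ".mp4", ".avi"}


@dataclass
class Frame:
    """A single RGB frame with its capture metadata.

    ``pixels`` is an ``H x W x 3`` uint8 array; ``angle_deg`` is the turntable
    rotation angle at capture time (``None`` for stills).
    """

    pixels: np.ndarray
    index: int = 0
    angle_deg: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"Frame expects an HxWx3 array, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("Frame must have positive height and width")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("Frame intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px
        if self.index < 0:
            raise ValueError("Frame.index must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class CameraCalibration:
    """Metric calibration of the acquisition geometry.

    ``mm_per_px`` is the scale at the rotation-axis plane; ``axis_distance_mm``
    is the camera-to-axis distance (default 1135 mm, the video-box geometry).
    ``focal_length_px`` is only needed by the pinhole perspective model.
    """

    mm_per_px: float
    axis_distance_mm: float = 1135.0
    focal_length_px: float | None = None

    def __post_init__(self) -> None:
        if not self.mm_per_px > 0:
            raise ValueError("mm_per_px must be > 0")
        if not self.axis_distance_mm > 0:
            raise ValueError("axis_distance_mm must be > 0")


@dataclass(frozen=True)
class SequenceSpec:
    """Where a frame sequence lives and how it was acquired."""

    source: str | Path
    angular_step_deg: float = 2.0
    n_frames: int | None = None
    full_rotation: bool = True

    def __post_init__(self) -> None:
        if not self.angular_step_deg > 0:
            raise ValueError("angular_step_deg must be > 0")


def px_to_mm(width_px: float | np.ndarray, cal: CameraCalibration) -> float | np.ndarray:
    """Convert a pixel measure to millimetres at the rotation-axis plane."""
    arr = np.asarray(width_px, dtype=float)
    if np.any(arr < 0):
        raise ValueError("pixel widths must be non-negative")
    out = arr * cal.mm_per_px
    return float(out) if np.isscalar(width_px) or out.ndim == 0 else out


def to_gray(frame: Frame | np.ndarray) -> np.ndarray:
    """Rec.601 luminance of an RGB frame as float64 in [0, 255]."""
    px = frame.pixels if isinstance(frame, Frame) else np.asarray(frame)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError("to_gray expects an HxWx3 array")
    w = np.asarray(LUMA_WEIGHTS)
    return px.astype(np.float64) @ w


def load_sequence(spec: SequenceSpec) -> list[Frame]:
    """Load a video or an image directory as an ordered list of frames.

    Image directories are read in lexicographic filename order.  When
    ``full_rotation`` is set, each frame is assigned
    ``angle_deg = index * angular_step_deg``.
    """
    source = Path(spec.source)
    if not source.exists():
        raise FileNotFoundError(f"sequence source does not exist: {source}")

    if source.is_dir():
        paths = sorted(
            p for p in source.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
        )
        raw = []
        for i, p in enumerate(paths):
            try:
                raw.append(_read_image(p))
            except Exception as exc:  # pragma: no cover - corrupt-file path
                raise OSError(f"could not read frame {i} ({p.name}): {exc}") from exc
    elif source.suffix.lower() in _VIDEO_SUFFIXES:
        raw = _read_video(source)
    else:
        raw = [_read_image(source)]

    if not raw:
        raise ValueError(f"no frames found in {source}")

    if spec.n_frames is not None and len(raw) != spec.n_frames:
        warnings.warn(
            f"{source}: expected {spec.n_frames} frames, got {len(raw)}",
            stacklevel=2,
        )

    frames = []
    for i, px in enumerate(raw):
        angle = i * spec.angular_step_deg if spec.full_rotation else None
        frames.append(Frame(pixels=px, index=i, angle_deg=angle))
    return frames


def _read_image(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    px = iio.imread(path)
    return _as_rgb(px)


def _read_video(path: Path) -> list[np.ndarray]:
    import imageio.v3 as iio

    try:
        return [_as_rgb(f) for f in iio.imiter(path)]
    except Exception as exc:
        raise OSError(f"could not decode video {path}: {exc}") from exc


def _as_rgb(px: np.ndarray) -> np.ndarray:
    if px.ndim == 2:
        px = np.stack([px] * 3, axis=-1)
    if px.shape[2] == 4:  # drop alpha
        px = px[:, :, :3]
    return np.ascontiguousarray(px[:, :, :3]).astype(np.uint8)


@dataclass
class AcquisitionConfig:
    """Flat configuration loaded from a TOML file.

    The fixture default of 0.5 mm/px is arbitrary; real runs must supply the
    calibrated scale of their own setup.
    """

    camera: CameraCalibration = field(
        default_factory=lambda: CameraCalibration(mm_per_px=0.5)
    )
    angular_step_deg: float = 2.0


def load_config(path: str | Path) -> AcquisitionConfig:
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    cam = data.get("camera", {})
    seq = data.get("sequence", {})
    cal = CameraCalibration(
        mm_per_px=float(cam.get("mm_per_px", 0.5)),
        axis_distance_mm=float(cam.get("axis_distance_mm", 1135.0)),
        focal_length_px=cam.get("focal_length_px"),
    )
    return AcquisitionConfig(
        camera=cal, angular_step_deg=float(seq.get("angular_step_deg", 2.0))
    )
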