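"""Synthetic 2D root-system images with exact analytic ground truth.

The validation strategy of the pipeline rests on rendered root systems whose
per-diameter-class constituent lengths are known exactly.  A root is a
disc-swept volume around a gently curved planar axis with a piecewise-linear
radius profile (narrow neck, swollen mid-region, thin tip for storage
types); the ground truth is integrated analytically from that profile —
never measured from pixels — so the truth table is exact regardless of
rendering resolution.

Three dataset families mirror the validation ladder:

* single roots of the four cassava types (I fibrous <2 mm, II transition
  2-6 mm, III early-storage 6-20 mm, IV storage >20 mm, capped at 45 mm),
* one-root-type systems sharing a basal anchor (self-occlusion allowed),
* a weekly growth series (weeks 2-13) of an 80-root system with secondary
  thickening, sampled each week as stratified 17-root subsets whose type
  proportions match the full system.

Scenes are front-lit (radial shading for a round impression) on a saturated
blue background, so the segmentation stage sees the same color contrast as
the real imaging box.  Truth lengths are kept in fine diameter bins
0-1, 1-2, ..., 9-10, 10-15, 15-20, 20-25, 25-30, 30+ mm and merged into the
four classes exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .classify import DiameterClassScheme

#: fine diameter-bin edges in mm (last bin open)
FINE_BIN_EDGES = np.array(
    [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 15, 20, 25, 30, np.inf]
)
N_FINE_BINS = len(FINE_BIN_EDGES) - 1

TYPE_ORDER = ("I", "II", "III", "IV")

#: per-type max-diameter ranges (mm); IV capped at 45 mm
TYPE_DIAMETER_RANGES = {
    "I": (1.2, 1.9),
    "II": (2.5, 6.0),
    "III": (7.0, 20.0),
    "IV": (22.0, 45.0),
}
#: per-type root-length ranges (mm)
TYPE_LENGTH_RANGES = {
    "I": (150.0, 250.0),
    "II": (180.0, 300.0),
    "III": (220.0, 380.0),
    "IV": (250.0, 400.0),
}

BACKGROUND_RGB = (20, 40, 210)   # saturated blue; very high blueness index
ROOT_BASE_RGB = (185.0, 165.0, 140.0)  # pale root surface; negative blueness


@dataclass
class RootSpec:
    """One root: planar axis (mm, y down) plus a piecewise-linear radius profile."""

    root_type: str
    axis_mm: np.ndarray          # (N, 2) columns (x, y) relative to the anchor
    radius_knots_s: np.ndarray   # arc positions of the radius knots (mm)
    radius_knots_r: np.ndarray   # radii at the knots (mm)

    def __post_init__(self) -> None:
        if np.any(self.radius_knots_r < 0):
            raise ValueError("radius profile must be non-negative")
        d = self.max_diameter_mm
        lo, hi = {"I": (0, 2), "II": (0, 6), "III": (0, 20), "IV": (0, 45.0001)}[
            self.root_type
        ]
        if not lo <= d <= max(hi, 45.0001):
            raise ValueError(f"type {self.root_type} diameter {d:.1f} out of range")

    @property
    def length_mm(self) -> float:
        return float(self.radius_knots_s[-1])

    @property
    def max_diameter_mm(self) -> float:
        return float(2.0 * self.radius_knots_r.max())

    def radius_at(self, s: np.ndarray) -> np.ndarray:
        return np.interp(s, self.radius_knots_s, self.radius_knots_r)

    def fine_bin_lengths(self) -> np.ndarray:
        """Exact arc length per fine diameter bin, from the radius knots."""
        out = np.zeros(N_FINE_BINS)
        s = self.radius_knots_s
        d = 2.0 * self.radius_knots_r
        for (s0, s1), (d0, d1) in zip(zip(s, s[1:]), zip(d, d[1:])):
            _accumulate_segment(out, s1 - s0, d0, d1)
        return out


def _accumulate_segment(out: np.ndarray, seg_len: float, d0: float, d1: float) -> None:
    """Distribute the length of a linear-diameter segment over the fine bins."""
    if seg_len <= 0:
        return
    lo, hi = (d0, d1) if d0 <= d1 else (d1, d0)
    if hi - lo < 1e-12:
        out[_fine_bin(lo)] += seg_len
        return
    # fraction of the segment with diameter in [a, b): linear inversion
    for b in range(N_FINE_BINS):
        a = max(lo, FINE_BIN_EDGES[b])
        bb = min(hi, FINE_BIN_EDGES[b + 1])
        if bb > a:
            out[b] += seg_len * (bb - a) / (hi - lo)


def _fine_bin(d: float) -> int:
    return int(np.searchsorted(FINE_BIN_EDGES, d, side="right")) - 1


@dataclass
class GroundTruth:
    """Exact constituent lengths (mm) per root and fine diameter bin."""

    per_root: np.ndarray  # (n_roots, N_FINE_BINS)

    @property
    def scene_fine(self) -> np.ndarray:
        return self.per_root.sum(axis=0)

    def class_lengths(
        self, scheme: DiameterClassScheme = DiameterClassScheme()
    ) -> np.ndarray:
        """Merge fine bins into the class scheme (lossless: bin edges align)."""
        lowers = FINE_BIN_EDGES[:-1]
        cls = scheme.classify(lowers)
        return np.bincount(cls, weights=self.scene_fine, minlength=scheme.n_classes)

    @property
    def total_length_mm(self) -> float:
        return float(self.scene_fine.sum())


# ---------------------------------------------------------------------------
# geometry generation


class Obstacles:
    """Existing roots of a scene, for collision-avoiding axis growth.

    Roots in the thin quasi-2D growth volume grow side by side and deflect
    around one another rather than stacking in depth; a growing axis steers
    away from any already-placed root it would intrude on.
    """

    def __init__(self) -> None:
        self._points: list[np.ndarray] = []
        self._radii: list[np.ndarray] = []
        self._tree: cKDTree | None = None
        self._all_r: np.ndarray | None = None
        self._rmax: float = 0.0

    def add_root(self, axis_mm: np.ndarray, radii_mm: np.ndarray) -> None:
        self._points.append(axis_mm)
        self._radii.append(np.asarray(radii_mm, dtype=float))
        pts = np.vstack(self._points)
        self._all_r = np.concatenate(self._radii)
        self._rmax = float(self._all_r.max())
        self._tree = cKDTree(pts)

    def deflection(
        self, p: np.ndarray, heading: float, r_own: float, clearance: float = 1.0
    ) -> float:
        """Steering correction (rad) pushing the heading away from intrusions."""
        if self._tree is None:
            return 0.0
        reach = r_own + self._rmax + clearance
        idx = self._tree.query_ball_point(p, reach)
        if not idx:
            return 0.0
        pts = self._tree.data[idx]
        rr = self._all_r[idx]
        vec = pts - p[None, :]
        dist = np.maximum(np.hypot(vec[:, 0], vec[:, 1]), 1e-6)
        overlap = (r_own + rr + clearance) - dist
        hit = overlap > 0
        if not hit.any():
            return 0.0
        # net escape direction: overlap-weighted sum of repulsions, so a
        # root squeezed between two neighbors steers along the free channel
        # instead of oscillating between them
        away = -(vec[hit] / dist[hit, None] * overlap[hit, None]).sum(axis=0)
        norm = np.hypot(*away)
        if norm < 1e-9:
            return 0.0
        target = float(np.arctan2(away[0], away[1]))  # (x, y) with y down
        diff = (target - heading + np.pi) % (2.0 * np.pi) - np.pi
        mag = min(0.2, 0.04 + 0.03 * float(overlap.max()))
        return float(np.clip(diff, -mag, mag))


def _random_axis(
    rng: np.random.Generator,
    length_mm: float,
    start_angle_rad: float,
    ds: float = 2.0,
    curl: float = 0.04,
    anchor_mm: tuple[float, float] = (0.0, 0.0),
    obstacles: Obstacles | None = None,
    radius_of_s=None,
) -> np.ndarray:
    """Gently curved, predominantly downward polyline of the given arc length."""
    n = max(int(np.ceil(length_mm / ds)), 2)
    dphi = rng.normal(0.0, curl, size=n)
    # smooth the curvature so the axis bends gently rather than jitters
    kernel = np.ones(7) / 7.0
    dphi = np.convolve(dphi, kernel, mode="same")
    step = length_mm / n
    phi = start_angle_rad
    p = np.asarray(anchor_mm, dtype=float)
    pts = [p.copy()]
    for i in range(n):
        phi = float(np.clip(phi + dphi[i], -1.35, 1.35))
        if obstacles is not None and radius_of_s is not None:
            s_here = (i + 1) * step
            if s_here > 10.0:  # bases may adjoin; steer only past the anchor zone
                phi += obstacles.deflection(p, phi, float(radius_of_s(s_here)))
                phi = float(np.clip(phi, -1.45, 1.45))
        p = p + step * np.array([np.sin(phi), np.cos(phi)])
        pts.append(p.copy())
    return np.asarray(pts)


#: proximal neck radius as a fraction of the maximum radius.  Storage-type
#: roots attach to the stem by a narrow neck and swell along the mid-root;
#: fibrous and transition roots are widest at the base.
NECK_RATIO = {"I": 1.0, "II": 0.85, "III": 0.6, "IV": 0.45}


def _profile_knots(
    length_mm: float,
    r_max_mm: float,
    root_type: str,
    flat_frac: float,
    mid_ratio: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear radius profile: neck, swollen region, taper, thin tip.

    Every root ends in a thin tip (<= 1 mm diameter), so thick roots taper
    through every diameter class on their way out.
    """
    r_tip = max(min(0.3 * r_max_mm, 0.5), 0.15)
    neck = NECK_RATIO[root_type] * r_max_mm
    mid = np.clip(mid_ratio * r_max_mm, r_tip, r_max_mm)
    L = length_mm
    if NECK_RATIO[root_type] >= 0.99:
        s = np.array([0.0, flat_frac * L, (flat_frac + 0.6 * (1 - flat_frac)) * L, L])
        r = np.array([r_max_mm, r_max_mm, mid, min(r_tip, r_max_mm)])
    else:
        swell0 = 0.28 * L
        swell1 = (0.28 + flat_frac) * L
        s = np.array([0.0, 0.12 * L, swell0, swell1, 0.8 * L, L])
        r = np.array([neck, neck, r_max_mm, r_max_mm, mid, min(r_tip, r_max_mm)])
    return s, r


def _radius_knots(
    rng: np.random.Generator,
    length_mm: float,
    r_base_mm: float,
    root_type: str = "I",
    flat_frac: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    if flat_frac is None:
        flat_frac = rng.uniform(0.15, 0.30)
    mid_ratio = rng.uniform(0.45, 0.65)
    return _profile_knots(length_mm, r_base_mm, root_type, flat_frac, mid_ratio)


def make_root(
    rng: np.random.Generator,
    root_type: str,
    start_angle_rad: float = 0.0,
    anchor_mm: tuple[float, float] = (0.0, 0.0),
    length_mm: float | None = None,
    max_diameter_mm: float | None = None,
    obstacles: Obstacles | None = None,
) -> RootSpec:
    """Draw a random root of the given type from the per-type parameter ranges.

    With ``obstacles``, the axis deflects around already-placed roots (and
    the new root is registered), emulating side-by-side growth in the thin
    volume; without it roots may freely overlap.
    """
    if root_type not in TYPE_ORDER:
        raise ValueError(f"unknown root type {root_type!r}")
    if length_mm is None:
        length_mm = rng.uniform(*TYPE_LENGTH_RANGES[root_type])
    if max_diameter_mm is None:
        max_diameter_mm = rng.uniform(*TYPE_DIAMETER_RANGES[root_type])
    s, r = _radius_knots(rng, length_mm, max_diameter_mm / 2.0, root_type=root_type)
    radius_of_s = lambda q: np.interp(q, s, r)  # noqa: E731
    axis = _random_axis(
        rng,
        length_mm,
        start_angle_rad,
        anchor_mm=anchor_mm,
        obstacles=obstacles,
        radius_of_s=radius_of_s,
    )
    if obstacles is not None:
        arc = np.concatenate([[0.0], np.cumsum(np.hypot(*np.diff(axis, axis=0).T))])
        obstacles.add_root(axis, radius_of_s(arc))
    return RootSpec(
        root_type=root_type, axis_mm=axis, radius_knots_s=s, radius_knots_r=r
    )


# ---------------------------------------------------------------------------
# rendering


def render_scene(
    roots: list[RootSpec],
    mm_per_px: float,
    rng: np.random.Generator,
    shading: bool = True,
    pad_mm: float = 5.0,
    background_rgb: tuple[int, int, int] = BACKGROUND_RGB,
) -> np.ndarray:
    """Render roots as anti-aliased, front-lit shapes on a blue background.

    Each root is a disc-swept volume around its axis: the silhouette is the
    set of pixels whose distance to the axis is below the local radius, with
    a 1-px signed-distance ramp as anti-aliasing.  Shading darkens each root
    from its axis toward its silhouette edge, giving the round front-lit
    impression; the edge brightness is capped at 75% of the root color so
    edge contrast never collapses.  Roots are composited in order (later
    roots occlude earlier ones).
    """
    if not roots:
        raise ValueError("render_scene needs at least one root")
    if mm_per_px <= 0:
        raise ValueError("mm_per_px must be > 0")

    # canvas bounding box over all roots (axis +- max radius)
    mins = np.full(2, np.inf)
    maxs = np.full(2, -np.inf)
    for root in roots:
        rmax = root.radius_knots_r.max()
        mins = np.minimum(mins, root.axis_mm.min(axis=0) - rmax)
        maxs = np.maximum(maxs, root.axis_mm.max(axis=0) + rmax)
    mins -= pad_mm
    maxs += pad_mm
    W = int(np.ceil((maxs[0] - mins[0]) / mm_per_px))
    H = int(np.ceil((maxs[1] - mins[1]) / mm_per_px))
    if H * W > 4096 * 4096:
        raise ValueError(f"scene would need a {H}x{W} canvas; roots exceed frame")

    img = np.empty((H, W, 3), dtype=np.float64)
    img[:] = np.asarray(background_rgb, dtype=np.float64)

    for root in roots:
        color = np.asarray(ROOT_BASE_RGB) * rng.uniform(0.92, 1.08)
        sl, alpha, shade = _render_root(root, mins, (H, W), mm_per_px, shading)
        layer = color[None, None, :] * shade[:, :, None]
        a = alpha[:, :, None]
        img[sl] = img[sl] * (1.0 - a) + layer * a

    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def _render_root(root, origin_mm, shape, mm_per_px, shading):
    """Alpha and shading of one root on its bounding sub-grid."""
    H, W = shape
    ax = (root.axis_mm - origin_mm[None, :]) / mm_per_px  # (x, y) px
    s_mm = np.concatenate(
        [[0.0], np.cumsum(np.hypot(*np.diff(root.axis_mm, axis=0).T))]
    )
    # resample the axis densely so distance-to-polyline is accurate
    s_dense = np.arange(0.0, s_mm[-1], 0.5 * mm_per_px)
    xd = np.interp(s_dense, s_mm, ax[:, 0])
    yd = np.interp(s_dense, s_mm, ax[:, 1])
    r_px = root.radius_at(s_dense) / mm_per_px
    rmax = float(r_px.max())

    x0 = max(int(np.floor(xd.min() - rmax - 2)), 0)
    x1 = min(int(np.ceil(xd.max() + rmax + 3)), W)
    y0 = max(int(np.floor(yd.min() - rmax - 2)), 0)
    y1 = min(int(np.ceil(yd.max() + rmax + 3)), H)
    sl = np.s_[y0:y1, x0:x1]
    yy, xx = np.mgrid[y0:y1, x0:x1]

    tree = cKDTree(np.column_stack([yd, xd]))
    dist, idx = tree.query(np.column_stack([yy.ravel(), xx.ravel()]), k=1)
    dist = dist.reshape(yy.shape)
    r_loc = np.maximum(r_px[idx].reshape(yy.shape), 1e-6)

    # 1-px anti-aliasing ramp on the signed distance to the silhouette
    alpha = np.clip(0.5 - (dist - r_loc), 0.0, 1.0)

    if not shading:
        return sl, alpha, np.ones_like(alpha)
    rel = np.clip(dist / r_loc, 0.0, 1.0)
    shade = 0.75 + 0.25 * np.sqrt(1.0 - rel**2)
    return sl, alpha, shade


# ---------------------------------------------------------------------------
# dataset families


def generate_single_root(
    root_type: str,
    mm_per_px: float,
    seed: int,
    shading: bool = True,
) -> tuple[np.ndarray, GroundTruth, RootSpec]:
    """One random root of the given type on its own canvas."""
    rng = np.random.default_rng(seed)
    root = make_root(rng, root_type, start_angle_rad=rng.uniform(-0.5, 0.5))
    img = render_scene([root], mm_per_px, rng, shading=shading)
    truth = GroundTruth(per_root=root.fine_bin_lengths()[None, :])
    return img, truth, root


def generate_root_system(
    n_roots: int,
    root_type: str,
    mm_per_px: float,
    seed: int,
    spread_rad: float = 1.3,
    anchor_halfwidth_mm: float = 50.0,
    shading: bool = True,
) -> tuple[np.ndarray, GroundTruth, list[RootSpec]]:
    """A one-type system: n roots fanning out of a common basal anchor.

    Emergence angles fill the fan evenly with random jitter (physical
    exclusion at the base) and anchor points distribute across the width of
    an excavated cassava root crown (±50 mm); roots deflect around each other as they
    would in the thin growth volume, so overlap concentrates near the base.
    """
    if n_roots < 1:
        raise ValueError("n_roots must be >= 1")
    rng = np.random.default_rng(seed)
    roots = []
    obstacles = Obstacles()
    slots = np.linspace(-spread_rad, spread_rad, n_roots) if n_roots > 1 else [0.0]
    order = rng.permutation(n_roots)
    for k in order:
        angle = float(slots[k]) + rng.uniform(-0.1, 0.1)
        ax = float(slots[k]) / max(spread_rad, 1e-9) * anchor_halfwidth_mm
        anchor = (ax + rng.uniform(-8.0, 8.0), rng.uniform(-8.0, 8.0))
        roots.append(
            make_root(
                rng,
                root_type,
                start_angle_rad=angle,
                anchor_mm=anchor,
                obstacles=obstacles,
            )
        )
    img = render_scene(roots, mm_per_px, rng, shading=shading)
    truth = GroundTruth(
        per_root=np.stack([r.fine_bin_lengths() for r in roots])
    )
    return img, truth, roots


# ---------------------------------------------------------------------------
# growth series


@dataclass
class RootGrowth:
    """Growth trajectory of one root of the simulated system.

    The full-grown axis is fixed; each week the root occupies its first
    ``length_at(week)`` mm of arc with a radius profile scaled to the
    current maximum diameter ``diameter_at(week)``.
    """

    destiny_type: str
    axis_full_mm: np.ndarray
    final_length_mm: float
    t_emerge: float
    t_full_length: float
    diam_knots_t: np.ndarray
    diam_knots_d: np.ndarray
    flat_frac: float
    mid_ratio: float = 0.55

    def length_at(self, week: float) -> float:
        f = np.clip(
            (week - self.t_emerge) / (self.t_full_length - self.t_emerge), 0.0, 1.0
        )
        return float(self.final_length_mm * f)

    def diameter_at(self, week: float) -> float:
        return float(np.interp(week, self.diam_knots_t, self.diam_knots_d))

    def type_at(self, week: float) -> str:
        d = self.diameter_at(week)
        idx = int(DiameterClassScheme().classify(np.array([d]))[0])
        return TYPE_ORDER[idx]

    def spec_at(self, week: float) -> RootSpec | None:
        length = self.length_at(week)
        if length < 10.0:  # not yet visible
            return None
        # clip the full axis to the current arc length
        steps = np.hypot(*np.diff(self.axis_full_mm, axis=0).T)
        s = np.concatenate([[0.0], np.cumsum(steps)])
        n = int(np.searchsorted(s, length)) + 1
        axis = self.axis_full_mm[: max(n, 2)]
        rtype = self.type_at(week)  # the neck develops as the root swells
        ks, kr = _profile_knots(
            length, self.diameter_at(week) / 2.0, rtype, self.flat_frac,
            self.mid_ratio,
        )
        return RootSpec(
            root_type=rtype,
            axis_mm=axis,
            radius_knots_s=ks,
            radius_knots_r=kr,
        )


#: destiny-type composition of the 80-root system
SYSTEM_TYPE_COUNTS = {"I": 40, "II": 20, "III": 14, "IV": 6}


def simulate_system(
    seed: int,
    n_roots: int = 80,
    week_class4: float = 10.0,
    final_week: float = 13.0,
) -> list[RootGrowth]:
    """Simulate the growth trajectories of an n-root system.

    Fibrous roots appear early; subsets thicken into transition, early
    storage and storage roots.  Storage-root trajectories are pinned so the
    first root reaches the 20 mm class-4 boundary exactly at
    ``week_class4``; before that week the class-4 truth is identically zero.
    """
    rng = np.random.default_rng(seed)
    counts = _scale_counts(SYSTEM_TYPE_COUNTS, n_roots)
    # thick roots are laid out first so they claim contiguous space; thin
    # fibrous roots thread through the remaining gaps
    type_list = [t for t in reversed(TYPE_ORDER) for _ in range(counts[t])]
    slots = np.linspace(-1.0, 1.0, n_roots) if n_roots > 1 else np.zeros(1)
    slot_of = rng.permutation(n_roots)

    roots: list[RootGrowth] = []
    obstacles = Obstacles()
    iv_index = 0
    for j, rtype in enumerate(type_list):
        final_len = rng.uniform(*TYPE_LENGTH_RANGES[rtype])
        d_final = rng.uniform(*TYPE_DIAMETER_RANGES[rtype])
        t_emerge = rng.uniform(1.0, 3.0)
        t_full = t_emerge + rng.uniform(3.0, 6.0)
        t_thick = rng.uniform(3.0, 5.0)
        d_start = rng.uniform(0.8, 1.2)
        if rtype == "I":
            kt = np.array([t_thick, final_week])
            kd = np.array([min(d_start, d_final), d_final])
        elif rtype == "II":
            kt = np.array([t_thick, rng.uniform(9.0, final_week)])
            kd = np.array([d_start, d_final])
        elif rtype == "III":
            t6 = rng.uniform(6.0, 8.0)
            kt = np.array([t_thick, t6, final_week])
            kd = np.array([d_start, 6.0, d_final])
        else:  # IV: pin the 20-mm crossing at or after week_class4
            t6 = rng.uniform(6.0, 7.5)
            n_iv = counts["IV"]
            t20 = week_class4 + 0.8 * iv_index / max(n_iv - 1, 1)
            iv_index += 1
            kt = np.array([t_thick, t6, t20, final_week])
            kd = np.array([d_start, 6.0, 20.0, d_final])
        flat_frac = rng.uniform(0.15, 0.30)
        mid_ratio = rng.uniform(0.45, 0.65)
        # avoidance against the other roots' final-size footprint
        prof_s, prof_r = _profile_knots(
            final_len, d_final / 2.0, rtype, flat_frac, mid_ratio
        )
        radius_of_s = lambda q, s=prof_s, r=prof_r: np.interp(q, s, r)  # noqa: E731
        slot = float(slots[slot_of[j]])
        anchor = (slot * 50.0 + rng.uniform(-8.0, 8.0), rng.uniform(-8.0, 8.0))
        axis = _random_axis(
            rng,
            final_len,
            start_angle_rad=slot * 1.25 + rng.uniform(-0.08, 0.08),
            anchor_mm=anchor,
            obstacles=obstacles,
            radius_of_s=radius_of_s,
        )
        arc = np.concatenate([[0.0], np.cumsum(np.hypot(*np.diff(axis, axis=0).T))])
        obstacles.add_root(axis, radius_of_s(arc))
        roots.append(
            RootGrowth(
                destiny_type=rtype,
                axis_full_mm=axis,
                final_length_mm=final_len,
                t_emerge=t_emerge,
                t_full_length=t_full,
                diam_knots_t=kt,
                diam_knots_d=kd,
                flat_frac=flat_frac,
                mid_ratio=mid_ratio,
            )
        )
    _relocate_buried(roots, rng)
    return roots


def _final_radii(root: RootGrowth) -> tuple[np.ndarray, np.ndarray]:
    axis = root.axis_full_mm
    arc = np.concatenate([[0.0], np.cumsum(np.hypot(*np.diff(axis, axis=0).T))])
    ks, kr = _profile_knots(
        root.final_length_mm,
        float(root.diam_knots_d[-1]) / 2.0,
        root.destiny_type,
        root.flat_frac,
        root.mid_ratio,
    )
    return axis, np.interp(arc, ks, kr)


def _relocate_buried(
    roots: list[RootGrowth], rng: np.random.Generator, max_attempts: int = 10
) -> None:
    """Regrow thick roots that ended up deeply inside other thick roots.

    Greedy sequential placement occasionally wedges a root between two
    neighbors it cannot escape; a real root would have found another gap.
    Each buried root is regrown from a fresh random emergence point and the
    least-overlapping attempt kept.
    """
    thick = [i for i, r in enumerate(roots) if r.diam_knots_d[-1] >= 2.5]

    def overlap_frac(axis, radii, others):
        tree = cKDTree(np.vstack([o[0] for o in others]))
        all_r = np.concatenate([o[1] for o in others])
        dd, ii = tree.query(axis)
        pen = radii + all_r[ii] - dd
        return float((pen > 0.3 * (radii + all_r[ii])).mean())

    finals = {i: _final_radii(roots[i]) for i in thick}
    for i in thick:
        others = [finals[j] for j in thick if j != i]
        if not others:
            continue
        axis, radii = finals[i]
        best = overlap_frac(axis, radii, others)
        if best <= 0.15:
            continue
        obs = Obstacles()
        for ax_o, r_o in others:
            obs.add_root(ax_o, r_o)
        root = roots[i]
        for _ in range(max_attempts):
            slot = rng.uniform(-1.0, 1.0)
            anchor = (slot * 50.0 + rng.uniform(-8.0, 8.0), rng.uniform(-8.0, 8.0))
            ks, kr = _profile_knots(
                root.final_length_mm,
                float(root.diam_knots_d[-1]) / 2.0,
                root.destiny_type,
                root.flat_frac,
                root.mid_ratio,
            )
            radius_of_s = lambda q, s=ks, r=kr: np.interp(q, s, r)  # noqa: E731
            cand = _random_axis(
                rng,
                root.final_length_mm,
                start_angle_rad=slot * 1.25 + rng.uniform(-0.08, 0.08),
                anchor_mm=anchor,
                obstacles=obs,
                radius_of_s=radius_of_s,
            )
            arc = np.concatenate(
                [[0.0], np.cumsum(np.hypot(*np.diff(cand, axis=0).T))]
            )
            frac = overlap_frac(cand, radius_of_s(arc), others)
            if frac < best:
                best = frac
                root.axis_full_mm = cand
                finals[i] = (cand, radius_of_s(arc))
            if best <= 0.05:
                break


def _scale_counts(counts: dict[str, int], n: int) -> dict[str, int]:
    """Largest-remainder scaling of the type composition to n roots."""
    total = sum(counts.values())
    raw = {k: v * n / total for k, v in counts.items()}
    out = {k: int(np.floor(v)) for k, v in raw.items()}
    rem = n - sum(out.values())
    order = sorted(counts, key=lambda k: raw[k] - out[k], reverse=True)
    for k in order[:rem]:
        out[k] += 1
    return out


def stratified_subset(
    system: list[RootGrowth],
    week: float,
    subset_size: int,
    rng: np.random.Generator,
) -> list[int]:
    """Indices of a random subset preserving the current type proportions."""
    visible = [i for i, r in enumerate(system) if r.spec_at(week) is not None]
    if len(visible) <= subset_size:
        return visible
    by_type: dict[str, list[int]] = {}
    for i in visible:
        by_type.setdefault(system[i].type_at(week), []).append(i)
    counts = _scale_counts(
        {t: len(idx) for t, idx in by_type.items()}, subset_size
    )
    chosen: list[int] = []
    for t, idx in by_type.items():
        k = min(counts.get(t, 0), len(idx))
        chosen.extend(rng.choice(idx, size=k, replace=False).tolist())
    return sorted(chosen)


@dataclass
class WeekScene:
    """One rendered subset scene of the growth series."""

    week: float
    subset: int
    image: np.ndarray
    truth: GroundTruth
    root_indices: list[int] = field(default_factory=list)


def generate_time_series(
    seed: int,
    mm_per_px: float = 0.6,
    weeks: tuple[float, ...] = tuple(range(2, 14)),
    n_roots: int = 80,
    n_subsets: int = 25,
    subset_size: int = 17,
    week_class4: float = 10.0,
    shading: bool = True,
):
    """Yield rendered subset scenes for every week of the growth series."""
    if subset_size > n_roots:
        raise ValueError("subset_size must be <= n_roots")
    system = simulate_system(seed, n_roots=n_roots, week_class4=week_class4)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    for week in weeks:
        for k in range(n_subsets):
            idx = stratified_subset(system, week, subset_size, rng)
            specs = [system[i].spec_at(week) for i in idx]
            specs = [sp for sp in specs if sp is not None]
            if not specs:
                continue
            img = render_scene(specs, mm_per_px, rng, shading=shading)
            truth = GroundTruth(
                per_root=np.stack([sp.fine_bin_lengths() for sp in specs])
            )
            yield WeekScene(
                week=week, subset=k, image=img, truth=truth, root_indices=idx
            )


def save_scene(
    directory: str | Path,
    name: str,
    image: np.ndarray,
    truth: GroundTruth,
    manifest: dict | None = None,
) -> None:
    """Write a scene as PNG + JSON truth (+ optional manifest entry)."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    iio.imwrite(directory / f"{name}.png", image)
    payload = {
        "fine_bin_edges_mm": [e if np.isfinite(e) else None for e in FINE_BIN_EDGES],
        "scene_fine_mm": truth.scene_fine.tolist(),
        "class_lengths_mm": truth.class_lengths().tolist(),
    }
    if manifest:
        payload["manifest"] = manifest
    with open(directory / f"{name}.json", "w") as fh:
        json.dump(payload, fh, indent=1)
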