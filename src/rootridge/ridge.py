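"""Curvilinear-structure (ridge) detection with per-point width measurement.

Roots appear in the masked gray image as bright bar-shaped structures on a
zeroed background.  Their centerlines are located in the Steger manner: the
image is smoothed with a Gaussian of scale σ, and a pixel is a line point if
the second directional derivative along the principal curvature direction
(the eigenvector of the Hessian with the largest-magnitude eigenvalue) is
strongly negative and the first directional derivative has a sub-pixel zero
crossing inside the pixel.  Hysteresis on the response links salient points
(response ≥ u) through weaker ones (response ≥ l).

The salient-point threshold follows from the response of an ideal bar of
half-width w and contrast h at scale σ:

    u = 2 w h / (√(2π) σ³) · exp(−w² / (2σ²)),

with the scale rule σ ≥ w/3.  Widths are read off as the distances from the
centerline to the first local maximum of the absolute gradient along the
positive and negative normal; a missing edge on one side is interpolated
from neighboring points of the same line and flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label
from skimage.morphology import thin

_SQRT2PI = float(np.sqrt(2.0 * np.pi))

#: offsets of the 8-neighborhood
_NBRS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def compute_threshold_u(w: float, sigma: float, h: float) -> float:
    """Salient-point threshold for a bar of half-width w and contrast h at scale σ."""
    if w <= 0 or sigma <= 0 or h < 0:
        raise ValueError("w and sigma must be > 0 and h >= 0")
    return 2.0 * w * h / (_SQRT2PI * sigma**3) * float(np.exp(-(w**2) / (2.0 * sigma**2)))


@dataclass
class RidgeParams:
    """One parameter constellation of the detector.

    ``w`` is the maximum root half-width in pixels the constellation targets,
    ``sigma`` the Gaussian scale (must satisfy σ ≥ w/3), ``h`` the expected
    root-background contrast in gray levels.  ``upper_u`` defaults to the
    ideal-bar response of (w, σ, h); ``lower_ratio`` = l/u.
    """

    w: float
    h: float
    sigma: float | None = None
    upper_u: float | None = None
    lower_ratio: float = 0.35

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError("w and h must be > 0")
        if self.sigma is None:
            # smallest scale allowed by the σ ≥ w/3 rule, floored for grid stability
            self.sigma = max(self.w / 3.0, 1.0)
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.sigma < self.w / 3.0 - 1e-12:
            warnings.warn(
                f"sigma={self.sigma:.3g} violates the rule sigma >= w/3 "
                f"(w={self.w:.3g})",
                stacklevel=2,
            )
        if not 0.0 < self.lower_ratio <= 1.0:
            raise ValueError("lower_ratio must lie in (0, 1]")
        if self.upper_u is None:
            self.upper_u = compute_threshold_u(self.w, self.sigma, self.h)
        if self.upper_u < 0:
            raise ValueError("upper_u must be >= 0")

    @property
    def lower_l(self) -> float:
        return self.lower_ratio * self.upper_u


@dataclass
class GaussianKernelSet:
    """Discrete Gaussian and derivative kernels at one scale."""

    sigma: float
    g0: np.ndarray
    g1: np.ndarray
    g2: np.ndarray
    radius: int


def gaussian_kernels(sigma: float) -> GaussianKernelSet:
    """Sampled Gaussian, first- and second-derivative kernels, truncated at ⌈3.5σ⌉."""
    radius = int(np.ceil(3.5 * sigma))
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    g0 = np.exp(-(x**2) / (2.0 * sigma**2)) / (_SQRT2PI * sigma)
    g0 = g0 / g0.sum()
    g1 = -x / sigma**2 * g0
    g1 = g1 - g1.mean()
    g2 = (x**2 - sigma**2) / sigma**4 * g0
    g2 = g2 - g2.mean()
    return GaussianKernelSet(sigma=sigma, g0=g0, g1=g1, g2=g2, radius=radius)


@dataclass
class LinePoint:
    """One centerline point with its sub-pixel position and width."""

    row: float
    col: float
    normal_angle: float
    response: float
    edge_left: float = np.nan
    edge_right: float = np.nan
    interpolated: bool = False

    @property
    def width_px(self) -> float:
        return self.edge_left + self.edge_right


@dataclass
class Line:
    """An ordered centerline path (pixel-adjacent before sub-pixel refinement).

    Per-point data is stored as parallel arrays; ``points`` materializes
    ``LinePoint`` objects on demand.
    """

    rows: np.ndarray          # sub-pixel row positions
    cols: np.ndarray          # sub-pixel col positions
    irows: np.ndarray         # integer pixel rows
    icols: np.ndarray         # integer pixel cols
    normal_angles: np.ndarray
    responses: np.ndarray
    closed: bool = False
    edge_left: np.ndarray = field(default=None)  # type: ignore[assignment]
    edge_right: np.ndarray = field(default=None)  # type: ignore[assignment]
    interpolated: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def width_px(self) -> np.ndarray:
        if self.edge_left is None:
            raise AttributeError("widths not measured yet")
        return self.edge_left + self.edge_right

    @property
    def points(self) -> list[LinePoint]:
        out = []
        measured = self.edge_left is not None
        for i in range(len(self)):
            out.append(
                LinePoint(
                    row=float(self.rows[i]),
                    col=float(self.cols[i]),
                    normal_angle=float(self.normal_angles[i]),
                    response=float(self.responses[i]),
                    edge_left=float(self.edge_left[i]) if measured else np.nan,
                    edge_right=float(self.edge_right[i]) if measured else np.nan,
                    interpolated=bool(self.interpolated[i]) if measured else False,
                )
            )
        return out


def _gaussian_derivatives(gray: np.ndarray, sigma: float):
    g = np.asarray(gray, dtype=np.float64)
    t = 3.5
    rr = ndimage.gaussian_filter(g, sigma, order=(2, 0), truncate=t)
    rc = ndimage.gaussian_filter(g, sigma, order=(1, 1), truncate=t)
    cc = ndimage.gaussian_filter(g, sigma, order=(0, 2), truncate=t)
    gr = ndimage.gaussian_filter(g, sigma, order=(1, 0), truncate=t)
    gc = ndimage.gaussian_filter(g, sigma, order=(0, 1), truncate=t)
    return gr, gc, rr, rc, cc


def _principal_curvature(rr, rc, cc):
    """Largest-|eigenvalue| of the Hessian and its (row, col) eigenvector."""
    half_tr = 0.5 * (rr + cc)
    disc = np.sqrt(np.maximum(0.25 * (rr - cc) ** 2 + rc**2, 0.0))
    lam1 = half_tr + disc
    lam2 = half_tr - disc
    lam = np.where(np.abs(lam1) >= np.abs(lam2), lam1, lam2)
    vr = rc.copy()
    vc = lam - rr
    nrm = np.hypot(vr, vc)
    tiny = nrm < 1e-12
    # degenerate (axis-aligned) case: pick the axis whose diagonal entry matches λ
    take_row = np.abs(rr - lam) <= np.abs(cc - lam)
    vr = np.where(tiny, np.where(take_row, 1.0, 0.0), vr)
    vc = np.where(tiny, np.where(take_row, 0.0, 1.0), vc)
    nrm = np.where(tiny, 1.0, nrm)
    return lam, vr / nrm, vc / nrm


def detect_ridges(
    gray: np.ndarray,
    params: RidgeParams,
    exclusion: np.ndarray | None = None,
    min_line_px: int = 3,
    _derivs=None,
) -> list[Line]:
    """Detect bright centerlines at one scale.

    ``exclusion`` is a boolean mask of pixels barred from becoming line
    points (the deletion mask of the iterative scheme).  Lines shorter than
    ``min_line_px`` pixels are discarded.
    """
    g = np.asarray(gray, dtype=np.float64)
    if g.size == 0:
        return []
    sigma = params.sigma
    gr, gc, rr, rc, cc = _derivs if _derivs is not None else _gaussian_derivatives(g, sigma)
    lam, nr, nc = _principal_curvature(rr, rc, cc)

    # bright lines: principal second derivative strongly negative
    response = np.where(lam < 0, -lam, 0.0)

    # sub-pixel stationary point of the profile along the normal
    denom = np.where(np.abs(lam) > 1e-12, lam, 1e-12)
    t = -(gr * nr + gc * nc) / denom
    within = (np.abs(t * nr) <= 0.55) & (np.abs(t * nc) <= 0.55)

    cand = within & (response >= params.lower_l) & (lam < 0)
    if exclusion is not None:
        cand &= ~exclusion.astype(bool)
    if not cand.any():
        return []

    # hysteresis: keep components (8-connectivity) containing a salient point
    lbl = cc_label(cand, connectivity=2)
    seed_ids = np.unique(lbl[cand & (response >= params.upper_u)])
    seed_ids = seed_ids[seed_ids > 0]
    if seed_ids.size == 0:
        return []
    keep_tab = np.zeros(lbl.max() + 1, dtype=bool)
    keep_tab[seed_ids] = True
    keep = keep_tab[lbl]

    # the sub-pixel zero crossing can fall inside two adjacent pixels (even
    # widths), giving a 2-px-thick band; thin to a 1-px chain before tracing
    keep = thin(keep)

    lines = _trace_lines(keep, min_line_px)

    out = []
    for irows, icols, closed in lines:
        tr = t[irows, icols]
        vr = nr[irows, icols]
        vc = nc[irows, icols]
        out.append(
            Line(
                rows=irows + tr * vr,
                cols=icols + tr * vc,
                irows=irows,
                icols=icols,
                normal_angles=np.arctan2(vr, vc),
                responses=response[irows, icols],
                closed=closed,
            )
        )
    return out


def _trace_lines(mask: np.ndarray, min_line_px: int):
    """Split a centerline mask into ordered simple paths.

    Junction pixels (more than 2 neighbors in the mask) terminate paths, so
    branches become separate lines.
    """
    nb_kernel = np.ones((3, 3), dtype=np.uint8)
    nb_kernel[1, 1] = 0
    nb = ndimage.convolve(mask.astype(np.uint8), nb_kernel, mode="constant")
    simple = mask & (nb <= 2)
    lbl = cc_label(simple, connectivity=2)
    results = []
    for region_id in range(1, lbl.max() + 1):
        rs, cs = np.nonzero(lbl == region_id)
        if rs.size < max(min_line_px, 1):
            continue
        pts = set(zip(rs.tolist(), cs.tolist()))
        order, closed = _walk_path(pts)
        arr = np.asarray(order)
        results.append((arr[:, 0], arr[:, 1], closed))
    return results


def _walk_path(pts: set[tuple[int, int]]):
    def neighbors(p):
        r, c = p
        for dr, dc in _NBRS:
            q = (r + dr, c + dc)
            if q in pts:
                yield q

    endpoints = [p for p in pts if sum(1 for _ in neighbors(p)) <= 1]
    closed = not endpoints
    start = min(endpoints) if endpoints else min(pts)
    visited = {start}
    path = [start]
    cur = start
    while True:
        nxt = [q for q in neighbors(cur) if q not in visited]
        if not nxt:
            break
        # prefer 4-adjacent continuation over diagonal to keep chain order
        cur = min(nxt, key=lambda q: ((q[0] - cur[0]) ** 2 + (q[1] - cur[1]) ** 2, q))
        visited.add(cur)
        path.append(cur)
    return path, closed


def measure_widths(
    lines: list[Line],
    gray: np.ndarray,
    params: RidgeParams,
    _derivs=None,
    refine: bool = True,
    medial_check: bool = False,
    _grad_cache: dict | None = None,
) -> list[Line]:
    """Attach per-point widths to detected lines.

    For every line point the absolute first directional derivative is sampled
    along ±normal; the distance to its first local maximum on each side gives
    ``edge_left``/``edge_right``.  The search extends to w + 2.5σ (the edge of
    a bar of half-width w lies at distance w from the center, beyond the bare
    2.5σ when σ is at its lower bound w/3).

    When ``refine`` is on, points whose provisional width is much smaller
    than the detection scale warrants are re-measured at a reduced scale
    σ' ≈ width/8: at large σ the smoothing also averages *along* the root, so
    tapering sections pull the gradient extrema of a thick crown inward; a
    scale proportional to the local width removes that bias while still
    suppressing pixel noise.

    Sides with no edge are filled by linear interpolation along the line and
    flagged; if a whole side of a line lacks edges it mirrors the other
    side; points of a line with no edges at all are dropped with the line.
    """
    g = np.asarray(gray, dtype=np.float64)
    sigma = params.sigma
    if _derivs is not None:
        gr, gc = _derivs[0], _derivs[1]
    else:
        gr, gc = _grad_fields(g, sigma)

    search_len = params.w + 2.5 * sigma
    step = 0.5
    dists = np.arange(0.0, search_len + step, step)
    # minimum believable edge strength: half the gradient peak of an ideal
    # step edge of contrast h at this scale.  Over-blurred thin structures
    # (half-width << sigma) fall below it and are dropped, which is the
    # failure mode the multi-scale iteration exists to fix.
    floor = _edge_floor(params.h, sigma)

    if _grad_cache is None:
        _grad_cache = {}

    edt = None
    if medial_check:
        if "edt" not in _grad_cache:
            _grad_cache["edt"] = ndimage.distance_transform_edt(g > 0)
        edt = _grad_cache["edt"]

    out = []
    for line in lines:
        nrv = np.sin(line.normal_angles)
        ncv = np.cos(line.normal_angles)
        el = _edge_distances(
            line.rows, line.cols, nrv, ncv, gr, gc, dists, floor, +1
        )
        er = _edge_distances(
            line.rows, line.cols, nrv, ncv, gr, gc, dists, floor, -1
        )
        if refine:
            for _ in range(2):
                el, er = _refine_edges(
                    line, nrv, ncv, el, er, g, params, _grad_cache
                )
        if edt is not None:
            # medial veto: a real centerline point is a local maximum of
            # the foreground distance transform along its normal.  Shading
            # gradients on the flank of a much thicker root mimic edges,
            # but there the distance transform keeps rising toward the
            # true axis; such points are marked missing (short runs are
            # bridged below, systematic runs drop out).
            bad = _off_medial_axis(line, nrv, ncv, edt)
            el[bad] = np.nan
            er[bad] = np.nan
        interp = np.isnan(el) | np.isnan(er)
        wmed = np.nanmedian(el + er) if np.isfinite(el + er).any() else 0.0
        max_gap = max(7, int(round(1.2 * wmed)))
        el = _fill_missing(el, max_gap=max_gap)
        er = _fill_missing(er, max_gap=max_gap)
        # points still lacking an edge on either side are dropped; short
        # occlusions were bridged by the interpolation above
        valid = np.isfinite(el) & np.isfinite(er)
        if valid.sum() < 2:
            continue
        _subset_line(line, valid)
        line.edge_left = el[valid]
        line.edge_right = er[valid]
        line.interpolated = interp[valid]
        out.append(line)
    return out


def _subset_line(line: Line, keep: np.ndarray) -> None:
    line.rows = line.rows[keep]
    line.cols = line.cols[keep]
    line.irows = line.irows[keep]
    line.icols = line.icols[keep]
    line.normal_angles = line.normal_angles[keep]
    line.responses = line.responses[keep]


def _off_medial_axis(line, nrv, ncv, edt, probe: float = 2.0, tol: float = 1.0):
    """Points where the foreground distance transform rises along the normal."""
    coords0 = np.stack([line.rows, line.cols])
    d0 = ndimage.map_coordinates(edt, coords0, order=1, mode="nearest")
    bad = np.zeros(len(line), dtype=bool)
    for sign in (+1, -1):
        rows = line.rows + sign * probe * nrv
        cols = line.cols + sign * probe * ncv
        d = ndimage.map_coordinates(
            edt, np.stack([rows, cols]), order=1, mode="nearest"
        )
        bad |= d > d0 + tol
    return bad


def _grad_fields(g: np.ndarray, sigma: float):
    gr = ndimage.gaussian_filter(g, sigma, order=(1, 0), truncate=3.5)
    gc = ndimage.gaussian_filter(g, sigma, order=(0, 1), truncate=3.5)
    return gr, gc


def _edge_floor(h: float, sigma: float) -> float:
    return 0.5 * h / (_SQRT2PI * sigma)


def _refine_edges(line, nrv, ncv, el, er, g, params, cache):
    """Re-localize edges at a scale matched to each point's provisional width."""
    w_prov = el + er
    ok = np.isfinite(w_prov)
    if not ok.any():
        return el, er
    # quantized refinement ladder: halving steps below the detection scale
    sig_tgt = np.clip(w_prov / 12.0, 1.0, params.sigma)
    levels = []
    s = params.sigma / 2.0
    while s >= 1.0:
        levels.append(s)
        s /= 2.0
    if not levels:
        return el, er
    levels = np.asarray(levels)
    for sig in levels:
        sel = ok & (np.abs(np.log(np.maximum(sig_tgt, 1e-9) / sig)) <= np.log(np.sqrt(2.0)))
        if not sel.any():
            continue
        key = round(float(sig), 3)
        if key not in cache:
            cache[key] = _grad_fields(g, sig)
        gr2, gc2 = cache[key]
        # the provisional width can be badly biased at large detection
        # scales, so the search must reach the full band of the step
        reach = 1.1 * params.w + 3.0 * sig
        d2 = np.arange(0.0, reach + 0.5, 0.5)
        floor2 = _edge_floor(params.h, sig)
        el2 = _edge_distances(
            line.rows[sel], line.cols[sel], nrv[sel], ncv[sel],
            gr2, gc2, d2, floor2, +1,
        )
        er2 = _edge_distances(
            line.rows[sel], line.cols[sel], nrv[sel], ncv[sel],
            gr2, gc2, d2, floor2, -1,
        )
        good = np.isfinite(el2) & np.isfinite(er2)
        idx = np.nonzero(sel)[0][good]
        el[idx] = el2[good]
        er[idx] = er2[good]
    return el, er


def _edge_distances(prows, pcols, nrv, ncv, gr, gc, dists, floor, sign):
    """Distance to the first local max of |directional derivative| along sign*normal."""
    n = prows.size
    k = dists.size
    rows = prows[:, None] + sign * dists[None, :] * nrv[:, None]
    cols = pcols[:, None] + sign * dists[None, :] * ncv[:, None]
    coords = np.stack([rows.ravel(), cols.ravel()])
    pg_r = ndimage.map_coordinates(gr, coords, order=1, mode="nearest").reshape(n, k)
    pg_c = ndimage.map_coordinates(gc, coords, order=1, mode="nearest").reshape(n, k)
    prof = np.abs(pg_r * nrv[:, None] + pg_c * ncv[:, None])

    # first interior local maximum above the floor
    is_max = np.zeros_like(prof, dtype=bool)
    is_max[:, 1:-1] = (
        (prof[:, 1:-1] >= prof[:, :-2])
        & (prof[:, 1:-1] >= prof[:, 2:])
        & (prof[:, 1:-1] >= floor)
    )
    any_max = is_max.any(axis=1)
    first = np.argmax(is_max, axis=1)

    out = np.full(n, np.nan)
    idx = np.nonzero(any_max)[0]
    if idx.size:
        j = first[idx]
        # parabolic sub-sample refinement around the peak
        y0 = prof[idx, j - 1]
        y1 = prof[idx, j]
        y2 = prof[idx, j + 1]
        denom = y0 - 2.0 * y1 + y2
        delta = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
        delta = np.clip(delta, -0.5, 0.5)
        out[idx] = dists[j] + delta * (dists[1] - dists[0])
    return out


def _fill_missing(vals: np.ndarray, max_gap: int = 7) -> np.ndarray:
    """Interpolate NaN runs of at most ``max_gap`` points along a line.

    Longer runs stay NaN: they are systematically missing edges (e.g. the
    flank of a much thicker structure), not short occlusions.
    """
    ok = ~np.isnan(vals)
    if not ok.any() or ok.all():
        return vals
    x = np.arange(vals.size, dtype=float)
    filled = vals.copy()
    filled[~ok] = np.interp(x[~ok], x[ok], vals[ok])
    # identify NaN runs longer than max_gap and restore them to NaN
    run_start = None
    for i in range(vals.size + 1):
        missing = i < vals.size and not ok[i]
        if missing and run_start is None:
            run_start = i
        elif not missing and run_start is not None:
            if i - run_start > max_gap:
                filled[run_start:i] = np.nan
            run_start = None
    return filled
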