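"""Fragment analysis (FA) of the lesion boundary.

The grayscale transition zone from the radiolucent lesion interior to the
surrounding bone is covered with oriented 1 mm x 1 mm squares: each square is
centered on the transition-zone centerline with one side parallel to the
local boundary tangent, consecutive squares touch without overlapping, and
the image fragments cut out by the squares are re-oriented (lesion interior
on the left) and concatenated end to end.  The result is a striped image
(ROI "S4") in which direction-sensitive texture statistics become
boundary-relative: rotating the whole radiograph leaves the stripes - and
hence the texture features - essentially unchanged.

Geometry is done in physical millimetre coordinates (x = col * spacing,
y = row * spacing); square placement marches exactly one square-side chord
per step, and exact polygon intersection tests verify that the non-overlap
and touching tolerances hold when the closure remainder is distributed.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from shapely.geometry import Polygon

from .edges import LesionContour, fill_contour
from .image import Radiograph


class TransitionError(RuntimeError):
    """Raised when the transition zone cannot be localized."""


class TilingError(RuntimeError):
    """Raised when the centerline cannot be tiled with squares."""


class ExtractionError(RuntimeError):
    """Raised when a square cannot be sampled from the image."""


class AssemblyError(ValueError):
    """Raised when fragments cannot be concatenated."""


@dataclass
class TransitionBand:
    """Localized transition zone along the lesion boundary.

    ``centerline`` holds the 50% intensity-crossing points (row, col, px),
    ordered consistently with the source contour and closed implicitly;
    ``normals`` are the outward unit normals at those points and
    ``local_width`` the 10%->90% rise distance in mm.
    """

    centerline: np.ndarray  # (N, 2) row/col px
    normals: np.ndarray  # (N, 2) outward unit vectors, row/col
    local_width: np.ndarray  # (N,) mm
    band_mask: np.ndarray  # bool, same shape as image
    spacing: float

    def __post_init__(self) -> None:
        if np.any(self.local_width <= 0):
            raise ValueError("local transition widths must be positive")

    def arclength_mm(self) -> float:
        d = np.diff(np.vstack([self.centerline, self.centerline[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum()) * self.spacing


@dataclass
class BoundarySquare:
    """One oriented FA square on the transition-zone centerline."""

    center: np.ndarray  # (row, col) px
    angle: float  # radians; tangent direction in (x=col, y=row) axes
    side_mm: float
    tangent: np.ndarray  # (row, col) unit vector
    normal: np.ndarray  # outward (row, col) unit vector

    def polygon_mm(self, spacing: float) -> Polygon:
        """Square outline in physical (x, y) = (col, row) mm coordinates."""
        c = np.array([self.center[1], self.center[0]]) * spacing
        t = np.array([self.tangent[1], self.tangent[0]])
        n = np.array([self.normal[1], self.normal[0]])
        h = self.side_mm / 2.0
        corners = [c + h * (st * t + sn * n) for st, sn in
                   ((-1, -1), (1, -1), (1, 1), (-1, 1))]
        return Polygon(corners)


@dataclass
class FragmentSet:
    """Ordered oriented squares and their resampled image fragments.

    Fragment axes: columns run along the outward normal (lesion interior on
    the LEFT half), rows along the boundary tangent.
    """

    squares: list[BoundarySquare]
    fragments: list[np.ndarray]
    spacing: float
    order_origin: str = "max-radius-clockwise"


@dataclass
class S4Image:
    """Reassembled boundary image: fragments concatenated left to right."""

    pixels: np.ndarray
    provenance: list[int]  # fragment order indices
    spacing: float


# ---------------------------------------------------------------------------
# Transition-zone localization
# ---------------------------------------------------------------------------

def _resample_closed(vertices: np.ndarray, step_px: float):
    """Resample a closed polyline at uniform arclength; returns pts, tangents."""
    pts = np.vstack([vertices, vertices[:1]])
    seg = np.hypot(*np.diff(pts, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n = max(int(np.floor(total / step_px)), 8)
    si = np.linspace(0.0, total, n, endpoint=False)
    rr = np.interp(si, s, pts[:, 0])
    cc = np.interp(si, s, pts[:, 1])
    out = np.column_stack([rr, cc])
    nxt = np.roll(out, -1, axis=0)
    prv = np.roll(out, 1, axis=0)
    tang = nxt - prv
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    return out, tang


def _first_crossing(s, v, level, rising=True):
    """Linear-interpolated first crossing of ``level`` in a sampled profile."""
    dv = v - level
    sign = dv > 0
    idx = np.nonzero(sign[1:] != sign[:-1])[0]
    for i in idx:
        if rising and v[i + 1] > v[i] or (not rising and v[i + 1] < v[i]):
            frac = (level - v[i]) / (v[i + 1] - v[i])
            return s[i] + frac * (s[i + 1] - s[i])
    return None


def locate_transition(
    image: Radiograph,
    contour: LesionContour,
    probe_len_mm: float = 2.0,
    step_mm: float = 0.15,
    smooth_sigma_px: float = 1.0,
    min_contrast: float = 5.0,
    max_invalid_frac: float = 0.2,
) -> TransitionBand:
    """Localize the intensity transition zone along the lesion boundary.

    For each arclength sample of the contour, the gray-level profile along
    the outward normal (probe of length ``probe_len_mm``) is measured on a
    lightly smoothed image; the centerline point is the 50% crossing between
    the inner and outer plateau levels and the local width is the 10%->90%
    rise distance, corrected in quadrature for the measurement blur (so a
    hard step reports one pixel-spacing quantum).  Profiles without a
    monotone crossing are invalid; more than ``max_invalid_frac`` of them
    raises :class:`TransitionError`, otherwise they are filled in by
    circular interpolation from their neighbours.
    """
    sp = image.spacing
    img = gaussian_filter(image.pixels, smooth_sigma_px) if smooth_sigma_px > 0 else image.pixels
    pts, tang = _resample_closed(contour.vertices, step_mm / sp)
    # outward normal: rotate tangent; pick the sign pointing out of the lesion
    normals = np.column_stack([-tang[:, 1], tang[:, 0]])
    filled = fill_contour(contour, image.shape)
    test = np.clip(np.round(pts + 3.0 * normals), 0,
                   np.array(image.shape) - 1).astype(int)
    inside = filled[test[:, 0], test[:, 1]]
    normals[inside] *= -1.0

    half = probe_len_mm / 2.0 / sp  # px
    m = int(max(2 * round(half / 0.25) + 1, 41))
    svals = np.linspace(-half, half, m)
    coords_r = pts[:, 0][:, None] + svals[None, :] * normals[:, 0][:, None]
    coords_c = pts[:, 1][:, None] + svals[None, :] * normals[:, 1][:, None]
    coords_r = np.clip(coords_r, 0, image.shape[0] - 1)
    coords_c = np.clip(coords_c, 0, image.shape[1] - 1)
    profiles = map_coordinates(
        img, np.stack([coords_r.ravel(), coords_c.ravel()]), order=1
    ).reshape(len(pts), m)

    k = max(m // 6, 2)
    centers = np.full(len(pts), np.nan)
    widths = np.full(len(pts), np.nan)
    s10 = np.full(len(pts), np.nan)
    s90 = np.full(len(pts), np.nan)
    for i, prof in enumerate(profiles):
        lo = prof[:k].mean()
        hi = prof[-k:].mean()
        if hi - lo < min_contrast:
            continue
        v50 = lo + 0.5 * (hi - lo)
        c50 = _first_crossing(svals, prof, v50, rising=True)
        if c50 is None:
            continue
        v10 = lo + 0.1 * (hi - lo)
        v90 = lo + 0.9 * (hi - lo)
        left = svals <= c50
        right = svals >= c50
        c10 = _first_crossing(svals[left][::-1], prof[left][::-1], v10, rising=False)
        c90 = _first_crossing(svals[right], prof[right], v90, rising=True)
        if c10 is None or c90 is None or c90 <= c10:
            continue
        centers[i] = c50
        s10[i], s90[i] = c10, c90
        widths[i] = (c90 - c10) * sp

    invalid = np.isnan(centers)
    if invalid.mean() > max_invalid_frac:
        raise TransitionError(
            f"no monotone transition at {invalid.mean():.0%} of boundary samples "
            f"(> {max_invalid_frac:.0%})"
        )
    if invalid.any():
        good = np.nonzero(~invalid)[0]
        idxs = np.arange(len(pts))
        for arr in (centers, widths, s10, s90):
            # circular nearest-neighbour interpolation over arclength index
            arr[invalid] = np.interp(
                idxs[invalid], good, arr[good], period=len(pts)
            )

    # blur correction: measured 10-90 width of a hard step is ~2.563*sigma_eff
    blur_w = 2.5631 * np.hypot(smooth_sigma_px, 0.5) * sp
    widths = np.sqrt(np.maximum(widths**2 - blur_w**2, sp**2))

    centerline = pts + centers[:, None] * normals
    band_mask = np.zeros(image.shape, dtype=bool)
    for i in range(len(pts)):
        seg = np.linspace(s10[i], s90[i], max(int((s90[i] - s10[i]) / 0.5) + 2, 2))
        rc = np.round(pts[i] + seg[:, None] * normals[i]).astype(int)
        rc = rc[(rc[:, 0] >= 0) & (rc[:, 0] < image.shape[0])
                & (rc[:, 1] >= 0) & (rc[:, 1] < image.shape[1])]
        band_mask[rc[:, 0], rc[:, 1]] = True
    from scipy.ndimage import binary_closing

    band_mask = binary_closing(band_mask, np.ones((3, 3)))

    return TransitionBand(centerline, normals, widths, band_mask, sp)


# ---------------------------------------------------------------------------
# Square tiling
# ---------------------------------------------------------------------------

class _ClosedCurve:
    """Arclength-parametrized closed curve through the centerline points."""

    def __init__(self, centerline: np.ndarray, spacing: float):
        pts = np.vstack([centerline, centerline[:1]])
        seg = np.hypot(*np.diff(pts, axis=0).T) * spacing
        self.s = np.concatenate([[0.0], np.cumsum(seg)])  # mm
        self.total = float(self.s[-1])
        self.pts = pts  # px
        self.spacing = spacing

    def point(self, s_mm: float) -> np.ndarray:
        s = np.mod(s_mm, self.total)
        r = np.interp(s, self.s, self.pts[:, 0])
        c = np.interp(s, self.s, self.pts[:, 1])
        return np.array([r, c])

    def tangent(self, s_mm: float, h_mm: float = 0.5) -> np.ndarray:
        a = self.point(s_mm - h_mm)
        b = self.point(s_mm + h_mm)
        t = b - a
        nrm = np.linalg.norm(t)
        if nrm < 1e-12:
            raise TilingError("degenerate centerline tangent")
        return t / nrm

    def max_deviation(self, s0: float, s1: float, n: int = 11) -> float:
        """Max distance (mm) of the arc [s0, s1] from its chord line."""
        a = self.point(s0) * self.spacing
        b = self.point(s1) * self.spacing
        chord = b - a
        nrm = np.linalg.norm(chord)
        if nrm < 1e-12:
            return 0.0
        u = chord / nrm
        dev = 0.0
        for s in np.linspace(s0, s1, n):
            p = self.point(s) * self.spacing - a
            dev = max(dev, abs(p[0] * u[1] - p[1] * u[0]))
        return dev


def _square_at(curve: _ClosedCurve, band: TransitionBand, s_mm: float,
               side_mm: float, parallel_tol_mm: float = 0.2) -> BoundarySquare:
    center = curve.point(s_mm)
    tang = curve.tangent(s_mm)
    # enforce "parallel to the side": if the local arc bows away from the
    # tangent line by more than the tolerance, use the secant direction
    if curve.max_deviation(s_mm - side_mm / 2, s_mm + side_mm / 2) > parallel_tol_mm:
        a = curve.point(s_mm - side_mm / 2)
        b = curve.point(s_mm + side_mm / 2)
        tang = (b - a) / np.linalg.norm(b - a)
    # outward normal: interpolate from the band normals (nearest centerline pt)
    d2 = np.sum((band.centerline - center) ** 2, axis=1)
    n_ref = band.normals[np.argmin(d2)]
    normal = np.array([-tang[1], tang[0]])
    if normal @ n_ref < 0:
        normal = -normal
    angle = float(np.arctan2(tang[0], tang[1]))  # in (x=col, y=row) axes
    return BoundarySquare(center, angle, side_mm, tang, normal)


def _chord_advance(curve: _ClosedCurve, s: float, side_mm: float) -> float:
    """Arc advance from s whose straight-line chord equals one square side."""

    def chord(adv: float) -> float:
        a = curve.point(s) * curve.spacing
        b = curve.point(s + adv) * curve.spacing
        return float(np.linalg.norm(b - a))

    lo, hi = 0.5 * side_mm, 2.0 * side_mm
    while chord(hi) < side_mm and hi < 4.0 * side_mm:
        hi += side_mm
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if chord(mid) < side_mm:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def tile_boundary(
    band: TransitionBand,
    side_mm: float = 1.0,
    closure: str = "distribute",
) -> list[BoundarySquare]:
    """Tile the transition-zone centerline with touching, non-overlapping squares.

    Greedy arc-length march starting at the centerline point farthest from
    the centroid (a rotation-equivariant origin) and proceeding clockwise on
    screen: each square is centered on the centerline
    with a side parallel to the local tangent, and the next center is exactly
    one chord of ``side_mm`` further along, so consecutive squares meet at
    the centerline (gap below the pixel quantum; residual corner overlap on
    the concave side stays below a half-pixel sliver at lesion-scale
    curvature).

    The closure mismatch (the march does not generally divide the perimeter
    evenly) is resolved per ``closure``:

    * ``"distribute"`` (default): the leftover arc is spread evenly over all
      advances, so the tiling closes without a gap; chords grow by at most a
      few hundredths of a millimetre.
    * ``"drop"``: the final square is dropped when it would overlap the
      first one, leaving up to one square side of boundary uncovered.
    """
    spacing = band.spacing
    centerline = band.centerline
    # orient the march clockwise on screen (positive shoelace in (col,row))
    x, y = centerline[:, 1], centerline[:, 0]
    shoelace = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if shoelace < 0:
        centerline = centerline[::-1]
    curve = _ClosedCurve(centerline, spacing)
    if curve.total < side_mm:
        raise TilingError(
            f"centerline arc length {curve.total:.2f} mm is shorter than one "
            f"{side_mm} mm square"
        )

    # start at the centerline point farthest from the centroid: an origin
    # intrinsic to the lesion geometry, so the tiling (and the fragment
    # order) is equivariant under rotation of the whole radiograph --
    # an image-frame origin such as "topmost" would break the S4
    # rotation-invariance property the method is built for
    centroid = centerline.mean(axis=0)
    start_idx = int(np.argmax(np.sum((centerline - centroid) ** 2, axis=1)))
    s_start = float(curve.s[start_idx])

    # greedy chord march
    steps: list[float] = []
    s = s_start
    max_squares = int(np.ceil(curve.total / side_mm)) + 4
    while True:
        adv = _chord_advance(curve, s, side_mm)
        if (s + adv) - s_start > curve.total - 0.5 * side_mm:
            break
        steps.append(adv)
        s += adv
        if len(steps) > max_squares:
            raise TilingError("tiling failed to close (runaway march)")

    if not steps:
        return [_square_at(curve, band, s_start, side_mm)]

    def build(step_list):
        positions = [s_start]
        pos = s_start
        for a in step_list:
            pos += a
            positions.append(pos)
        return [_square_at(curve, band, p, side_mm) for p in positions]

    if closure == "distribute":
        # n squares use n advances around the closed loop; the greedy march
        # produced n-1 of them plus an implicit closing advance.  Rescale all
        # advances by a common factor so they sum exactly to the perimeter.
        # Rescaling down (more squares) deepens the corner overlaps while
        # rescaling up (fewer squares) opens centerline gaps, so both
        # candidates are built and the one meeting the half-pixel overlap
        # and gap tolerances (or coming closest) wins.
        tol_overlap = 0.5 * spacing * side_mm  # half-pixel sliver area
        candidates = []
        for drop in (0, 1):
            use = steps[: len(steps) - drop]
            if not use:
                continue
            factor = curve.total / (sum(use) + float(np.mean(use)))
            cand = build([a * factor for a in use])
            polys = [sq.polygon_mm(spacing) for sq in cand]
            max_ov = max(
                polys[i].intersection(polys[(i + 1) % len(polys)]).area
                for i in range(len(polys))
            )
            gap = max(0.0, factor * side_mm - side_mm)
            ok = max_ov <= tol_overlap and gap <= 0.5 * spacing
            candidates.append((not ok, max(max_ov - tol_overlap, 0.0)
                               + max(gap - 0.5 * spacing, 0.0), drop, cand))
        candidates.sort(key=lambda c: (c[0], c[1], c[2]))
        return candidates[0][3]

    squares = build(steps)
    if closure == "drop" and len(squares) > 1:
        half_px_sliver = 0.5 * spacing * side_mm
        if (
            squares[-1].polygon_mm(spacing)
            .intersection(squares[0].polygon_mm(spacing)).area
            > half_px_sliver
        ):
            squares = squares[:-1]
    return squares


def extract_fragments(
    image: Radiograph, squares: list[BoundarySquare], spacing: float | None = None
) -> FragmentSet:
    """Resample each oriented square to a side_px x side_px fragment.

    Bilinear interpolation on a grid aligned with the square: fragment
    columns run along the outward normal so the lesion interior lands on the
    left half.  Raises :class:`ExtractionError` (naming the square index)
    when a square exceeds the image bounds.
    """
    sp = spacing if spacing is not None else image.spacing
    if not squares:
        raise ExtractionError("no squares to extract")
    side_px = int(round(squares[0].side_mm / sp))
    offs = (np.arange(side_px) - (side_px - 1) / 2.0) * (squares[0].side_mm / side_px) / sp
    frags = []
    h, w = image.shape
    for idx, sq in enumerate(squares):
        rr = (sq.center[0]
              + offs[:, None] * sq.tangent[0]  # rows: along tangent
              + offs[None, :] * sq.normal[0])  # cols: along outward normal
        cc = (sq.center[1]
              + offs[:, None] * sq.tangent[1]
              + offs[None, :] * sq.normal[1])
        if rr.min() < -0.5 or rr.max() > h - 0.5 or cc.min() < -0.5 or cc.max() > w - 0.5:
            raise ExtractionError(f"square {idx} exceeds the image bounds")
        frag = map_coordinates(image.pixels, np.stack([rr.ravel(), cc.ravel()]),
                               order=1, mode="nearest").reshape(side_px, side_px)
        frags.append(frag)
    return FragmentSet(list(squares), frags, sp)


def reassemble(frag_set: FragmentSet) -> S4Image:
    """Concatenate fragments left-to-right into the striped S4 image."""
    frags = frag_set.fragments
    if not frags:
        raise AssemblyError("no fragments to assemble")
    shape0 = frags[0].shape
    if any(f.shape != shape0 for f in frags):
        raise AssemblyError("fragments have mixed sizes")
    pixels = np.hstack(frags)
    return S4Image(pixels, list(range(len(frags))), frag_set.spacing)


def fragment_pipeline(
    image: Radiograph,
    contour: LesionContour,
    side_mm: float = 1.0,
    **transition_kwargs,
) -> tuple[TransitionBand, FragmentSet, S4Image]:
    """Convenience chain: locate transition -> tile -> extract -> reassemble."""
    band = locate_transition(image, contour, **transition_kwargs)
    squares = tile_boundary(band, side_mm=side_mm)
    frag_set = extract_fragments(image, squares)
    return band, frag_set, reassemble(frag_set)


def tiling_to_json(squares: list[BoundarySquare]) -> list[dict]:
    """Tiling export: centers, angles and order as JSON-ready dicts."""
    return [
        {
            "order": i,
            "center_row": float(sq.center[0]),
            "center_col": float(sq.center[1]),
            "angle_rad": float(sq.angle),
            "side_mm": float(sq.side_mm),
        }
        for i, sq in enumerate(squares)
    ]
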