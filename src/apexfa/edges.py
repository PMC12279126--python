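"""Canny edge detection and ROI construction (S1 interior, S2 extended, S3 annulus).

The lesion contour is recovered from the Canny edge map deterministically:
dilating the edge mask bridges small gaps in the detected edge chain, the
enclosed region containing a user-supplied seed point plays the role of the
operator's click in semi-automatic contouring, and the region boundary is
smoothed with a circular Gaussian after uniform arclength resampling.  ROIs
follow the standard construction: S1 is the lesion
interior clear of the edge (filled contour eroded by an inner margin), S2
extends the interior across the edge (filled contour dilated by an outer
margin) and S3 = S2 minus S1, exactly, pixelwise.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import feature as skfeature
from skimage.draw import polygon2mask
from skimage.morphology import dilation as _dilation, erosion as _erosion, disk

from .image import Radiograph

#: Double-threshold defaults (lower/higher) on the 0-255 gray-level scale.
CANNY_LOW = 35.0
CANNY_HIGH = 50.0
DEFAULT_SIGMA = 1.4  # px, Gaussian smoothing of the Canny chain


class ContourError(RuntimeError):
    """Raised when no closed lesion boundary can be recovered."""


class MarginError(ValueError):
    """Raised when an ROI margin empties or degenerates a mask."""


@dataclass
class EdgeMap:
    """Binary edge mask aligned to its source radiograph."""

    mask: np.ndarray
    spacing: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class LesionContour:
    """Closed lesion boundary as an ordered (row, col) polyline.

    Orientation is normalized counter-clockwise in (x=col, y=row) axes
    (negative shoelace area), i.e. visually counter-clockwise on screen.
    """

    vertices: np.ndarray  # (N, 2) float, not repeating the first point
    closed: bool = True

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("contour vertices must be (N, 2)")

    @property
    def signed_area(self) -> float:
        """Shoelace area in (x=col, y=row) axes; positive = visually clockwise."""
        x = self.vertices[:, 1]
        y = self.vertices[:, 0]
        return 0.5 * float(
            np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        )

    def perimeter(self, spacing: float = 1.0) -> float:
        d = np.diff(np.vstack([self.vertices, self.vertices[:1]]), axis=0)
        return float(np.sum(np.hypot(d[:, 0], d[:, 1]))) * spacing


@dataclass
class RoiMasks:
    """Nested ROI masks: S1 (interior), S2 (extended), S3 = S2 - S1."""

    s1: np.ndarray
    s2: np.ndarray
    s3: np.ndarray
    margins: tuple[float, float]  # (inner_mm, outer_mm)

    def __post_init__(self) -> None:
        self.s1 = np.asarray(self.s1, dtype=bool)
        self.s2 = np.asarray(self.s2, dtype=bool)
        self.s3 = np.asarray(self.s3, dtype=bool)
        if self.s1.shape != self.s2.shape or self.s2.shape != self.s3.shape:
            raise ValueError("ROI masks must share one shape")
        if np.any(self.s1 & ~self.s2):
            raise ValueError("S1 must be a subset of S2")
        if np.any(self.s3 != (self.s2 & ~self.s1)):
            raise ValueError("S3 must equal S2 minus S1 pixelwise")


def canny(
    image: Radiograph,
    sigma: float = DEFAULT_SIGMA,
    low: float = CANNY_LOW,
    high: float = CANNY_HIGH,
) -> EdgeMap:
    """Canny edge detection with gray-level double thresholds.

    Full chain: Gaussian smoothing, Sobel gradients, non-maximum suppression
    and double-threshold hysteresis (weak edges kept only when connected to
    strong edges).  Thresholds are interpreted on the 0-255 scale of 8-bit
    radiographs; deeper inputs are rescaled first.  A constant image yields a
    valid empty edge map.
    """
    if not (low < high):
        raise ValueError("require low < high threshold")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    img = image.to_8bit().pixels
    mask = skfeature.canny(
        img, sigma=sigma, low_threshold=low, high_threshold=high,
        use_quantiles=False,
    )
    return EdgeMap(mask, image.spacing)


def trace_contour(
    edges: EdgeMap,
    seed: tuple[int, int],
    closing_radius_mm: float = 0.3,
    smoothing: float = 2.0,
    n_points: int = 400,
) -> LesionContour:
    """Recover the closed lesion boundary around a seed point.

    Gaps in the edge chain are bridged by dilating the edge mask by the
    gap-closing radius r (connecting breaks up to ~2r; a plain morphological
    closing cannot bridge gaps in one-pixel-wide chains because the thin
    bridge erodes away again).  The enclosed free region containing ``seed``
    is extracted, grown back by the same radius so its boundary lands on the
    edge centerline, then resampled at uniform arclength and smoothed with a
    circular Gaussian of ``smoothing`` pixels.  Raises :class:`ContourError`
    when the seed region is not enclosed (it leaks to the image border).
    """
    mask = edges.mask
    h, w = mask.shape
    r_px = max(int(round(closing_radius_mm / edges.spacing)), 1)
    closed = _dilation(mask, disk(r_px))

    seed = (int(round(seed[0])), int(round(seed[1])))
    if not (0 <= seed[0] < h and 0 <= seed[1] < w):
        raise ContourError(f"seed {seed} outside the image")
    free = ~closed
    if not free[seed]:
        # seed fell on a (closed) edge pixel; look in a small neighborhood
        nb = free[max(seed[0] - 2, 0):seed[0] + 3, max(seed[1] - 2, 0):seed[1] + 3]
        if not nb.any():
            raise ContourError(f"seed {seed} lies on the edge structure")
        off = np.argwhere(nb)[0]
        seed = (max(seed[0] - 2, 0) + off[0], max(seed[1] - 2, 0) + off[1])

    labels, _ = ndimage.label(free)
    region = labels == labels[seed]
    if region[0, :].any() or region[-1, :].any() or region[:, 0].any() or region[:, -1].any():
        raise ContourError(
            "no closed region around the seed after gap closing "
            f"(max gap bridged ~{2 * r_px} px = {2 * r_px * edges.spacing:.2f} mm)"
        )
    region = ndimage.binary_fill_holes(region)
    region = _dilation(region, disk(r_px))  # boundary onto the edge centerline

    from skimage import measure

    contours = measure.find_contours(region.astype(float), 0.5)
    if not contours:
        raise ContourError("region produced no boundary contour")
    boundary = max(contours, key=len)
    if np.allclose(boundary[0], boundary[-1]):
        boundary = boundary[:-1]

    # uniform arclength resampling + circular Gaussian smoothing
    pts = np.vstack([boundary, boundary[:1]])
    seg = np.hypot(*np.diff(pts, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    si = np.linspace(0.0, s[-1], n_points, endpoint=False)
    rr = np.interp(si, s, pts[:, 0])
    cc = np.interp(si, s, pts[:, 1])
    if smoothing > 0 and s[-1] > 0:
        sig = smoothing / (s[-1] / n_points)
        rr = ndimage.gaussian_filter1d(rr, sig, mode="wrap")
        cc = ndimage.gaussian_filter1d(cc, sig, mode="wrap")
    vertices = np.column_stack([rr, cc])

    contour = LesionContour(vertices)
    if contour.signed_area > 0:  # normalize to counter-clockwise on screen
        contour = LesionContour(vertices[::-1])
    return contour


def fill_contour(contour: LesionContour, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize the closed contour interior to a boolean mask."""
    return polygon2mask(shape, contour.vertices)


def build_rois(
    contour: LesionContour,
    shape: tuple[int, int],
    spacing: float,
    inner_margin_mm: float = 0.5,
    outer_margin_mm: float = 0.5,
) -> RoiMasks:
    """Build S1/S2/S3 masks from a lesion contour.

    S1 = filled contour eroded by the inner margin; S2 = filled contour
    dilated by the outer margin; S3 = S2 and not S1.  Raises
    :class:`MarginError` when erosion empties S1.
    """
    if inner_margin_mm < 0 or outer_margin_mm < 0:
        raise ValueError("margins must be >= 0")
    filled = fill_contour(contour, shape)
    if not filled.any():
        raise MarginError("contour encloses no pixels")
    r_in = int(round(inner_margin_mm / spacing))
    r_out = int(round(outer_margin_mm / spacing))
    s1 = _erosion(filled, disk(r_in)) if r_in > 0 else filled.copy()
    s2 = _dilation(filled, disk(r_out)) if r_out > 0 else filled.copy()
    if not s1.any():
        raise MarginError(
            f"inner margin {inner_margin_mm} mm erodes the interior to nothing"
        )
    s3 = s2 & ~s1
    return RoiMasks(s1, s2, s3, margins=(inner_margin_mm, outer_margin_mm))


def export_contour_json(contour: LesionContour) -> list[list[float]]:
    """Contour vertices as a JSON-ready list of [row, col] pairs."""
    return [[float(r), float(c)] for r, c in contour.vertices]


def write_roi_labels(path, rois: RoiMasks) -> None:
    """Write an S-label PNG: 0 background, 1 = S1, 2 = S3."""
    from PIL import Image

    labels = np.zeros(rois.s1.shape, dtype=np.uint8)
    labels[rois.s3] = 2
    labels[rois.s1] = 1
    Image.fromarray(labels).save(path)
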