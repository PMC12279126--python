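"""MaZda-convention texture features over masked ROIs.

Implements the three feature families used for the boundary radiomics
signature: first-order histogram statistics, gray-level co-occurrence
matrices (GLCM) at offsets S(d, theta), and gray-level run-length matrices
(GLRLM).  All second-order features operate on a quantized ROI: intensities
are clipped to mu +/- k*sigma computed over the ROI and binned uniformly to
G gray levels (G = 64, k = 3 by default, the MaZda normalization
convention), which also makes every feature invariant to adding a constant
gray level to the image.

Feature naming follows MaZda so that the S(5,0) contrast discussed for
lesion boundaries maps one-to-one: GLCM features are ``S(d,theta)Stat``
(e.g. ``S(5,0)Contrast``), run-length features ``RL(theta)Stat`` and
histogram features plain (``Mean``, ``Perc50`` ...).  Entropies use the
natural logarithm.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

GLCM_STATS = (
    "AngScMom", "Contrast", "Correlat", "SumOfSqs", "InvDfMom",
    "SumAverg", "SumVarnc", "SumEntrp", "Entropy", "DifVarnc", "DifEntrp",
)
GLRLM_STATS = ("ShrtREmph", "LngREmph", "GLevNonUni", "RLNonUni", "Fraction")
HIST_STATS = (
    "Mean", "Variance", "Skewness", "Kurtosis",
    "Perc01", "Perc10", "Perc50", "Perc90", "Perc99",
)
ANGLES = (0, 45, 90, 135)

#: (d, theta) -> (row, col) pixel offset; theta measured in image coords,
#: theta = 0 horizontal.
def _offset(d: int, theta: int) -> tuple[int, int]:
    return {
        0: (0, d),
        45: (-d, d),
        90: (-d, 0),
        135: (-d, -d),
    }[theta]


class EmptyPairsError(ValueError):
    """Raised when a ROI admits no co-occurring pixel pair at an offset."""


@dataclass
class QuantizedRoi:
    """ROI pixels quantized to integer gray levels in [0, G-1].

    ``levels`` is a full-size integer array with -1 outside the mask.
    """

    levels: np.ndarray
    mask: np.ndarray
    G: int
    normalization: tuple[float, float]  # (mu, sigma) used for clipping

    def __post_init__(self) -> None:
        inside = self.levels[self.mask]
        if inside.size and (inside.min() < 0 or inside.max() >= self.G):
            raise ValueError("quantized levels out of range")


def quantize(image: np.ndarray, roi_mask: np.ndarray, G: int = 64,
             clip_k: float | None = 3.0) -> QuantizedRoi:
    """Clip ROI intensities to mu +/- clip_k*sigma and bin to G levels.

    ``clip_k=None`` disables clipping (min/max binning).  A zero-variance
    ROI maps every pixel to the middle level G//2 (documented degenerate
    case, not an error).
    """
    if G < 2:
        raise ValueError("G must be >= 2")
    mask = np.asarray(roi_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty ROI")
    vals = np.asarray(image, dtype=float)[mask]
    mu, sigma = float(vals.mean()), float(vals.std())
    levels = np.full(mask.shape, -1, dtype=np.int32)
    if sigma == 0.0:
        levels[mask] = G // 2
        return QuantizedRoi(levels, mask, G, (mu, sigma))
    if clip_k is None:
        lo, hi = float(vals.min()), float(vals.max())
    else:
        lo, hi = mu - clip_k * sigma, mu + clip_k * sigma
    clipped = np.clip(vals, lo, hi)
    binned = np.floor((clipped - lo) / (hi - lo) * G).astype(np.int32)
    levels[mask] = np.clip(binned, 0, G - 1)
    return QuantizedRoi(levels, mask, G, (mu, sigma))


def glcm(q: QuantizedRoi, d: int, theta: int) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix at offset S(d, theta).

    Both pixels of a pair must lie inside the ROI mask; pairs are counted in
    both directions and the matrix normalized to sum 1.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    if theta not in ANGLES:
        raise ValueError(f"theta must be one of {ANGLES}")
    dr, dc = _offset(d, theta)
    lv, mask = q.levels, q.mask
    h, w = mask.shape
    r0s, r0e = max(0, -dr), min(h, h - dr)
    c0s, c0e = max(0, -dc), min(w, w - dc)
    a = lv[r0s:r0e, c0s:c0e]
    b = lv[r0s + dr:r0e + dr, c0s + dc:c0e + dc]
    valid = mask[r0s:r0e, c0s:c0e] & mask[r0s + dr:r0e + dr, c0s + dc:c0e + dc]
    if not valid.any():
        raise EmptyPairsError(f"no valid pixel pairs at S({d},{theta})")
    i = a[valid].ravel()
    j = b[valid].ravel()
    P = np.zeros((q.G, q.G))
    np.add.at(P, (i, j), 1.0)
    np.add.at(P, (j, i), 1.0)
    return P / P.sum()


def glcm_features(P: np.ndarray, prefix: str = "") -> dict[str, float]:
    """The 11 MaZda GLCM statistics of a normalized co-occurrence matrix."""
    if not np.isclose(P.sum(), 1.0, atol=1e-8):
        raise ValueError("co-occurrence matrix must be normalized to sum 1")
    G = P.shape[0]
    i = np.arange(G)[:, None]
    j = np.arange(G)[None, :]
    px = P.sum(axis=1)
    mu_x = float((np.arange(G) * px).sum())
    var_x = float(((np.arange(G) - mu_x) ** 2 * px).sum())

    # p_{x+y}(k), k = 0..2G-2 and p_{x-y}(k), k = 0..G-1
    psum = np.zeros(2 * G - 1)
    pdiff = np.zeros(G)
    for k in range(G):
        psum[k: k + G] += P[k]
        np.add.at(pdiff, np.abs(np.arange(G) - k), P[k])

    def ent(p):
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    contrast = float((((i - j) ** 2) * P).sum())
    if var_x > 0:
        correlat = float((((i - mu_x) * (j - mu_x) * P).sum()) / var_x)
    else:
        correlat = 0.0  # degenerate single-level matrix
    ks = np.arange(2 * G - 1)
    sum_avg = float((ks * psum).sum())
    kd = np.arange(G)
    dif_avg = float((kd * pdiff).sum())
    feats = {
        "AngScMom": float((P**2).sum()),
        "Contrast": contrast,
        "Correlat": correlat,
        "SumOfSqs": var_x,
        "InvDfMom": float((P / (1.0 + (i - j) ** 2)).sum()),
        "SumAverg": sum_avg,
        "SumVarnc": float(((ks - sum_avg) ** 2 * psum).sum()),
        "SumEntrp": ent(psum),
        "Entropy": ent(P.ravel()),
        "DifVarnc": float(((kd - dif_avg) ** 2 * pdiff).sum()),
        "DifEntrp": ent(pdiff),
    }
    return {prefix + k: v for k, v in feats.items()}


def _scan_runs(flat: np.ndarray):
    """Maximal constant runs of a 1-D level sequence; -1 marks separators."""
    if len(flat) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    boundaries = np.nonzero(np.diff(flat) != 0)[0]
    starts = np.concatenate([[0], boundaries + 1])
    ends = np.concatenate([boundaries, [len(flat) - 1]])
    vals = flat[starts]
    keep = vals >= 0
    return vals[keep], (ends - starts + 1)[keep]


def _runs_along(levels: np.ndarray, mask: np.ndarray, theta: int):
    """(levels, lengths) of maximal constant runs inside the mask along theta.

    Lines are laid end to end with -1 separators so one vectorized scan
    handles the whole ROI; runs never cross a line or mask boundary.
    """
    rows = np.any(mask, axis=1).nonzero()[0]
    cols = np.any(mask, axis=0).nonzero()[0]
    sub = np.where(mask, levels, -1)[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
    h, w = sub.shape
    sep = np.full((h, 1), -1, dtype=sub.dtype)
    if theta == 0:
        flat = np.hstack([sub, sep]).ravel()
    elif theta == 90:
        flat = np.hstack([sub.T, np.full((w, 1), -1, dtype=sub.dtype)]).ravel()
    else:
        src = sub[::-1] if theta == 45 else sub  # anti-diagonals for 45 deg
        parts = []
        for k in range(-(h - 1), w):
            parts.append(np.diagonal(src, offset=k))
            parts.append([-1])
        flat = np.concatenate(parts)
    return _scan_runs(np.asarray(flat))


def glrlm_features(q: QuantizedRoi, theta: int, prefix: str = "") -> dict[str, float]:
    """Run-length features over maximal constant-level runs inside the ROI."""
    if theta not in ANGLES:
        raise ValueError(f"theta must be one of {ANGLES}")
    if not q.mask.any():
        raise ValueError("empty ROI")
    levels, lengths = _runs_along(q.levels, q.mask, theta)
    lengths = lengths.astype(float)
    n_runs = len(lengths)
    n_pix = int(q.mask.sum())
    gl_counts = np.bincount(levels, minlength=q.G).astype(float)
    rl_counts = np.bincount(lengths.astype(int))[1:].astype(float)
    feats = {
        "ShrtREmph": float((1.0 / lengths**2).sum() / n_runs),
        "LngREmph": float((lengths**2).sum() / n_runs),
        "GLevNonUni": float((gl_counts**2).sum() / n_runs),
        "RLNonUni": float((rl_counts**2).sum() / n_runs),
        "Fraction": n_runs / n_pix,
    }
    return {prefix + k: v for k, v in feats.items()}


def histogram_features(image: np.ndarray, roi_mask: np.ndarray,
                       prefix: str = "") -> dict[str, float]:
    """First-order statistics of the raw (unquantized) ROI intensities."""
    mask = np.asarray(roi_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty ROI")
    v = np.asarray(image, dtype=float)[mask]
    var = float(v.var())
    feats = {
        "Mean": float(v.mean()),
        "Variance": var,
        "Skewness": float(sps.skew(v)) if var > 0 else 0.0,
        "Kurtosis": float(sps.kurtosis(v)) if var > 0 else 0.0,
    }
    for p in (1, 10, 50, 90, 99):
        feats[f"Perc{p:02d}"] = float(np.percentile(v, p))
    return {prefix + k: v for k, v in feats.items()}


def roi_features(image: np.ndarray, mask: np.ndarray, prefix: str,
                 d_values=(1, 2, 3, 4, 5), G: int = 64,
                 clip_k: float | None = 3.0) -> dict[str, float]:
    """All texture families for one ROI; failures become NaN with a warning."""
    feats: dict[str, float] = {}
    feats.update(histogram_features(image, mask, prefix=prefix))
    q = quantize(image, mask, G=G, clip_k=clip_k)
    for d in d_values:
        for theta in ANGLES:
            name = f"{prefix}S({d},{theta})"
            try:
                feats.update(glcm_features(glcm(q, d, theta), prefix=name))
            except EmptyPairsError as exc:
                log.warning("%s: %s", name, exc)
                feats.update({name + s: np.nan for s in GLCM_STATS})
    for theta in ANGLES:
        name = f"{prefix}RL({theta})"
        feats.update(glrlm_features(q, theta, prefix=name))
    return feats


def extract_all(image, rois, s4, d_values=(1, 2, 3, 4, 5), G: int = 64,
                clip_k: float | None = 3.0) -> pd.Series:
    """One named feature row for a patient: S1/S2/S3 ROIs plus the S4 image.

    ``image`` may be a Radiograph or an array; ``rois`` carries the s1/s2/s3
    masks and ``s4`` the reassembled boundary image.
    """
    pixels = getattr(image, "pixels", image)
    s4_pixels = getattr(s4, "pixels", s4)
    feats: dict[str, float] = {}
    for name, mask in (("S1_", rois.s1), ("S2_", rois.s2), ("S3_", rois.s3)):
        feats.update(roi_features(pixels, mask, name, d_values, G, clip_k))
    feats.update(
        roi_features(s4_pixels, np.ones(s4_pixels.shape, dtype=bool), "S4_",
                     d_values, G, clip_k)
    )
    return pd.Series(feats)


def feature_schema(d_values=(1, 2, 3, 4, 5)) -> list[dict]:
    """JSON-ready schema: name, ROI, family and offset of every feature."""
    schema = []
    for roi in ("S1", "S2", "S3", "S4"):
        for stat in HIST_STATS:
            schema.append({"name": f"{roi}_{stat}", "roi": roi,
                           "family": "histogram", "d": None, "theta": None})
        for d in d_values:
            for theta in ANGLES:
                for stat in GLCM_STATS:
                    schema.append({
                        "name": f"{roi}_S({d},{theta}){stat}", "roi": roi,
                        "family": "glcm", "d": d, "theta": theta,
                    })
        for theta in ANGLES:
            for stat in GLRLM_STATS:
                schema.append({"name": f"{roi}_RL({theta}){stat}", "roi": roi,
                               "family": "glrlm", "d": None, "theta": theta})
    return schema
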