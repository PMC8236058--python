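"""Cell-intrinsic features: shape/size, color statistics, Haralick texture.

Shape descriptors come from the moment-equivalent ellipse of a binary mask:
axis lengths are ``4 * sqrt(eigenvalue)`` of the second central moment matrix,
so a filled disk of radius r yields major = minor = 2r. Texture is measured on
a gray projection of the color image (first principal component of the channel
covariance) through the 13 classic gray-level co-occurrence statistics,
accumulated only over pixel pairs that both fall inside the region of interest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .catalog import (
    COLOR_NAMES,
    HARALICK_NAMES,
    INTRINSIC_NAMES,
    SHAPE_NAMES,
)
from .io import CalibratedImage

if TYPE_CHECKING:  # pragma: no cover
    from .delineate import CellRecord

__all__ = [
    "EllipseFit",
    "GrayImage",
    "HaralickParams",
    "fit_ellipse",
    "ellipse_from_points",
    "shape_size_features",
    "pca_gray",
    "color_features",
    "haralick_features",
    "compute_intrinsic_features",
]

#: Luminance weights used only to fix the sign of the PCA projection.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class EllipseFit:
    """Moment-equivalent ellipse: full axis lengths (µm), orientation of the
    major axis in [0, pi) measured in (x=col, y=row) coordinates."""

    major_um: float
    minor_um: float
    orientation_rad: float

    @property
    def elongation(self) -> float:
        return self.major_um / self.minor_um


@dataclass
class GrayImage:
    """Single-channel raster in [0, 255] with the unit-norm channel weights
    that produced it."""

    pixels: np.ndarray
    weights: np.ndarray


@dataclass
class HaralickParams:
    n_gray_levels: int = 32
    #: (row, col) displacement vectors; the classic 4 directions at distance 1.
    offsets: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.n_gray_levels < 2:
            raise ValueError("n_gray_levels must be >= 2")


def _moment_ellipse(xy: np.ndarray, minor_floor: float = 0.0) -> tuple[float, float, float]:
    """Axes (full lengths) and orientation from a point cloud's second central
    moments. ``xy`` is (n, 2) in (x, y)."""
    mu = xy.mean(axis=0)
    d = xy - mu
    cov = d.T @ d / len(xy)  # population second central moments
    evals, evecs = np.linalg.eigh(cov)  # ascending
    evals = np.clip(evals, 0.0, None)
    major = 4.0 * np.sqrt(evals[1])
    minor = 4.0 * np.sqrt(evals[0])
    minor = max(minor, minor_floor)
    major = max(major, minor)
    vx, vy = evecs[:, 1]
    theta = np.arctan2(vy, vx) % np.pi
    if major == minor:
        theta = 0.0  # orientation undefined for isotropic masks
    return float(major), float(minor), float(theta)


def fit_ellipse(region_mask: np.ndarray, calibration: float = 1.0) -> EllipseFit:
    """Fit the moment-equivalent ellipse to a binary mask.

    Degenerate masks (single pixel, or collinear pixels) get a minor-axis
    floor of 1 px so elongation stays finite.
    """
    rows, cols = np.nonzero(region_mask)
    if rows.size == 0:
        raise ValueError("cannot fit an ellipse to an empty mask")
    xy = np.column_stack([cols.astype(float), rows.astype(float)])
    major, minor, theta = _moment_ellipse(xy, minor_floor=1.0)
    major = max(major, 1.0)
    return EllipseFit(major * calibration, minor * calibration, theta)


def ellipse_from_points(points_um: np.ndarray) -> EllipseFit:
    """Moment ellipse of a set of (x, y) points in µm (e.g. neighborhood
    centroids). A tiny minor-axis floor keeps collinear sets finite."""
    pts = np.asarray(points_um, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 points")
    major, minor, theta = _moment_ellipse(pts, minor_floor=1e-9)
    major = max(major, 1e-9)
    return EllipseFit(major, minor, theta)


def shape_size_features(rec: "CellRecord") -> dict[str, float]:
    """The 9 shape/size features of one cell record.

    ``area_ratio`` is cytoplasm area over nucleus area (cytoplasm = cell minus
    nucleus), so a cell identical to its nucleus scores 0.
    """
    if rec.nucleus_area_um2 <= 0:
        raise ValueError("nucleus area must be positive")
    vals = {
        "nucleus_major_um": rec.nucleus_ellipse.major_um,
        "nucleus_minor_um": rec.nucleus_ellipse.minor_um,
        "nucleus_elongation": rec.nucleus_ellipse.elongation,
        "nucleus_area_um2": rec.nucleus_area_um2,
        "cell_major_um": rec.cell_ellipse.major_um,
        "cell_minor_um": rec.cell_ellipse.minor_um,
        "cell_elongation": rec.cell_ellipse.elongation,
        "cell_area_um2": rec.cell_area_um2,
        "area_ratio": (rec.cell_area_um2 - rec.nucleus_area_um2)
        / rec.nucleus_area_um2,
    }
    assert tuple(vals) == SHAPE_NAMES
    return vals


def pca_gray(img: CalibratedImage) -> GrayImage:
    """Project a color image onto the first principal component of its channel
    covariance, sign-aligned with luminance, min–max rescaled to [0, 255].

    Single-channel images pass through (rescaled); zero-variance images fall
    back to a constant zero raster with weights (1,1,1)/sqrt(3).
    """
    px = img.pixels.astype(float)
    if img.n_channels == 1:
        lo, hi = px.min(), px.max()
        if hi > lo:
            px = (px - lo) / (hi - lo) * 255.0
        else:
            px = np.zeros_like(px)
        return GrayImage(px, np.array([1.0, 0.0, 0.0]))
    flat = px.reshape(-1, 3)
    cov = np.cov(flat, rowvar=False)
    if not np.isfinite(cov).all() or np.allclose(cov, 0):
        return GrayImage(
            np.zeros(px.shape[:2]), np.full(3, 1.0 / np.sqrt(3.0))
        )
    evals, evecs = np.linalg.eigh(cov)
    w = evecs[:, np.argmax(evals)]
    if w @ _LUMA < 0:
        w = -w
    proj = flat @ w
    lo, hi = proj.min(), proj.max()
    if hi > lo:
        proj = (proj - lo) / (hi - lo) * 255.0
    else:
        proj = np.zeros_like(proj)
    return GrayImage(proj.reshape(px.shape[:2]), w)


def color_features(
    img: CalibratedImage,
    nucleus_mask: np.ndarray,
    cytoplasm_mask: np.ndarray,
    fill: float = 0.0,
) -> dict[str, float]:
    """Mean and population standard deviation of each channel over the nucleus
    and the cytoplasm (12 values).

    Single-channel images populate the c0 slots; the remaining channel slots
    keep the default fill so the descriptor length is unchanged. An empty
    cytoplasm fills its 6 slots.
    """
    if nucleus_mask.shape != cytoplasm_mask.shape:
        raise ValueError("mask shapes differ")
    if np.logical_and(nucleus_mask, cytoplasm_mask).any():
        raise ValueError("nucleus and cytoplasm masks overlap")
    px = img.pixels.astype(float)
    nch = img.n_channels
    vals: dict[str, float] = {}
    for region, mask in (("nucleus", nucleus_mask), ("cytoplasm", cytoplasm_mask)):
        for ch in range(3):
            mkey, skey = f"{region}_mean_c{ch}", f"{region}_sd_c{ch}"
            if ch >= nch or not mask.any():
                vals[mkey] = fill
                vals[skey] = fill
                continue
            data = px[mask] if nch == 1 else px[..., ch][mask]
            vals[mkey] = float(data.mean())
            vals[skey] = float(data.std())  # population sd
    assert tuple(vals) == COLOR_NAMES[:6] + COLOR_NAMES[6:]
    return vals


def _masked_glcm(
    gray: np.ndarray, mask: np.ndarray, params: HaralickParams
) -> np.ndarray:
    """Normalized co-occurrence matrix over pixel pairs both inside the mask.

    Gray values are quantized to ``n_gray_levels`` using the region's own
    min–max range (local contrast stretch); a flat region maps to level 0.
    """
    levels = params.n_gray_levels
    vals = gray[mask]
    lo, hi = vals.min(), vals.max()
    q = np.zeros(gray.shape, dtype=np.intp)
    if hi > lo:
        q[mask] = np.minimum(
            ((gray[mask] - lo) / (hi - lo) * levels).astype(np.intp), levels - 1
        )
    glcm = np.zeros((levels, levels), dtype=float)
    h, w = mask.shape
    for dr, dc in params.offsets:
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        m = mask[r0:r1, c0:c1] & mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        a = q[r0:r1, c0:c1][m]
        b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc][m]
        np.add.at(glcm, (a, b), 1.0)
        if params.symmetric:
            np.add.at(glcm, (b, a), 1.0)
    total = glcm.sum()
    if total > 0:
        glcm /= total
    return glcm


def _xlogx(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz])
    return out


def haralick_statistics(glcm: np.ndarray) -> dict[str, float]:
    """The 13 classic Haralick statistics of a normalized GLCM.

    Degenerate single-level regions give ASM 1, entropy 0, contrast 0 and
    correlation 0 (the marginal variance vanishes).
    """
    levels = glcm.shape[0]
    i = np.arange(levels, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = glcm.sum(axis=1)
    py = glcm.sum(axis=0)
    mu_x = float(i @ px)
    mu_y = float(i @ py)
    var_x = float(((i - mu_x) ** 2) @ px)
    var_y = float(((i - mu_y) ** 2) @ py)
    sd_x, sd_y = np.sqrt(var_x), np.sqrt(var_y)

    asm = float((glcm**2).sum())
    contrast = float(((ii - jj) ** 2 * glcm).sum())
    if sd_x > 0 and sd_y > 0:
        correlation = float(((ii * jj * glcm).sum() - mu_x * mu_y) / (sd_x * sd_y))
    else:
        correlation = 0.0
    variance = float((((ii - mu_x) ** 2) * glcm).sum())
    idm = float((glcm / (1.0 + (ii - jj) ** 2)).sum())

    # Sum and difference marginal distributions.
    p_sum = np.zeros(2 * levels - 1)
    p_diff = np.zeros(levels)
    np.add.at(p_sum, (ii + jj).astype(int).ravel(), glcm.ravel())
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), glcm.ravel())
    k_sum = np.arange(2 * levels - 1, dtype=float)
    k_diff = np.arange(levels, dtype=float)
    sum_average = float(k_sum @ p_sum)
    sum_variance = float(((k_sum - sum_average) ** 2) @ p_sum)
    sum_entropy = float(-_xlogx(p_sum).sum())
    entropy = float(-_xlogx(glcm).sum())
    diff_mean = float(k_diff @ p_diff)
    difference_variance = float(((k_diff - diff_mean) ** 2) @ p_diff)
    difference_entropy = float(-_xlogx(p_diff).sum())

    # Information measures of correlation.
    hx = float(-_xlogx(px).sum())
    hy = float(-_xlogx(py).sum())
    pxy = np.outer(px, py)
    nz = (glcm > 0) & (pxy > 0)
    hxy1 = float(-(glcm[nz] * np.log(pxy[nz])).sum())
    hxy2 = float(-_xlogx(pxy).sum())
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    return {
        "asm": asm,
        "contrast": contrast,
        "correlation": correlation,
        "variance": variance,
        "idm": idm,
        "sum_average": sum_average,
        "sum_variance": sum_variance,
        "sum_entropy": sum_entropy,
        "entropy": entropy,
        "difference_variance": difference_variance,
        "difference_entropy": difference_entropy,
        "imc1": imc1,
        "imc2": imc2,
    }


def haralick_features(
    gray: GrayImage | np.ndarray,
    region_mask: np.ndarray,
    params: HaralickParams | None = None,
) -> dict[str, float]:
    """13 Haralick texture values for one region of a gray image."""
    params = params or HaralickParams()
    g = gray.pixels if isinstance(gray, GrayImage) else np.asarray(gray, float)
    if region_mask.sum() < 2:
        raise ValueError("Haralick texture needs a region of >= 2 pixels")
    glcm = _masked_glcm(g, region_mask.astype(bool), params)
    stats = haralick_statistics(glcm)
    assert tuple(stats) == HARALICK_NAMES
    return stats


def compute_intrinsic_features(
    img: CalibratedImage,
    nuclei: np.ndarray,
    cells: np.ndarray,
    records,
    haralick_params: HaralickParams | None = None,
) -> pd.DataFrame:
    """Per-cell 47-column intrinsic feature table (rows follow ``records``).

    The PCA gray projection is computed once over the whole analyzed image.
    Empty cytoplasms fall back to the nucleus region for texture so every slot
    stays populated.
    """
    from scipy import ndimage as ndi

    haralick_params = haralick_params or HaralickParams()
    gray = pca_gray(img)
    out = np.empty((len(records), len(INTRINSIC_NAMES)))
    boxes = ndi.find_objects(cells)
    for row, rec in enumerate(records):
        lab = rec.cell_label
        sl = boxes[lab - 1]
        cell_m = cells[sl] == lab
        nuc_m = nuclei[sl] == lab
        cyt_m = cell_m & ~nuc_m
        sub = CalibratedImage(
            img.pixels[sl], img.calibration, img.channel_names
        )
        vals = shape_size_features(rec)
        vals.update(color_features(sub, nuc_m, cyt_m))
        gsub = gray.pixels[sl]
        vals.update(
            {
                f"nucleus_haralick_{k}": v
                for k, v in haralick_features(gsub, nuc_m, haralick_params).items()
            }
        )
        tex_m = cyt_m if cyt_m.sum() >= 2 else nuc_m
        vals.update(
            {
                f"cytoplasm_haralick_{k}": v
                for k, v in haralick_features(gsub, tex_m, haralick_params).items()
            }
        )
        out[row] = [vals[n] for n in INTRINSIC_NAMES]
    return pd.DataFrame(out, columns=list(INTRINSIC_NAMES))
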