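"""Calibrated image I/O, stain unmixing, duct ROI extraction, and table output.

Brightfield H&E images follow the Beer–Lambert model: each stain attenuates
transmitted light along a characteristic optical-density (OD) direction in RGB
space. Color deconvolution converts intensities to OD (``-log10(I/I0)``) and
unmixes them with the inverse of the stain matrix, yielding per-stain density
maps (hematoxylin, eosin, DAB). Ducts are located on the eosin map: Gaussian
smoothing, isodata thresholding, connected components, and slightly enlarged
bounding boxes.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.filters import threshold_isodata
from skimage.measure import label as cc_label

from .catalog import catalog_names

__all__ = [
    "CalibratedImage",
    "StainVectors",
    "DuctROI",
    "read_image",
    "write_image",
    "read_label_image",
    "write_label_image",
    "color_deconvolve",
    "stains_to_rgb",
    "extract_duct_rois",
    "write_feature_table",
    "read_feature_table",
    "render_overlay",
]


@dataclass
class CalibratedImage:
    """A 2-D raster (1 or 3 channels) with an isotropic µm-per-pixel scale."""

    pixels: np.ndarray
    calibration: float  # µm per pixel, isotropic
    channel_names: tuple[str, ...] = ("R", "G", "B")

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.calibration <= 0:
            raise ValueError("calibration must be > 0 µm/px")
        if self.pixels.ndim == 2:
            if len(self.channel_names) != 1:
                self.channel_names = ("gray",)
        elif self.pixels.ndim == 3 and self.pixels.shape[2] == 3:
            if len(self.channel_names) != 3:
                raise ValueError("3-channel image needs 3 channel names")
        else:
            raise ValueError("image must have 1 or 3 channels (HxW or HxWx3)")
        if not np.isfinite(np.asarray(self.pixels, dtype=float)).all():
            raise ValueError("pixel values must be finite")

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def white_level(self) -> float:
        """Reference intensity I0 for optical-density conversion."""
        if self.pixels.dtype == np.uint16:
            return 65535.0
        return 255.0


# Published H&E-DAB optical-density stain vectors (hematoxylin, eosin, DAB),
# the de-facto "built-in" matrix of ImageJ's color deconvolution.
_RUIFROK_HE_DAB = np.array(
    [
        [0.650, 0.704, 0.286],
        [0.072, 0.990, 0.105],
        [0.268, 0.570, 0.776],
    ]
)


@dataclass
class StainVectors:
    """Rows are unit-norm stain OD vectors in RGB space (H, E, DAB)."""

    matrix: np.ndarray = field(
        default_factory=lambda: _RUIFROK_HE_DAB.copy()
    )

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("stain matrix must be 3x3")
        if (m < 0).any():
            raise ValueError("stain vectors must be non-negative")
        norms = np.linalg.norm(m, axis=1)
        if (norms == 0).any():
            raise ValueError("stain vectors must be non-zero")
        self.matrix = m / norms[:, None]
        if abs(np.linalg.det(self.matrix)) < 1e-8:
            raise ValueError("stain matrix is singular")

    @classmethod
    def he_dab(cls) -> "StainVectors":
        return cls()


@dataclass(frozen=True)
class DuctROI:
    """Half-open bounding box (row_min, col_min, row_max, col_max), 0-based."""

    bbox: tuple[int, int, int, int]
    source_id: str = ""

    def __post_init__(self) -> None:
        r0, c0, r1, c1 = self.bbox
        if not (r0 < r1 and c0 < c1):
            raise ValueError("degenerate bounding box")
        if r0 < 0 or c0 < 0:
            raise ValueError("bounding box outside image bounds")


def read_image(path, calibration_um_per_px: float) -> CalibratedImage:
    """Read a TIFF or PNG raster as a :class:`CalibratedImage`.

    Bit depths above 16 are rejected; channel order is kept as stored.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"file not found: {path}")
    p = str(path)
    if p.lower().endswith((".tif", ".tiff")):
        px = tifffile.imread(p)
    else:
        px = iio.imread(p)
    px = np.asarray(px)
    if px.dtype not in (np.uint8, np.uint16, np.int16, np.int8):
        if np.issubdtype(px.dtype, np.integer):
            raise ValueError(f"unsupported bit depth: {px.dtype}")
        raise ValueError(f"unsupported pixel dtype: {px.dtype}")
    if px.ndim == 3 and px.shape[2] == 4:  # drop alpha
        px = px[:, :, :3]
    names = ("R", "G", "B") if px.ndim == 3 else ("gray",)
    return CalibratedImage(px, calibration_um_per_px, names)


def write_image(path, pixels: np.ndarray) -> None:
    p = str(path)
    if p.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(p, pixels)
    else:
        iio.imwrite(p, pixels)


def read_label_image(path) -> np.ndarray:
    if not os.path.exists(path):
        raise FileNotFoundError(f"file not found: {path}")
    labels = tifffile.imread(str(path))
    if labels.ndim != 2 or not np.issubdtype(labels.dtype, np.integer):
        raise ValueError("label image must be a 2-D integer raster")
    if labels.min() < 0:
        raise ValueError("label image must be non-negative")
    return labels.astype(np.int32)


def write_label_image(path, labels: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(labels, dtype=np.int32))


def color_deconvolve(
    img: CalibratedImage, stains: StainVectors | None = None
) -> np.ndarray:
    """Unmix an RGB brightfield image into per-stain OD maps.

    Returns an (H, W, 3) float array, channels ordered H, E, DAB. OD is
    ``-log10((I + eps) / I0)`` with eps = 1 intensity step to keep zero
    intensities finite.
    """
    if img.n_channels != 3:
        raise ValueError("color deconvolution requires a 3-channel image")
    stains = stains or StainVectors.he_dab()
    i0 = img.white_level
    eps = 1.0
    od = -np.log10((img.pixels.astype(float) + eps) / (i0 + eps))
    conc = od.reshape(-1, 3) @ np.linalg.inv(stains.matrix)
    return conc.reshape(od.shape)


def stains_to_rgb(
    concentrations: np.ndarray,
    stains: StainVectors | None = None,
    white_level: float = 255.0,
) -> np.ndarray:
    """Forward Beer–Lambert mixing: stain OD maps -> RGB intensity image."""
    stains = stains or StainVectors.he_dab()
    od = np.asarray(concentrations, dtype=float) @ stains.matrix
    rgb = (white_level + 1.0) * np.power(10.0, -od) - 1.0
    return np.clip(rgb, 0, white_level)


def extract_duct_rois(
    img: CalibratedImage,
    sigma_px: float = 2.0,
    margin_px: int = 20,
    min_area_px: int = 500,
    min_od: float = 0.05,
    stains: StainVectors | None = None,
    source_id: str = "",
) -> list[DuctROI]:
    """Locate duct-like regions as dense eosin blobs on an H&E image.

    Eosin OD map -> Gaussian blur (sigma_px) -> isodata threshold (floored at
    ``min_od`` so blank images yield nothing) -> connected components ->
    bounding boxes enlarged by ``margin_px`` and clipped to the image.
    Components smaller than ``min_area_px`` are discarded.
    """
    if img.n_channels != 3:
        raise ValueError("duct extraction is defined for 3-channel H&E images")
    eosin = color_deconvolve(img, stains)[:, :, 1]
    blurred = ndimage.gaussian_filter(eosin, sigma=sigma_px)
    if blurred.max() <= min_od:
        return []
    try:
        thr = float(threshold_isodata(blurred, nbins=256))
    except ValueError:
        return []
    thr = max(thr, min_od)
    mask = blurred > thr
    labels = cc_label(mask, connectivity=2)
    h, w = labels.shape
    rois: list[DuctROI] = []
    for sl in ndimage.find_objects(labels):
        if sl is None:
            continue
        area = int(mask[sl].sum())
        if area < min_area_px:
            continue
        r0 = max(sl[0].start - margin_px, 0)
        c0 = max(sl[1].start - margin_px, 0)
        r1 = min(sl[0].stop + margin_px, h)
        c1 = min(sl[1].stop + margin_px, w)
        rois.append(DuctROI((r0, c0, r1, c1), source_id))
    rois.sort(key=lambda r: r.bbox)
    return rois


def write_feature_table(
    records,
    features: pd.DataFrame,
    path,
    classes=None,
    probabilities: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Write the per-cell feature table as CSV.

    Columns: cell_id, nucleus_label, centroid_x, centroid_y (µm), the 484
    canonical feature names, then optionally ``class`` and per-class
    probability columns. Returns the assembled frame.
    """
    records = list(records)
    if len(records) != len(features):
        raise ValueError(
            f"{len(records)} cell records but {len(features)} feature rows"
        )
    names = catalog_names()
    feats = pd.DataFrame(np.asarray(features, dtype=float), columns=names)
    meta = pd.DataFrame(
        {
            "cell_id": [r.cell_label for r in records],
            "nucleus_label": [r.nucleus_label for r in records],
            "centroid_x": [r.centroid[0] for r in records],
            "centroid_y": [r.centroid[1] for r in records],
        }
    )
    out = pd.concat([meta.reset_index(drop=True), feats.reset_index(drop=True)], axis=1)
    if classes is not None:
        if len(classes) != len(records):
            raise ValueError("class list length mismatch")
        out["class"] = list(classes)
    if probabilities is not None:
        for col in probabilities.columns:
            out[f"prob_{col}"] = np.asarray(probabilities[col], dtype=float)
    out.to_csv(path, index=False)
    return out


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [n for n in catalog_names() if n not in df.columns]
    if missing:
        raise ValueError(
            f"feature table missing {len(missing)} catalog columns "
            f"(first: {missing[0]})"
        )
    return df


_DEFAULT_COLORS = {"human": (0, 255, 0), "mouse": (255, 0, 0)}


def render_overlay(
    img: CalibratedImage,
    cells: np.ndarray,
    predictions: dict,
    color_map: dict | None = None,
    radius_px: int = 3,
) -> np.ndarray:
    """Mark each cell centroid with a class-colored dot on an RGB copy.

    ``predictions`` maps cell label -> class name; labels absent from the
    raster raise. Centroids are label-moment centroids, rounded to pixels.
    """
    colors = dict(_DEFAULT_COLORS)
    if color_map:
        colors.update(color_map)
    px = img.pixels
    if px.ndim == 2:
        base = np.stack([px] * 3, axis=-1)
    else:
        base = px.copy()
    if base.dtype != np.uint8:
        scale = 255.0 / max(float(base.max()), 1.0)
        base = np.clip(base.astype(float) * scale, 0, 255).astype(np.uint8)
    labels_present = set(np.unique(cells)) - {0}
    unknown = set(predictions) - labels_present
    if unknown:
        raise ValueError(f"prediction for unknown label(s): {sorted(unknown)[:5]}")
    if not predictions:
        return base
    ids = sorted(predictions)
    coms = ndimage.center_of_mass(cells > 0, cells, ids)
    h, w = cells.shape
    yy, xx = np.mgrid[-radius_px : radius_px + 1, -radius_px : radius_px + 1]
    disk = yy**2 + xx**2 <= radius_px**2
    for lab, (cr, cc) in zip(ids, coms):
        cls = predictions[lab]
        if cls not in colors:
            warnings.warn(f"no color for class {cls!r}; using white")
        color = colors.get(cls, (255, 255, 255))
        r, c = int(round(cr)), int(round(cc))
        r0, r1 = max(r - radius_px, 0), min(r + radius_px + 1, h)
        c0, c1 = max(c - radius_px, 0), min(c + radius_px + 1, w)
        sub = disk[
            r0 - (r - radius_px) : disk.shape[0] - ((r + radius_px + 1) - r1),
            c0 - (c - radius_px) : disk.shape[1] - ((c + radius_px + 1) - c1),
        ]
        region = base[r0:r1, c0:c1]
        region[sub] = color
    return base
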