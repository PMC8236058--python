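"""Synthetic H&E-like tissue scenes with ground truth.

Two cell populations echo the qualitative species differences seen in
intraductal xenografts: "human" nuclei are larger and more elongated and are
placed along smooth closed duct-like curves with their major axes normal to
the curve tangent (so consecutive cells form mutual lateral neighbors and
chains); "mouse" nuclei are rounder, randomly oriented, and packed into blob
clusters with no preferred arrangement. Nuclei carry population-specific
intra-nuclear texture noise and the image is composed by Beer–Lambert mixing
of hematoxylin and eosin stain vectors over a white background.

Everything is driven by a single seeded generator: the same seed reproduces
the image, label raster, class mask, and truth table bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import CalibratedImage, StainVectors, stains_to_rgb

__all__ = [
    "PopulationSpec",
    "SceneSpec",
    "Scene",
    "generate_scene",
    "generate_detection_pair",
]

CLASS_IDS = {"human": 1, "mouse": 2}


@dataclass
class PopulationSpec:
    """Morphology and arrangement of one cell population (lengths in µm)."""

    name: str
    major_mean: float
    major_sd: float
    minor_mean: float
    minor_sd: float
    orientation: str  # radial_to_curve | uniform_random
    arrangement: str  # chain_along_curve | blob_cluster
    spacing_mean: float = 7.0
    spacing_sd: float = 0.8
    texture_noise_sd: float = 0.08  # OD units inside the nucleus
    hematoxylin_od: float = 0.9
    eosin_od: float = 0.1

    def __post_init__(self) -> None:
        if not (self.major_mean >= self.minor_mean > 0):
            raise ValueError("need mean major >= mean minor > 0")
        if self.spacing_mean <= 0:
            raise ValueError("spacing must be > 0")


def human_population() -> PopulationSpec:
    return PopulationSpec(
        name="human",
        major_mean=9.0,
        major_sd=1.2,
        minor_mean=5.0,
        minor_sd=0.8,
        orientation="radial_to_curve",
        arrangement="chain_along_curve",
        texture_noise_sd=0.06,
    )


def mouse_population() -> PopulationSpec:
    return PopulationSpec(
        name="mouse",
        major_mean=6.0,
        major_sd=0.8,
        minor_mean=5.0,
        minor_sd=0.7,
        orientation="uniform_random",
        arrangement="blob_cluster",
        texture_noise_sd=0.12,
    )


@dataclass
class SceneSpec:
    """Layout of one synthetic scene."""

    size_px: int = 1024
    calibration: float = 0.5  # µm per pixel
    n_human: int = 150
    n_mouse: int = 150
    n_curves: int = 3
    seed: int = 0
    human: PopulationSpec = field(default_factory=human_population)
    mouse: PopulationSpec = field(default_factory=mouse_population)
    cluster_radius_um: float = 38.0
    max_retries: int = 100

    def __post_init__(self) -> None:
        if self.n_human < 0 or self.n_mouse < 0:
            raise ValueError("cell counts must be >= 0")
        if self.calibration <= 0:
            raise ValueError("calibration must be > 0")


@dataclass
class Scene:
    image: CalibratedImage
    nuclei: np.ndarray  # int32 labels
    class_mask: np.ndarray  # uint8: 0 background, 1 human, 2 mouse
    truth: pd.DataFrame
    stain_od: dict  # generation-time H and E OD fields
    spec: SceneSpec


def _ellipse_pixels(size, cy, cx, a_px, b_px, theta):
    """Pixel coordinates inside an ellipse (semi-axes in px, major along
    ``theta`` in (x, y) convention); None when it leaves the image."""
    r = int(np.ceil(a_px)) + 1
    r0, r1 = int(np.floor(cy)) - r, int(np.floor(cy)) + r + 1
    c0, c1 = int(np.floor(cx)) - r, int(np.floor(cx)) + r + 1
    if r0 < 0 or c0 < 0 or r1 > size or c1 > size:
        return None
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dx = xx - cx
    dy = yy - cy
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    inside = (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0
    return yy[inside], xx[inside]


def _sample_axes(rng, pop: PopulationSpec):
    minor = max(rng.normal(pop.minor_mean, pop.minor_sd), 1.5)
    major = max(rng.normal(pop.major_mean, pop.major_sd), minor + 0.2)
    return major, minor


def _closed_curve(rng, center, radius_um):
    """A perturbed circle r(phi); returns a callable phi -> (x, y) µm."""
    amps = rng.uniform(0.0, 0.06, size=3)
    phases = rng.uniform(0, 2 * np.pi, size=3)

    def point(phi):
        r = radius_um * (
            1.0
            + sum(a * np.cos((k + 2) * phi + p) for k, (a, p) in enumerate(zip(amps, phases)))
        )
        return center[0] + r * np.cos(phi), center[1] + r * np.sin(phi)

    return point


def _spread_centers(rng, n, size_um, margin, existing, min_sep, n_cand=200):
    """Pick n centers, greedily maximizing separation from existing points."""
    centers = list(existing)
    picked = []
    for _ in range(n):
        best, best_score = None, -1.0
        for _ in range(n_cand):
            c = rng.uniform(margin, size_um - margin, size=2)
            score = (
                min(np.hypot(c[0] - e[0], c[1] - e[1]) for e in centers)
                if centers
                else np.inf
            )
            if score > best_score:
                best, best_score = c, score
            if best_score >= min_sep:
                break
        centers.append(tuple(best))
        picked.append(tuple(best))
    return picked


def generate_scene(spec: SceneSpec | None = None) -> Scene:
    """Render one scene: H&E-like image, nucleus labels, class mask, truth.

    Raises RuntimeError (reporting achieved counts) if the requested counts
    cannot be placed within the retry budget.
    """
    spec = spec or SceneSpec()
    rng = np.random.default_rng(spec.seed)
    size = spec.size_px
    cal = spec.calibration
    size_um = size * cal
    labels = np.zeros((size, size), dtype=np.int32)
    class_mask = np.zeros((size, size), dtype=np.uint8)
    rows: list[dict] = []
    next_label = 1

    def try_place(x_um, y_um, major, minor, theta, pop: PopulationSpec):
        nonlocal next_label
        px_coords = _ellipse_pixels(
            size, y_um / cal, x_um / cal, major / 2.0 / cal, minor / 2.0 / cal, theta
        )
        if px_coords is None:
            return False
        yy, xx = px_coords
        if yy.size < 4 or labels[yy, xx].any():
            return False
        # 1-px clearance so neighboring nuclei stay separable instances.
        if labels[
            np.clip(yy[:, None] + [-1, 0, 1], 0, size - 1),
            np.clip(xx[:, None] + [-1, 0, 1], 0, size - 1),
        ].any():
            return False
        labels[yy, xx] = next_label
        class_mask[yy, xx] = CLASS_IDS[pop.name]
        rows.append(
            {
                "cell_id": next_label,
                "class": pop.name,
                "centroid_x_um": float(xx.mean() * cal),
                "centroid_y_um": float(yy.mean() * cal),
                "major_um": major,
                "minor_um": minor,
                "orientation_rad": float(theta % np.pi),
            }
        )
        next_label += 1
        return True

    placed = {"human": 0, "mouse": 0}
    curve_centers: list[tuple[float, float]] = []

    # --- human: chains along closed duct-like curves ------------------------
    pop = spec.human
    if spec.n_human > 0:
        max_curves = spec.n_curves + 5
        radius_hi = min(70.0, size_um / 2 - pop.major_mean - 12)
        radius_lo = min(45.0, radius_hi)
        while placed["human"] < spec.n_human and len(curve_centers) < max_curves:
            radius = rng.uniform(radius_lo, radius_hi)
            margin = radius * 1.15 + pop.major_mean + 5
            if 2 * margin >= size_um:
                raise RuntimeError(
                    f"image too small for duct curves; placed {placed['human']} "
                    f"human and {placed['mouse']} mouse cells"
                )
            (center,) = _spread_centers(
                rng, 1, size_um, margin, curve_centers, 2.3 * radius
            )
            curve_centers.append(center)
            curve = _closed_curve(rng, center, radius)
            phi = rng.uniform(0, 2 * np.pi)
            total = 0.0
            misses = 0
            while total < 2 * np.pi and placed["human"] < spec.n_human:
                x, y = curve(phi)
                major, minor = _sample_axes(rng, pop)
                if pop.orientation == "radial_to_curve":
                    theta = float(np.arctan2(y - center[1], x - center[0]))
                else:
                    theta = float(rng.uniform(0, np.pi))
                if try_place(x, y, major, minor, theta, pop):
                    placed["human"] += 1
                    misses = 0
                else:
                    misses += 1
                    if misses > spec.max_retries:
                        break
                spacing = max(rng.normal(pop.spacing_mean, pop.spacing_sd), 3.0)
                # local radius for arc-length stepping
                r_loc = max(np.hypot(x - center[0], y - center[1]), 1.0)
                dphi = spacing / r_loc
                phi += dphi
                total += dphi
        if placed["human"] < spec.n_human:
            raise RuntimeError(
                f"could not place requested cells; achieved {placed['human']} "
                f"human and {placed['mouse']} mouse"
            )

    # --- mouse: blob clusters ----------------------------------------------
    pop = spec.mouse
    if spec.n_mouse > 0:
        r_cl = spec.cluster_radius_um
        per_cluster = max(
            int(np.floor(0.55 * np.pi * r_cl**2 / (np.pi * (pop.spacing_mean / 2) ** 2))),
            1,
        )
        n_clusters = int(np.ceil(spec.n_mouse / per_cluster)) + 2
        centers = _spread_centers(
            rng,
            n_clusters,
            size_um,
            r_cl + pop.major_mean + 4,
            curve_centers,
            95.0,
        )
        pts_by_cluster: list[list[tuple[float, float]]] = [[] for _ in centers]
        ci = 0
        failures = 0
        while placed["mouse"] < spec.n_mouse:
            center = centers[ci % len(centers)]
            cluster_pts = pts_by_cluster[ci % len(centers)]
            ok = False
            for _ in range(spec.max_retries):
                rr = r_cl * np.sqrt(rng.uniform())
                ang = rng.uniform(0, 2 * np.pi)
                x = center[0] + rr * np.cos(ang)
                y = center[1] + rr * np.sin(ang)
                if any(
                    np.hypot(x - px_, y - py_) < pop.spacing_mean
                    for px_, py_ in cluster_pts
                ):
                    continue
                major, minor = _sample_axes(rng, pop)
                theta = float(rng.uniform(0, np.pi))
                if try_place(x, y, major, minor, theta, pop):
                    cluster_pts.append((x, y))
                    placed["mouse"] += 1
                    ok = True
                    break
            failures = 0 if ok else failures + 1
            if failures > len(centers) * 3:
                raise RuntimeError(
                    f"could not place requested cells; achieved {placed['human']} "
                    f"human and {placed['mouse']} mouse"
                )
            ci += 1

    # --- render -------------------------------------------------------------
    nuc = labels > 0
    od_h = np.zeros((size, size))
    od_e = np.zeros((size, size))
    truth = pd.DataFrame(rows)
    for pop in (spec.human, spec.mouse):
        sel = class_mask == CLASS_IDS[pop.name]
        if not sel.any():
            continue
        od_h[sel] = pop.hematoxylin_od + rng.normal(
            0.0, pop.texture_noise_sd, size=int(sel.sum())
        )
        od_e[sel] = pop.eosin_od
    # Soft eosin-dense tissue around the cells (cytoplasm/stroma).
    tissue = ndimage.gaussian_filter(nuc.astype(float), sigma=8.0)
    tmax = tissue.max() if tissue.max() > 0 else 1.0
    od_e += 0.38 * np.clip(tissue / (0.6 * tmax), 0, 1)
    od_e += rng.normal(0.0, 0.02, od_e.shape)
    od_h = np.clip(ndimage.gaussian_filter(od_h, sigma=0.6), 0, None)
    od_e = np.clip(ndimage.gaussian_filter(od_e, sigma=0.8), 0, None)

    conc = np.stack([od_h, od_e, np.zeros_like(od_h)], axis=-1)
    rgb = np.round(stains_to_rgb(conc, StainVectors.he_dab())).astype(np.uint8)
    image = CalibratedImage(rgb, cal)
    return Scene(image, labels, class_mask, truth, {"h": od_h, "e": od_e}, spec)


def generate_detection_pair(
    gt_labels: np.ndarray,
    drop_fraction: float = 0.0,
    spurious_count: int = 0,
    jitter_px: int = 0,
    seed: int = 0,
):
    """Perturb a ground-truth label image to a known TP/FP/FN budget.

    Drops a seeded fraction of objects, shifts survivors by up to
    ``jitter_px`` (integer offsets), and sprinkles spurious small disks in the
    background. Returns (gt, perturbed, info) with the dropped/spurious ids.
    """
    rng = np.random.default_rng(seed)
    gt = np.asarray(gt_labels).astype(np.int32)
    ids = np.unique(gt)
    ids = ids[ids > 0]
    n_drop = int(round(drop_fraction * len(ids)))
    dropped = set(
        rng.choice(ids, size=n_drop, replace=False).tolist() if n_drop else []
    )
    pert = np.zeros_like(gt)
    h, w = gt.shape
    for lab in ids:
        if lab in dropped:
            continue
        rr, cc = np.nonzero(gt == lab)
        if jitter_px > 0:
            dr = int(rng.integers(-jitter_px, jitter_px + 1))
            dc = int(rng.integers(-jitter_px, jitter_px + 1))
        else:
            dr = dc = 0
        rr2 = np.clip(rr + dr, 0, h - 1)
        cc2 = np.clip(cc + dc, 0, w - 1)
        pert[rr2, cc2] = lab
    spurious_ids = []
    next_lab = int(ids.max()) + 1 if len(ids) else 1
    yy, xx = np.mgrid[-4:5, -4:5]
    disk = yy**2 + xx**2 <= 16
    for _ in range(spurious_count):
        for _ in range(200):
            r = int(rng.integers(5, h - 5))
            c = int(rng.integers(5, w - 5))
            region = pert[r - 4 : r + 5, c - 4 : c + 5]
            gtr = gt[r - 4 : r + 5, c - 4 : c + 5]
            if region[disk].any() or gtr[disk].any():
                continue
            region[disk] = next_lab
            spurious_ids.append(next_lab)
            next_lab += 1
            break
        else:
            raise RuntimeError("could not place spurious object")
    info = {
        "dropped_ids": sorted(int(i) for i in dropped),
        "spurious_ids": spurious_ids,
        "jitter_px": jitter_px,
    }
    return gt, pert, info
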