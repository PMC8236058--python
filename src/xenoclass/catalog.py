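"""Canonical catalog of the 484 per-cell features.

The descriptor has three blocks:

* ``intrinsic`` (47): properties of the cell itself — 9 shape/size, 12 color
  statistics, 26 Haralick texture values (13 per region, nucleus and cytoplasm).
* ``neighbor_derived`` (376): mean and variance of each of the 47 intrinsic
  features over the K-connected neighborhood (K closest cells by shortest-path
  distance on the Delaunay graph), for K in 5, 10, 20, 40: 47 x 2 x 4.
* ``organization`` (61): spatial arrangement of the neighborhood — direct
  Delaunay neighbors, lateral (left/right) neighbors, cell chains, and the
  K-nearest / K-connected set statistics.

The ordering of this catalog is the column contract for every feature table the
package writes; it is deterministic and hashed so that a trained model can
refuse incompatible feature tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

__all__ = [
    "FeatureDef",
    "HARALICK_NAMES",
    "SHAPE_NAMES",
    "COLOR_NAMES",
    "INTRINSIC_NAMES",
    "K_VALUES",
    "N_INTRINSIC",
    "N_NEIGHBOR_DERIVED",
    "N_ORGANIZATION",
    "N_FEATURES",
    "feature_catalog",
    "catalog_names",
    "catalog_categories",
    "catalog_fills",
    "catalog_hash",
    "export_catalog_json",
]

#: Neighborhood sizes for the K-nearest / K-connected vicinities.
K_VALUES: tuple[int, ...] = (5, 10, 20, 40)

#: The 13 classic second-order GLCM texture statistics.
HARALICK_NAMES: tuple[str, ...] = (
    "asm",
    "contrast",
    "correlation",
    "variance",
    "idm",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
)

#: Shape/size block: moment-ellipse axes + elongation + area for nucleus and
#: cell, plus the cytoplasm/nucleus area ratio.
SHAPE_NAMES: tuple[str, ...] = (
    "nucleus_major_um",
    "nucleus_minor_um",
    "nucleus_elongation",
    "nucleus_area_um2",
    "cell_major_um",
    "cell_minor_um",
    "cell_elongation",
    "cell_area_um2",
    "area_ratio",
)

#: Color block: per-region, per-channel mean and standard deviation. Channels
#: are named c0/c1/c2 (R/G/B for brightfield H&E; c0 only for single-channel
#: fluorescence, the rest default-filled).
COLOR_NAMES: tuple[str, ...] = tuple(
    f"{region}_{stat}_c{ch}"
    for region in ("nucleus", "cytoplasm")
    for ch in range(3)
    for stat in ("mean", "sd")
)

_HARALICK_FULL: tuple[str, ...] = tuple(
    f"{region}_haralick_{name}"
    for region in ("nucleus", "cytoplasm")
    for name in HARALICK_NAMES
)

INTRINSIC_NAMES: tuple[str, ...] = SHAPE_NAMES + COLOR_NAMES + _HARALICK_FULL

N_INTRINSIC = len(INTRINSIC_NAMES)  # 47
N_NEIGHBOR_DERIVED = N_INTRINSIC * 2 * len(K_VALUES)  # 376
N_ORGANIZATION = 61
N_FEATURES = N_INTRINSIC + N_NEIGHBOR_DERIVED + N_ORGANIZATION  # 484


@dataclass(frozen=True)
class FeatureDef:
    """One catalog entry: column name, block, and the default fill value used
    when a cell lacks the neighborhood required to compute the feature."""

    name: str
    category: str  # intrinsic | neighbor_derived | organization
    fill: float = 0.0


def _organization_defs() -> list[FeatureDef]:
    defs: list[FeatureDef] = []
    org = "organization"
    # Direct Delaunay neighbors (3).
    for n in ("direct_count", "direct_mean_dist", "direct_var_dist"):
        defs.append(FeatureDef(n, org))
    # Lateral neighbors, left and right (6).
    for side in ("left", "right"):
        for n in ("dist", "alignment", "orientation_diff"):
            defs.append(FeatureDef(f"lateral_{side}_{n}", org))
    # Cell chains (4); tortuosity of a missing chain is 1 (a straight,
    # degenerate chain), every other absent feature fills with 0.
    defs.append(FeatureDef("chain_size", org))
    defs.append(FeatureDef("chain_tortuosity", org, fill=1.0))
    defs.append(FeatureDef("chain_mean_link_dist", org))
    defs.append(FeatureDef("chain_mean_orientation_diff", org))
    # K-nearest sets (4 per K = 16).
    for k in K_VALUES:
        for n in ("mean_dist", "var_dist", "dist_to_centroid", "member_count"):
            defs.append(FeatureDef(f"knear{k}_{n}", org))
    # K-connected sets (8 per K = 32).
    for k in K_VALUES:
        for n in (
            "mean_dist",
            "var_dist",
            "dist_to_centroid",
            "member_count",
            "ellipse_major",
            "ellipse_minor",
            "ellipse_elongation",
            "ellipse_area",
        ):
            defs.append(FeatureDef(f"kconn{k}_{n}", org))
    return defs


def feature_catalog() -> list[FeatureDef]:
    """Full ordered catalog: 47 intrinsic, 376 neighbor-derived, 61 organization."""
    defs = [FeatureDef(n, "intrinsic") for n in INTRINSIC_NAMES]
    for k in K_VALUES:
        for name in INTRINSIC_NAMES:
            defs.append(FeatureDef(f"kconn{k}_mean_{name}", "neighbor_derived"))
            defs.append(FeatureDef(f"kconn{k}_var_{name}", "neighbor_derived"))
    defs.extend(_organization_defs())
    if len(defs) != N_FEATURES:  # pragma: no cover - catalog is static
        raise AssertionError("feature catalog size mismatch")
    return defs


def catalog_names() -> list[str]:
    return [d.name for d in feature_catalog()]


def catalog_categories() -> list[str]:
    return [d.category for d in feature_catalog()]


def catalog_fills() -> list[float]:
    return [d.fill for d in feature_catalog()]


def catalog_hash() -> str:
    """SHA-256 of the ordered (name, category, fill) triples."""
    payload = json.dumps(
        [(d.name, d.category, d.fill) for d in feature_catalog()]
    ).encode()
    return hashlib.sha256(payload).hexdigest()


def export_catalog_json(path) -> None:
    """Write the catalog as a JSON list of {name, category, fill} objects."""
    with open(path, "w") as fh:
        json.dump(
            [
                {"name": d.name, "category": d.category, "fill": d.fill}
                for d in feature_catalog()
            ],
            fh,
            indent=1,
        )
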