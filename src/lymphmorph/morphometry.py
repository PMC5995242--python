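"""Per-vessel shape/size descriptors and per-sample quantity metrics.

Every measurement is taken on the vessel *lumen* (the interior enclosed by
the endothelial wall), independent of wall thickness, and expressed in
micrometres via the image pixel size.  Vessels are assigned to caliber
classes by their longest axis (maximum Feret diameter):

    small capillaries        5–15 μm
    intermediate capillaries 15–20 μm
    large capillaries        20–50 μm
    small collector vessels  50–200 μm

Structures outside 5–200 μm are not considered.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull
from skimage import measure, morphology

CALIBER_CLASSES = ("small_cap", "intermediate_cap", "large_cap", "small_collector")

#: half-open lower edges: a length on a boundary belongs to the upper class
CALIBER_BOUNDS: Mapping[str, tuple[float, float]] = {
    "small_cap": (5.0, 15.0),
    "intermediate_cap": (15.0, 20.0),
    "large_cap": (20.0, 50.0),
    "small_collector": (50.0, 200.0),
}

CLASS_LABELS = {
    "small_cap": "5-15 um",
    "intermediate_cap": "15-20 um",
    "large_cap": "20-50 um",
    "small_collector": "50-200 um",
}

SHAPE_COLUMNS = (
    "area",
    "length",
    "width",
    "perimeter",
    "roundness",
    "aspect",
    "perimeter_ratio",
    "deformity",
    "shape_factor",
    "branching",
)


class CaliberError(ValueError):
    """Length outside the evaluable 5–200 μm range."""


def classify_caliber(length: float) -> str:
    """Assign a caliber class from the longest axis in μm.

    Intervals are half-open at the lower edge ([5,15), [15,20), [20,50),
    [50,200]), so a 15 μm vessel is an intermediate capillary.
    """
    if not np.isfinite(length) or length < 5.0 or length > 200.0:
        raise CaliberError(f"longest axis {length!r} μm outside [5, 200]")
    if length < 15.0:
        return "small_cap"
    if length < 20.0:
        return "intermediate_cap"
    if length < 50.0:
        return "large_cap"
    return "small_collector"


@dataclass(frozen=True)
class VesselMorphometry:
    """Descriptor suite for one vessel lumen.

    Sizes are in μm/μm²; shape descriptors are dimensionless.  ``roundness``
    is the normalised perimeter ``P² / (4πA)`` (1 for a disc, >1 otherwise);
    ``aspect`` is length/width; ``perimeter_ratio`` compares the lumen
    perimeter with its convex hull's; ``deformity`` is 1 − solidity;
    ``shape_factor`` is ``L² / (4A/π)`` (elongation-normalised length);
    ``branching`` counts endpoints of the lumen's morphological skeleton
    (a simple tube scores 2).
    """

    region_id: int | str
    area: float
    length: float
    width: float
    perimeter: float
    roundness: float
    aspect: float
    perimeter_ratio: float
    deformity: float
    shape_factor: float
    branching: int
    caliber_class: str
    was_closed: bool = False

    def as_dict(self) -> dict:
        return asdict(self)


def _hull_feret(coords: np.ndarray) -> tuple[float, float]:
    """Max/min Feret diameters (px) of a pixel set, via its center hull.

    Pixel centers sit at integer coordinates; measuring between extreme
    centers is unbiased for boundary-inclusive rasterization (verified on
    digital discs of known diameter).
    """
    if len(coords) < 3 or np.linalg.matrix_rank(coords - coords[0]) < 2:
        ptp = coords.max(axis=0) - coords.min(axis=0)
        d = float(np.hypot(*ptp))
        return max(d, 1.0), float(min(ptp))
    hull = ConvexHull(coords)
    pts = coords[hull.vertices]
    diff = pts[:, None, :] - pts[None, :, :]
    feret_max = float(np.sqrt((diff**2).sum(-1)).max())
    # min Feret: smallest width over hull edge directions (rotating calipers)
    edges = np.roll(pts, -1, axis=0) - pts
    norms = np.hypot(edges[:, 0], edges[:, 1])
    normals = np.stack([-edges[:, 1], edges[:, 0]], axis=1) / norms[:, None]
    proj = pts @ normals.T
    feret_min = float((proj.max(axis=0) - proj.min(axis=0)).min())
    return feret_max, feret_min


def _skeleton_endpoints(mask: np.ndarray) -> int:
    skel = morphology.skeletonize(mask)
    if skel.sum() <= 1:
        return int(skel.sum())
    kernel = np.ones((3, 3), int)
    kernel[1, 1] = 10
    conv = ndimage.convolve(skel.astype(int), kernel, mode="constant")
    return int(((conv == 10) | (conv == 11)).sum())


def measure_vessel(
    lumen_mask: np.ndarray,
    pixel_size: float,
    region_id: int | str = 0,
    was_closed: bool = False,
) -> VesselMorphometry:
    """Measure one lumen mask (2-D boolean array) at the given μm/px scale.

    Raises ``ValueError`` for degenerate regions (<1 px) and
    ``CaliberError`` when the longest axis falls outside 5–200 μm.
    """
    lumen_mask = np.asarray(lumen_mask, bool)
    n_px = int(lumen_mask.sum())
    if n_px < 1:
        raise ValueError("degenerate region: empty lumen mask")

    coords = np.argwhere(lumen_mask)
    feret_max_px, feret_min_px = _hull_feret(coords.astype(float))
    length = feret_max_px * pixel_size
    width = max(feret_min_px, 1.0) * pixel_size
    # the 5/200 μm evaluable bounds cannot be resolved sharper than one
    # pixel: snap boundary-grazing lengths onto the bound
    if 5.0 - pixel_size <= length < 5.0:
        length = 5.0
    elif 200.0 < length <= 200.0 + pixel_size:
        length = 200.0

    area = n_px * pixel_size**2
    perimeter = measure.perimeter_crofton(lumen_mask, directions=4) * pixel_size
    if perimeter <= 0:  # single-pixel regions
        perimeter = 4 * pixel_size

    # convex hull perimeter/area from the filled convex image, same estimator
    props = measure.regionprops(lumen_mask.astype(np.uint8))[0]
    hull_perimeter = measure.perimeter_crofton(props.image_convex, directions=4)
    hull_perimeter = max(hull_perimeter * pixel_size, perimeter * 1e-9)
    hull_area = props.image_convex.sum() * pixel_size**2

    roundness = perimeter**2 / (4.0 * np.pi * area)
    aspect = length / width
    perimeter_ratio = max(perimeter / hull_perimeter, 1.0)
    deformity = float(np.clip(1.0 - area / hull_area, 0.0, 1.0))
    shape_factor = length**2 / (4.0 * area / np.pi)
    branching = max(2, _skeleton_endpoints(lumen_mask))

    return VesselMorphometry(
        region_id=region_id,
        area=area,
        length=length,
        width=width,
        perimeter=perimeter,
        roundness=roundness,
        aspect=aspect,
        perimeter_ratio=perimeter_ratio,
        deformity=deformity,
        shape_factor=shape_factor,
        branching=branching,
        caliber_class=classify_caliber(length),
        was_closed=was_closed,
    )


def vessels_to_frame(vessels: Iterable[VesselMorphometry]) -> pd.DataFrame:
    """Tabulate per-vessel descriptors (one row per vessel)."""
    rows = [v.as_dict() for v in vessels]
    if not rows:
        return pd.DataFrame(
            columns=["region_id", *SHAPE_COLUMNS, "caliber_class", "was_closed"]
        )
    return pd.DataFrame(rows)


def aggregate_sample(
    vessels: pd.DataFrame | Sequence[VesselMorphometry],
    tissue_area: float,
) -> pd.DataFrame:
    """Per-sample quantity metrics per caliber class and in total.

    ``tissue_area`` is in mm².  Returns one row per class plus a ``total``
    row with columns ``n``, ``density`` (vessels/mm²), ``sa_pct`` (% of the
    tissue area occupied by lumen), ``rel_density`` and ``rel_sa_pct``
    (per-class share of the total, in %), followed by per-class medians of
    every descriptor.  An empty vessel table yields all-zero quantities and
    the ``no_lymphatic_vascularization`` flag set on every row.
    """
    if tissue_area <= 0:
        raise ValueError("tissue_area must be positive (mm²)")
    if not isinstance(vessels, pd.DataFrame):
        vessels = vessels_to_frame(vessels)

    rows = []
    total_n = len(vessels)
    total_area = float(vessels["area"].sum()) if total_n else 0.0
    total_density = total_n / tissue_area
    total_sa = 100.0 * total_area / (tissue_area * 1e6)

    for cls in CALIBER_CLASSES:
        sub = vessels[vessels["caliber_class"] == cls] if total_n else vessels
        n = len(sub)
        density = n / tissue_area
        sa = 100.0 * float(sub["area"].sum()) / (tissue_area * 1e6) if n else 0.0
        row = {
            "caliber_class": cls,
            "n": n,
            "density": density,
            "sa_pct": sa,
            "rel_density": 100.0 * density / total_density if total_n else 0.0,
            "rel_sa_pct": 100.0 * sa / total_sa if total_sa > 0 else 0.0,
        }
        for col in SHAPE_COLUMNS:
            row[f"median_{col}"] = float(sub[col].median()) if n else np.nan
        rows.append(row)

    total_row = {
        "caliber_class": "total",
        "n": total_n,
        "density": total_density,
        "sa_pct": total_sa,
        "rel_density": 100.0 if total_n else 0.0,
        "rel_sa_pct": 100.0 if total_sa > 0 else 0.0,
    }
    for col in SHAPE_COLUMNS:
        total_row[f"median_{col}"] = float(vessels[col].median()) if total_n else np.nan
    rows.append(total_row)

    out = pd.DataFrame(rows)
    out["no_lymphatic_vascularization"] = total_n == 0
    return out
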