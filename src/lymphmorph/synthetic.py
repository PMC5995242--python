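"""Seeded synthetic histology and cohort generation.

Emulates the study material downstream stages are built for: ~1 mm tissue
microarray (TMA) core images containing ring-shaped stained lymphatic
vessels of 5–200 μm caliber (some with broken walls), and a patient cohort
whose total vessel density is heavy-tailed around a median of ~40.6
vessels/mm² with ~75% small capillaries, binary pre-treatment risk
covariates, and exponential event/censoring survival times.

Everything is driven by explicit integer seeds; identical seeds give
identical ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from skimage import draw

from .morphometry import CALIBER_BOUNDS, aggregate_sample, classify_caliber

# stain reference colors (8-bit RGB): DAB-like brown walls on a pale
# hematoxylin-like counterstained core over a white slide background
STAIN_RGB = (130, 80, 50)
TISSUE_RGB = (205, 195, 225)
BACKGROUND_RGB = (250, 250, 250)

#: INRG-style adverse-factor prevalences for the default synthetic cohort
DEFAULT_PREVALENCES = {
    "stage_m": 0.45,
    "age_gt18m": 0.50,
    "histo_unfav": 0.80,
    "mna": 0.20,
    "del11q": 0.20,
    "high_risk": 0.45,
}

#: log-hazards of the adverse factors the survival stage should recover;
#: "high_total_density" is the above-median total-density indicator
DEFAULT_HAZARDS = {
    "stage_m": 1.1,
    "mna": 0.95,
    "age_gt18m": 1.0,
    "high_total_density": 0.9,
}

# class mix: 75% small capillaries, remainder split like the per-class
# median densities of the study cohort (4.3 : 6.39 : 2.35)
DEFAULT_CLASS_FRACTIONS = {
    "small_cap": 0.75,
    "intermediate_cap": 0.082,
    "large_cap": 0.123,
    "small_collector": 0.045,
}


class PackingError(RuntimeError):
    """Vessels could not be placed without overlap within the attempt bound."""


@dataclass(frozen=True)
class VesselGroundTruth:
    """One synthetic vessel: lumen geometry plus wall/break parameters.

    ``major_axis``/``minor_axis`` describe the lumen ellipse (μm) before
    irregular perturbation; ``wall_thickness`` is the stained wall drawn
    outward from the lumen boundary; ``irregularity`` ∈ [0,1] scales
    low-order radial perturbation modes; ``open_fraction`` ∈ [0,0.35] is
    the fraction of the wall perimeter removed (0 = intact ring).
    """

    vessel_id: int
    center: tuple[float, float]  # μm (x, y); may be NaN for "unplaced"
    major_axis: float
    minor_axis: float
    wall_thickness: float
    irregularity: float
    open_fraction: float
    caliber_class: str

    def __post_init__(self):
        if not (0 < self.minor_axis <= self.major_axis):
            raise ValueError("require major_axis >= minor_axis > 0")
        if not (5.0 <= self.major_axis <= 200.0):
            raise ValueError("major_axis must lie in [5, 200] μm")
        if not (0.0 <= self.open_fraction <= 0.35):
            raise ValueError("open_fraction must lie in [0, 0.35]")
        if not (0.0 <= self.irregularity <= 1.0):
            raise ValueError("irregularity must lie in [0, 1]")
        if classify_caliber(self.major_axis) != self.caliber_class:
            raise ValueError(
                f"caliber_class {self.caliber_class} inconsistent with "
                f"major_axis {self.major_axis} μm"
            )


@dataclass
class SyntheticCohortConfig:
    """Study-level knobs for :func:`generate_cohort`.

    Defaults mirror the emulated cohort: 332 samples, 37.9% without any
    stained vessel, heavy-tailed total density with median 40.6/mm²,
    75% small capillaries, binary adverse covariates, exponential survival
    with proportional hazards and ~30% censoring.
    """

    n_samples: int = 332
    target_median_density: float = 40.6  # vessels/mm²
    density_log_sigma: float = 1.0  # lognormal spread across samples
    small_cap_fraction: float = 0.75
    zero_vessel_fraction: float = 0.379
    tissue_area: float = 1.571  # mm², two 1-mm cylinders per sample
    covariate_prevalences: dict = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES)
    )
    hazard_log_ratios: dict = field(default_factory=lambda: dict(DEFAULT_HAZARDS))
    baseline_hazard: float = 0.0015  # events/month; pooled 5-yr EFS ~60-70%
    censoring_rate: float = 0.30
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        probs = [
            self.zero_vessel_fraction,
            self.censoring_rate,
            self.small_cap_fraction,
            *self.covariate_prevalences.values(),
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.target_median_density <= 0 or self.tissue_area <= 0:
            raise ValueError("density target and tissue area must be positive")

    def class_fractions(self) -> dict[str, float]:
        rest = {k: v for k, v in DEFAULT_CLASS_FRACTIONS.items() if k != "small_cap"}
        scale = (1.0 - self.small_cap_fraction) / sum(rest.values())
        out = {"small_cap": self.small_cap_fraction}
        out.update({k: v * scale for k, v in rest.items()})
        return out


# ---------------------------------------------------------------------------
# vessel shapes


def _feret_of(points: np.ndarray) -> float:
    if len(points) < 3:
        return float(np.linalg.norm(points.max(0) - points.min(0)))
    hull = points[ConvexHull(points).vertices]
    diff = hull[:, None, :] - hull[None, :, :]
    return float(np.sqrt((diff**2).sum(-1)).max())


def generate_vessel_shape(truth: VesselGroundTruth, rng_seed: int) -> np.ndarray:
    """Polygonal lumen-boundary contour (μm) for one vessel.

    The base ellipse is perturbed radially by Fourier modes 2–8 with
    amplitudes scaled by ``irregularity``, then rescaled so the maximum
    Feret diameter equals ``major_axis`` (within discretisation).  When
    ``open_fraction`` > 0, one contiguous arc of that fraction of the
    closed perimeter is removed and an open polyline is returned.
    """
    rng = np.random.default_rng(rng_seed)
    n_pts = max(96, int(np.ceil(np.pi * truth.major_axis / 0.25)))
    theta = np.linspace(0.0, 2 * np.pi, n_pts, endpoint=False)
    a, b = truth.major_axis / 2.0, truth.minor_axis / 2.0
    r = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)

    if truth.irregularity > 0:
        pert = np.zeros_like(theta)
        for k in range(2, 9):
            amp = truth.irregularity * rng.uniform(0.08, 0.25)
            pert += amp * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
        r = r * np.clip(1.0 + pert, 0.25, None)

    pts = np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1)
    pts *= truth.major_axis / _feret_of(pts)

    if truth.open_fraction > 0:
        seg = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)
        total = seg.sum()
        start = rng.uniform(0, total)
        cum = np.concatenate([[0.0], np.cumsum(seg)])[:-1]
        arc_pos = (cum - start) % total
        keep = arc_pos >= truth.open_fraction * total
        # roll so the kept run is contiguous from the gap's end
        first = int(np.argmax(keep & ~np.roll(keep, 1)))
        order = (np.arange(n_pts) + first) % n_pts
        pts = pts[order][keep[order]]

    return pts + np.asarray(truth.center, float)


# ---------------------------------------------------------------------------
# vessel sampling and core rendering


def _sample_length(rng: np.random.Generator, cls: str) -> float:
    lo, hi = CALIBER_BOUNDS[cls]
    if cls == "small_collector":
        hi = 140.0  # observed collector lengths top out well below 200 μm
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi - 1e-6))))


def sample_core_vessels(
    n_vessels: int,
    rng_seed: int,
    class_fractions: dict[str, float] | None = None,
    open_vessel_fraction: float = 0.2,
    core_diameter: float = 1000.0,
    max_attempts: int = 500,
) -> list[VesselGroundTruth]:
    """Sample non-overlapping ground-truth vessels inside a circular core.

    A fraction ``open_vessel_fraction`` of vessels get a broken wall with a
    gap chord of 2–8 μm (a local stain discontinuity).  Placement is by
    rejection sampling of bounding circles; exceeding ``max_attempts`` for
    any vessel raises :class:`PackingError`.
    """
    rng = np.random.default_rng(rng_seed)
    fractions = class_fractions or dict(DEFAULT_CLASS_FRACTIONS)
    classes = list(fractions)
    probs = np.asarray([fractions[c] for c in classes], float)
    probs = probs / probs.sum()

    placed: list[VesselGroundTruth] = []
    radii: list[float] = []
    centers: list[np.ndarray] = []
    core_r = core_diameter / 2.0
    for vid in range(n_vessels):
        cls = classes[int(rng.choice(len(classes), p=probs))]
        major = _sample_length(rng, cls)
        aspect = 1.0 + rng.exponential(0.25)
        minor = max(major / min(aspect, 2.5), 2.0)
        minor = min(minor, major)
        wall = float(rng.uniform(1.5, 3.0 if major < 50 else 5.0))
        irregularity = float(rng.beta(1.5, 4.0))
        open_fraction = 0.0
        if rng.random() < open_vessel_fraction:
            # local stain discontinuity: 2-8 μm chord, never wider than
            # a modest fraction of the vessel itself
            chord = min(rng.uniform(2.0, 8.0), 0.45 * major)
            open_fraction = min(0.35, np.arcsin(min(chord / major, 1.0)) / np.pi)
        bound_r = major / 2.0 + wall + 3.0

        for attempt in range(max_attempts):
            pos = rng.uniform(-core_r + bound_r, core_r - bound_r, size=2)
            if np.hypot(*pos) + bound_r > core_r:
                continue
            if all(
                np.linalg.norm(pos - c) > bound_r + r_
                for c, r_ in zip(centers, radii)
            ):
                break
        else:
            raise PackingError(
                f"could not place vessel {vid} within {max_attempts} attempts"
            )
        centers.append(pos)
        radii.append(bound_r)
        placed.append(
            VesselGroundTruth(
                vessel_id=vid,
                center=(float(pos[0]), float(pos[1])),
                major_axis=major,
                minor_axis=minor,
                wall_thickness=wall,
                irregularity=irregularity,
                open_fraction=open_fraction,
                caliber_class=cls,
            )
        )
    return placed


def ground_truth_table(vessels: list[VesselGroundTruth]) -> pd.DataFrame:
    cols = [
        "vessel_id",
        "center_x",
        "center_y",
        "major_axis",
        "minor_axis",
        "wall_thickness",
        "irregularity",
        "open_fraction",
        "caliber_class",
    ]
    rows = [
        {
            "vessel_id": v.vessel_id,
            "center_x": v.center[0],
            "center_y": v.center[1],
            "major_axis": v.major_axis,
            "minor_axis": v.minor_axis,
            "wall_thickness": v.wall_thickness,
            "irregularity": v.irregularity,
            "open_fraction": v.open_fraction,
            "caliber_class": v.caliber_class,
        }
        for v in vessels
    ]
    return pd.DataFrame(rows, columns=cols)


def render_core_image(
    vessels: list[VesselGroundTruth],
    core_diameter: float = 1000.0,
    pixel_size: float = 0.5,
    rng_seed: int = 0,
    noise_sigma: float = 6.0,
) -> tuple[np.ndarray, pd.DataFrame, float]:
    """Render a TMA core as an 8-bit RGB image plus ground truth.

    Returns ``(image, truth_table, tissue_area_mm2)``.  Vessel walls are
    painted in the stain color outward from each lumen contour; lumens and
    the outside of the core are background-colored; the remaining core is
    counterstained tissue.  Gaussian pixel noise of ``noise_sigma`` grey
    levels is added.  Requires ``pixel_size`` ≤ 1 μm/px so 5 μm lumens span
    at least 5 px.
    """
    if pixel_size > 1.0:
        raise ValueError("pixel_size must be <= 1 μm/px")
    rng = np.random.default_rng(rng_seed)
    pad = 10
    size = int(np.ceil(core_diameter / pixel_size)) + 2 * pad
    cy = cx = size / 2.0

    img = np.empty((size, size, 3), np.float32)
    img[:] = BACKGROUND_RGB
    rr, cc = draw.disk((cy, cx), core_diameter / 2.0 / pixel_size, shape=(size, size))
    img[rr, cc] = TISSUE_RGB
    tissue_px = len(rr)

    def to_px(points_um: np.ndarray) -> np.ndarray:
        # μm (x, y) -> px (row, col); origin at core center
        out = np.empty_like(points_um)
        out[:, 0] = cy + points_um[:, 1] / pixel_size
        out[:, 1] = cx + points_um[:, 0] / pixel_size
        return out

    lumen_px = 0
    for v in vessels:
        closed = dataclasses.replace(v, open_fraction=0.0)
        contour = generate_vessel_shape(closed, rng_seed=rng_seed * 100003 + v.vessel_id)
        center = np.asarray(v.center, float)
        rel = contour - center
        radial = np.linalg.norm(rel, axis=1)
        outer = center + rel * ((radial + v.wall_thickness) / radial)[:, None]

        lumen_poly = to_px(contour)
        outer_poly = to_px(outer)
        rr_o, cc_o = draw.polygon(outer_poly[:, 0], outer_poly[:, 1], shape=(size, size))
        rr_l, cc_l = draw.polygon(lumen_poly[:, 0], lumen_poly[:, 1], shape=(size, size))
        wall = np.zeros((size, size), bool)
        wall[rr_o, cc_o] = True
        wall[rr_l, cc_l] = False

        if v.open_fraction > 0:
            # carve the gap: drop wall pixels inside the removed arc's sector
            seg = np.linalg.norm(np.roll(rel, -1, axis=0) - rel, axis=1)
            total = seg.sum()
            start_i = rng.integers(len(rel))
            cum = (np.concatenate([[0.0], np.cumsum(seg)])[:-1] - seg[:start_i].sum()) % total
            removed = cum < v.open_fraction * total
            ang = np.arctan2(rel[:, 1], rel[:, 0])
            ang_rm = ang[removed]
            wr, wc = np.nonzero(wall)
            px_ang = np.arctan2(
                (wr - cy) * pixel_size - center[1], (wc - cx) * pixel_size - center[0]
            )
            ref = ang_rm[0]
            span = (ang_rm - ref) % (2 * np.pi)
            width = span.max()
            in_gap = ((px_ang - ref) % (2 * np.pi)) <= width
            wall[wr[in_gap], wc[in_gap]] = False

        img[wall] = STAIN_RGB
        img[rr_l, cc_l] = BACKGROUND_RGB  # empty lumen
        lumen_px += len(rr_l)

    if noise_sigma > 0:
        img += rng.normal(0.0, noise_sigma, img.shape).astype(np.float32)
    image = np.clip(img, 0, 255).astype(np.uint8)
    tissue_area_mm2 = (tissue_px - lumen_px) * pixel_size**2 / 1e6
    return image, ground_truth_table(vessels), tissue_area_mm2


# ---------------------------------------------------------------------------
# cohort generation (tabular; no image rendering)

_CLASS_ROUNDNESS_MED = {  # lumen irregularity grows with caliber
    "small_cap": 1.45,
    "intermediate_cap": 2.7,
    "large_cap": 4.0,
    "small_collector": 8.0,
}
_CLASS_BRANCH_RATE = {
    "small_cap": 0.4,
    "intermediate_cap": 0.6,
    "large_cap": 0.9,
    "small_collector": 1.5,
}


@dataclass
class CohortTables:
    per_vessel: pd.DataFrame
    per_sample: pd.DataFrame
    covariates: pd.DataFrame
    survival: pd.DataFrame


def _synthesize_vessel_rows(
    rng: np.random.Generator, sample_ids: np.ndarray, classes: np.ndarray
) -> pd.DataFrame:
    n = len(classes)
    lo = np.array([CALIBER_BOUNDS[c][0] for c in classes])
    hi = np.array(
        [140.0 if c == "small_collector" else CALIBER_BOUNDS[c][1] for c in classes]
    )
    length = np.exp(rng.uniform(np.log(lo), np.log(hi - 1e-6)))
    aspect = 1.0 + rng.exponential(0.3, n)
    aspect = np.minimum(aspect, 3.0)
    width = length / aspect
    fill = rng.uniform(0.7, 1.0, n)
    area = np.pi / 4.0 * length * width * fill
    r_med = np.array([_CLASS_ROUNDNESS_MED[c] for c in classes])
    roundness = 1.0 + (r_med - 1.0) * rng.lognormal(0.0, 0.5, n)
    perimeter = np.sqrt(4.0 * np.pi * area * roundness)
    branch_rate = np.array([_CLASS_BRANCH_RATE[c] for c in classes])
    branching = 2 + rng.poisson(branch_rate)
    deformity = rng.beta(1.5, 6.0, n)
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "region_id": np.arange(n),
            "area": area,
            "length": length,
            "width": width,
            "perimeter": perimeter,
            "roundness": roundness,
            "aspect": aspect,
            "perimeter_ratio": 1.0 + 0.6 * deformity,
            "deformity": deformity,
            "shape_factor": length**2 / (4.0 * area / np.pi),
            "branching": branching,
            "caliber_class": classes,
            "was_closed": rng.random(n) < 0.2,
        }
    )


def generate_cohort(config: SyntheticCohortConfig) -> CohortTables:
    """Generate a full synthetic study: vessels, samples, covariates, survival.

    Total vessel density per stained sample is lognormal with median
    ``target_median_density``; a ``zero_vessel_fraction`` share of samples
    carries no vessel at all (unstained).  Survival times (EFS and OS) are
    exponential with proportional hazards on the configured covariates and
    on the above-median total-density indicator; a ``censoring_rate`` share
    of records is censored uniformly before their event time.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = np.array([f"S{i:04d}" for i in range(n)])

    is_zero = rng.random(n) < config.zero_vessel_fraction
    density = np.exp(
        rng.normal(np.log(config.target_median_density), config.density_log_sigma, n)
    )
    counts = np.maximum(np.round(density * config.tissue_area).astype(int), 1)
    counts[is_zero] = 0

    fractions = config.class_fractions()
    class_names = np.array(list(fractions))
    class_p = np.array([fractions[c] for c in class_names])
    total_vessels = int(counts.sum())
    classes = class_names[rng.choice(len(class_names), total_vessels, p=class_p)]
    vessel_sample = np.repeat(sample_ids, counts)
    per_vessel = _synthesize_vessel_rows(rng, vessel_sample, classes)

    sample_frames = []
    grouped = dict(list(per_vessel.groupby("sample_id", sort=False)))
    for sid in sample_ids:
        sub = grouped.get(sid, per_vessel.iloc[0:0])
        agg = aggregate_sample(sub, tissue_area=config.tissue_area)
        agg.insert(0, "sample_id", sid)
        sample_frames.append(agg)
    per_sample = pd.concat(sample_frames, ignore_index=True)

    cov = {"sample_id": sample_ids}
    for name, prev in config.covariate_prevalences.items():
        cov[name] = (rng.random(n) < prev).astype(int)
    covariates = pd.DataFrame(cov)

    total_density = per_sample.loc[
        per_sample["caliber_class"] == "total", "density"
    ].to_numpy()
    stained = total_density > 0
    med = np.median(total_density[stained]) if stained.any() else 0.0
    high_density = (total_density > med).astype(int)

    records = []
    for endpoint, base in (("EFS", config.baseline_hazard), ("OS", config.baseline_hazard * 0.6)):
        log_hr = np.zeros(n)
        for name, beta in config.hazard_log_ratios.items():
            if name == "high_total_density":
                log_hr += beta * high_density
            elif name in covariates.columns:
                log_hr += beta * covariates[name].to_numpy()
            else:
                raise KeyError(f"unknown hazard covariate {name!r}")
        t_event = rng.exponential(1.0 / (base * np.exp(log_hr)))
        censored = rng.random(n) < config.censoring_rate
        time = np.where(censored, t_event * rng.uniform(0, 1, n), t_event)
        records.append(
            pd.DataFrame(
                {
                    "sample_id": sample_ids,
                    "time_months": time,
                    "event": (~censored).astype(int),
                    "endpoint": endpoint,
                }
            )
        )
    survival = pd.concat(records, ignore_index=True)

    return CohortTables(per_vessel, per_sample, covariates, survival)
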