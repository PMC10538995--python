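"""Synthetic muscle cross-sections and cohorts with planted ground truth.

The simulator emulates a vastus lateralis cross-section imaged at x20: a
Lloyd-relaxed Voronoi tessellation of near-convex myofibers separated by thin
boundaries, fiber types I/IIa/IIx in roughly 46/44/10 proportions, channel
intensities ordered by type (Fp: I > IIa > IIx; NADH: I ~ IIa > IIx),
capillaries at fiber junctions, nuclei at fiber peripheries, additive
Gaussian noise on a uniform background, and optional saturation clipping.
Every planted quantity is returned in a :class:`SectionTruth` so downstream
stages can be scored against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi
from shapely.geometry import Polygon, box
from skimage import draw

from fiberredox.types import ChannelImage, FIBER_TYPES

__all__ = [
    "SectionParams",
    "SectionTruth",
    "CohortEffects",
    "generate_section",
    "generate_cohort",
    "default_cohort_effects",
]

#: Default per-type channel means (a.u. above background). The orderings are
#: what matters (Fp: I > IIa > IIx; NADH: I ~ IIa > IIx; MHC channels high only
#: in the matching type); absolute values are free parameters of the simulator.
DEFAULT_CHANNEL_MEANS: dict[str, dict[str, float]] = {
    "NADH": {"I": 800.0, "IIa": 780.0, "IIx": 520.0},
    "Fp": {"I": 900.0, "IIa": 700.0, "IIx": 450.0},
    "MHC1": {"I": 1000.0, "IIa": 0.0, "IIx": 0.0},
    "MHC2a": {"I": 0.0, "IIa": 1000.0, "IIx": 0.0},
}


@dataclass
class SectionParams:
    """Parameters of one simulated cross-section.

    Defaults reproduce the scale of a recreationally active adult's vastus
    lateralis: ~70 analyzable fibers of ~5,000 µm² mean area, type proportions
    45.9/44.5/9.6 % (I/IIa/IIx), capillaries at fiber junctions giving a
    capillary-to-fiber ratio near 2, and ~780 nuclei/mm².
    """

    n_fibers: int = 70
    image_size: tuple[int, int] = (896, 896)
    pixel_size: float = 0.65  # µm/px at x20
    type_proportions: tuple[float, float, float] = (0.459, 0.445, 0.096)
    channel_means: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CHANNEL_MEANS.items()}
    )
    noise_sd: float = 20.0
    background_level: float = 100.0
    capillary_retention: float = 1.0
    nuclei_per_fiber: float = 3.8
    hybrid_rate: float = 0.02
    saturation_cap: float | None = None
    boundary_px: float = 1.5  # erosion of each Voronoi cell, px
    capillary_diameter_um: float = 2.6
    nucleus_diameter_um: float = 3.9
    capillary_min_separation_um: float = 4.0
    dapi_level: float = 900.0
    cap_level: float = 900.0
    collagen_fraction: float = 0.0075
    collagen_level: float = 800.0
    lloyd_iterations: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        props = np.asarray(self.type_proportions, dtype=float)
        if props.shape != (3,) or np.any(props < 0):
            raise ValueError("type_proportions must be 3 nonnegative fractions")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"type_proportions must sum to 1 (got {props.sum():.12g})"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_fibers < 1:
            raise ValueError("n_fibers must be >= 1")
        h, w = self.image_size
        if h <= 0 or w <= 0:
            raise ValueError("image_size must be positive")
        if h * w < 100 * self.n_fibers:
            raise ValueError(
                f"image of {h}x{w} px cannot host {self.n_fibers} non-overlapping "
                "fibers; enlarge the image or reduce n_fibers"
            )
        if not 0.0 <= self.capillary_retention <= 1.0:
            raise ValueError("capillary_retention must be in [0, 1]")
        if not 0.0 <= self.hybrid_rate < 1.0:
            raise ValueError("hybrid_rate must be in [0, 1)")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if not 0.0 <= self.collagen_fraction <= 1.0:
            raise ValueError("collagen_fraction must be in [0, 1]")


@dataclass
class SectionTruth:
    """Planted ground truth of one simulated section.

    ``fibers`` has one row per fiber: fiber_id, fiber_type (I/IIa/IIx/hybrid),
    mean_nadh / mean_fp (planted background-subtracted means), area_um2 and
    centroid. ``label_map`` assigns each interior pixel its fiber_id (0 =
    background/boundary). Capillary and nucleus coordinates are (x, y) px.
    """

    fibers: pd.DataFrame
    polygons: dict[int, Polygon]
    label_map: np.ndarray
    capillaries: np.ndarray
    nuclei: np.ndarray
    background_level: float
    collagen_mask: np.ndarray
    params: SectionParams

    def true_redox_ratio(self, fiber_id: int) -> float:
        row = self.fibers.loc[self.fibers.fiber_id == fiber_id].iloc[0]
        return float(row.mean_fp / (row.mean_fp + row.mean_nadh))

    def fiber_mask(self, fiber_id: int) -> np.ndarray:
        return self.label_map == fiber_id


def _bounded_voronoi(points: np.ndarray, width: float, height: float):
    """Voronoi diagram of ``points`` with cells clipped to [0,w]x[0,h].

    Cells are bounded by mirroring the generators across all four image edges,
    a standard trick that makes every real cell finite.
    """
    mirrored = [points]
    for refl in (
        np.column_stack([-points[:, 0], points[:, 1]]),
        np.column_stack([2 * width - points[:, 0], points[:, 1]]),
        np.column_stack([points[:, 0], -points[:, 1]]),
        np.column_stack([points[:, 0], 2 * height - points[:, 1]]),
    ):
        mirrored.append(refl)
    vor = Voronoi(np.vstack(mirrored))
    rect = box(0.0, 0.0, width, height)
    cells = []
    for i in range(len(points)):
        region = vor.regions[vor.point_region[i]]
        poly = Polygon(vor.vertices[region]).intersection(rect)
        cells.append(poly)
    return cells, vor


def _junction_vertices(vor: Voronoi, n_real: int, width: float, height: float,
                       margin: float) -> np.ndarray:
    """Voronoi vertices shared by >= 2 real cells, inside the image margin."""
    counts: dict[int, int] = {}
    for i in range(n_real):
        for v in vor.regions[vor.point_region[i]]:
            if v >= 0:
                counts[v] = counts.get(v, 0) + 1
    idx = [v for v, c in counts.items() if c >= 2]
    verts = vor.vertices[idx]
    keep = (
        (verts[:, 0] >= margin)
        & (verts[:, 0] <= width - margin)
        & (verts[:, 1] >= margin)
        & (verts[:, 1] <= height - margin)
    )
    return verts[keep]


def _rasterize(poly: Polygon, shape: tuple[int, int]) -> np.ndarray | None:
    """Interior pixel coordinates (n, 2) of a polygon, or None if empty."""
    if poly.is_empty or poly.area <= 0:
        return None
    if poly.geom_type == "MultiPolygon":
        poly = max(poly.geoms, key=lambda g: g.area)
    xs, ys = poly.exterior.coords.xy
    rr, cc = draw.polygon(np.asarray(ys), np.asarray(xs), shape=shape)
    if len(rr) == 0:
        return None
    return np.column_stack([rr, cc])


def generate_section(params: SectionParams) -> tuple[dict[str, ChannelImage], SectionTruth]:
    """Simulate one multichannel section and its planted ground truth.

    Returns a dict of channel label -> :class:`ChannelImage` for the channels
    NADH, Fp, MHC1, MHC2a, DAPI, CAP and COLLAGEN, plus a
    :class:`SectionTruth`. Deterministic for fixed ``params`` (the seed lives
    inside ``params``).
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_size
    px = params.pixel_size

    # --- tessellation: Lloyd-relaxed Voronoi, eroded for visible boundaries
    margin = 2.0
    pts = np.column_stack(
        [rng.uniform(margin, w - margin, params.n_fibers),
         rng.uniform(margin, h - margin, params.n_fibers)]
    )
    for _ in range(params.lloyd_iterations):
        cells, _ = _bounded_voronoi(pts, w, h)
        pts = np.array([[c.centroid.x, c.centroid.y] for c in cells])
    cells, vor = _bounded_voronoi(pts, w, h)

    label_map = np.zeros((h, w), dtype=np.int32)
    polygons: dict[int, Polygon] = {}
    fiber_rows = []
    fiber_coords: dict[int, np.ndarray] = {}
    fid = 0
    for cell in cells:
        eroded = cell.buffer(-params.boundary_px)
        coords = _rasterize(eroded, (h, w))
        if coords is None:
            continue
        fid += 1
        if eroded.geom_type == "MultiPolygon":
            eroded = max(eroded.geoms, key=lambda g: g.area)
        polygons[fid] = eroded
        fiber_coords[fid] = coords
        label_map[coords[:, 0], coords[:, 1]] = fid

    # --- fiber types: a small hybrid rate, then the planted I/IIa/IIx mixture
    n = len(polygons)
    is_hybrid = rng.random(n) < params.hybrid_rate
    types = rng.choice(FIBER_TYPES, size=n, p=np.asarray(params.type_proportions))
    types = np.where(is_hybrid, "hybrid", types)

    means = {ch: dict(v) for ch, v in params.channel_means.items()}

    def _mean(ch: str, t: str) -> float:
        if t == "hybrid":
            if ch in ("MHC1", "MHC2a"):  # co-expression of both isoforms
                return max(means[ch].values())
            return 0.5 * (means[ch]["I"] + means[ch]["IIa"])
        return means[ch][t]

    for i, fid_ in enumerate(sorted(polygons)):
        coords = fiber_coords[fid_]
        c = coords.mean(axis=0)
        fiber_rows.append(
            dict(
                fiber_id=fid_,
                fiber_type=types[i],
                mean_nadh=_mean("NADH", types[i]),
                mean_fp=_mean("Fp", types[i]),
                area_um2=len(coords) * px**2,
                centroid_x=float(c[1]),
                centroid_y=float(c[0]),
            )
        )
    fibers = pd.DataFrame(fiber_rows)

    # --- capillaries at fiber junctions, thinned by retention + min separation
    junctions = _junction_vertices(vor, params.n_fibers, w, h,
                                   margin=params.capillary_diameter_um / px)
    order = rng.permutation(len(junctions))
    min_sep_px = params.capillary_min_separation_um / px
    kept: list[np.ndarray] = []
    for j in order:
        if rng.random() >= params.capillary_retention:
            continue
        v = junctions[j]
        if any(np.hypot(*(v - k)) < min_sep_px for k in kept):
            continue
        kept.append(v)
    capillaries = np.array(kept).reshape(-1, 2)

    # --- nuclei at fiber peripheries, non-overlapping
    nuc_r_px = params.nucleus_diameter_um / px / 2.0
    nuclei_pts: list[np.ndarray] = []
    for fid_ in sorted(polygons):
        k = rng.poisson(params.nuclei_per_fiber)
        ring = polygons[fid_].exterior
        placed = 0
        attempts = 0
        while placed < k and attempts < 20 * max(k, 1):
            attempts += 1
            p = ring.interpolate(rng.random() * ring.length)
            cand = np.array([p.x, p.y])
            if all(np.hypot(*(cand - q)) >= 2.5 * nuc_r_px for q in nuclei_pts):
                nuclei_pts.append(cand)
                placed += 1
    nuclei = np.array(nuclei_pts).reshape(-1, 2)

    # --- collagen: an exact planted fraction of tissue pixels stained
    tissue = label_map > 0
    tissue_idx = np.flatnonzero(tissue.ravel())
    k_collagen = int(round(params.collagen_fraction * len(tissue_idx)))
    stained = rng.choice(tissue_idx, size=k_collagen, replace=False)
    collagen_mask = np.zeros((h, w), dtype=bool)
    collagen_mask.ravel()[stained] = True

    # --- render channels
    def _disc_image(points_xy: np.ndarray, radius_px: float, level: float) -> np.ndarray:
        img = np.zeros((h, w))
        for x, y in points_xy:
            rr, cc = draw.disk((y, x), radius_px, shape=(h, w))
            img[rr, cc] = level
        return img

    signal: dict[str, np.ndarray] = {}
    for ch in ("NADH", "Fp", "MHC1", "MHC2a"):
        img = np.zeros((h, w))
        for row in fiber_rows:
            coords = fiber_coords[row["fiber_id"]]
            img[coords[:, 0], coords[:, 1]] = _mean(ch, row["fiber_type"])
        signal[ch] = img
    signal["DAPI"] = _disc_image(nuclei, nuc_r_px, params.dapi_level)
    signal["CAP"] = _disc_image(capillaries, params.capillary_diameter_um / px / 2.0,
                                params.cap_level)
    signal["COLLAGEN"] = np.where(collagen_mask, params.collagen_level, 0.0)

    images: dict[str, ChannelImage] = {}
    for ch, img in signal.items():
        img = img + params.background_level
        if params.noise_sd > 0:
            img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
        img = np.clip(img, 0.0, params.saturation_cap)
        images[ch] = ChannelImage(img, channel=ch, pixel_size=px)

    truth = SectionTruth(
        fibers=fibers,
        polygons=polygons,
        label_map=label_map,
        capillaries=capillaries,
        nuclei=nuclei,
        background_level=params.background_level,
        collagen_mask=collagen_mask,
        params=params,
    )
    return images, truth


# ---------------------------------------------------------------------------
# Cohort-level simulation for the inference layer
# ---------------------------------------------------------------------------

@dataclass
class CohortEffects:
    """Planted additive effects of a simulated cohort.

    outcome = grand_mean + fiber_type_effect + time_effect
              + sex_effect(if male) + subject_intercept + residual,
    with subject_intercept ~ N(0, subject_sd^2), residual ~ N(0, residual_sd^2).
    This is exactly the additive structure the mixed-model layer assumes.
    """

    grand_mean: float
    fiber_type_effects: Mapping[str, float]
    time_effects: Mapping[str, float]
    subject_sd: float
    residual_sd: float
    sex_effect: float = 0.0

    def __post_init__(self) -> None:
        if self.subject_sd < 0 or self.residual_sd < 0:
            raise ValueError("variance components must be >= 0")

    def cell_mean(self, fiber_type: str, timepoint: str, sex: str = "F") -> float:
        return (
            self.grand_mean
            + self.fiber_type_effects[fiber_type]
            + self.time_effects[timepoint]
            + (self.sex_effect if sex == "M" else 0.0)
        )


def default_cohort_effects(
    baseline_ratio: float = 0.47,
    pct_i_vs_iia: float = 7.2,
    pct_iia_vs_iix: float = 8.0,
    subject_sd: float = 0.03,
    residual_sd: float = 0.02,
) -> CohortEffects:
    """Effects mimicking the baseline fiber-type redox gradient.

    Type IIa is the reference level; type I sits ``pct_i_vs_iia`` percent above
    it and type IIx sits ``pct_iia_vs_iix`` percent below it, so the percent
    differences of the marginal means equal the requested values exactly.
    """
    t_iia = 0.0
    t_i = baseline_ratio * pct_i_vs_iia / 100.0
    t_iix = baseline_ratio * (1.0 / (1.0 + pct_iia_vs_iix / 100.0) - 1.0)
    return CohortEffects(
        grand_mean=baseline_ratio,
        fiber_type_effects={"I": t_i, "IIa": t_iia, "IIx": t_iix},
        time_effects={"baseline": 0.0, "post": 0.0, "post3h": 0.0},
        subject_sd=subject_sd,
        residual_sd=residual_sd,
    )


def generate_cohort(
    n_subjects: int,
    timepoints: Sequence[str],
    effects: CohortEffects,
    seed: int,
    fiber_types: Sequence[str] = FIBER_TYPES,
    outcome: str = "redox_ratio",
    missing_rate: float = 0.0,
) -> tuple[pd.DataFrame, CohortEffects]:
    """Simulate per-subject, per-timepoint, per-fiber-type outcomes.

    Returns a long table with columns subject_id, sex, timepoint, fiber_type,
    outcome, value, n_fibers, together with the planted ``effects`` (the
    ground truth). ``missing_rate`` deletes cells completely at random,
    mimicking histology allocation driven by biopsy yield.
    """
    if n_subjects < 2:
        raise ValueError("need >= 2 subjects")
    if len(timepoints) < 1:
        raise ValueError("need >= 1 timepoint")
    for tp in timepoints:
        if tp not in effects.time_effects:
            raise ValueError(f"no planted time effect for {tp!r}")
    rng = np.random.default_rng(seed)
    intercepts = rng.normal(0.0, effects.subject_sd, size=n_subjects)
    sexes = ["M" if i % 2 == 0 else "F" for i in range(n_subjects)]
    rows = []
    for i in range(n_subjects):
        sid = f"S{i + 1:02d}"
        for tp in timepoints:
            for ft in fiber_types:
                eps = rng.normal(0.0, effects.residual_sd)
                value = effects.cell_mean(ft, tp, sexes[i]) + intercepts[i] + eps
                n_fib = max(1, int(round(rng.normal(65.0, 10.0))))
                rows.append(
                    dict(subject_id=sid, sex=sexes[i], timepoint=tp,
                         fiber_type=ft, outcome=outcome, value=value,
                         n_fibers=n_fib)
                )
    data = pd.DataFrame(rows)
    if missing_rate > 0:
        keep = rng.random(len(data)) >= missing_rate
        data = data.loc[keep].reset_index(drop=True)
    return data, effects
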