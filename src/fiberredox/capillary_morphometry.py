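"""Capillarization morphometry: detection, contact graph, panel, diffusion distances.

Panel definitions follow standard muscle morphometry: capillary density (CD,
capillaries/mm2), capillary-to-fiber ratio (C:F), mean capillary contacts per
fiber (CC), sharing factor (SF = CC / C:F), contacts per fiber area (CC/FA,
x1,000), and O2 diffusion distances defined geometrically: the maximal
(average) diffusion distance is the radius within which 95% (50%) of a
fiber's area is served by its nearest capillary. The geometric definition is
primary; a legacy regression form on C:F and fiber area can be enabled
explicitly through configured coefficients, and is always reported alongside,
never in place of, the geometric estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Point
from shapely.strtree import STRtree
from skimage import measure

from fiberredox.types import ChannelImage, FiberROI

__all__ = [
    "CapillaryMap",
    "CapillaryPanel",
    "DiffusionRegressionCoefficients",
    "detect_capillaries",
    "build_contact_graph",
    "capillary_panel",
    "diffusion_distances_geometric",
    "diffusion_distances_regression",
    "nuclei_count",
]


@dataclass
class CapillaryMap:
    """Capillary coordinates, the capillary-fiber contact graph, and the
    analyzed area.

    ``edges`` is a list of (capillary_index, fiber_id) pairs; an edge exists
    when the capillary center lies within the contact tolerance of the fiber
    boundary (or inside the fiber). ``area_mm2`` is the analyzed section area.
    """

    capillaries: np.ndarray  # (n, 2) of (x, y) px
    edges: list[tuple[int, int]]
    area_mm2: float
    fiber_ids: list[int]

    def __post_init__(self) -> None:
        if self.area_mm2 <= 0:
            raise ValueError("analyzed area must be > 0")
        fiber_set = set(self.fiber_ids)
        n_cap = len(self.capillaries)
        for c, f in self.edges:
            if not (0 <= c < n_cap) or f not in fiber_set:
                raise ValueError(f"edge ({c}, {f}) references a missing node")

    def capillary_degree(self) -> np.ndarray:
        deg = np.zeros(len(self.capillaries), dtype=int)
        for c, _ in self.edges:
            deg[c] += 1
        return deg

    def fiber_degree(self) -> dict[int, int]:
        deg = {f: 0 for f in self.fiber_ids}
        for _, f in self.edges:
            deg[f] += 1
        return deg


@dataclass
class CapillaryPanel:
    """Section-level capillarization morphometrics (units per muscle-morphometry
    convention: densities /mm2, distances µm, areas µm2)."""

    capillary_density: float
    cf_ratio: float
    cc: float
    sharing_factor: float  # NaN when C:F = 0
    cc_per_fa: float
    max_dd: float
    avg_dd: float
    nuclei_density: float = float("nan")
    max_dd_regression: float = float("nan")
    avg_dd_regression: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def detect_capillaries(
    cap_channel: ChannelImage,
    *,
    threshold: float | None = None,
    min_diameter_um: float = 2.0,
    max_diameter_um: float = 8.0,
) -> np.ndarray:
    """Detect capillaries as small bright blobs; returns (n, 2) (x, y) px.

    Connected bright regions whose equivalent diameter falls in the configured
    size window yield one centroid each. A region up to twice the maximum
    diameter is kept as a single detection with a warning (two capillaries
    merged within the resolution limit); larger regions are rejected.
    """
    img = cap_channel.pixels
    if threshold is None:
        from skimage.filters import threshold_otsu

        if img.max() <= img.min():
            return np.empty((0, 2))
        threshold = float(threshold_otsu(img))
    binary = img > threshold
    labels, n = ndimage.label(binary)
    if n == 0:
        return np.empty((0, 2))
    coords = []
    px = cap_channel.pixel_size
    for region in measure.regionprops(labels):
        d_um = region.equivalent_diameter_area * px
        if min_diameter_um <= d_um <= max_diameter_um:
            coords.append((region.centroid[1], region.centroid[0]))
        elif max_diameter_um < d_um <= 2.0 * max_diameter_um:
            warnings.warn(
                f"blob of equivalent diameter {d_um:.1f} µm exceeds the single-"
                "capillary size window; counting as one (possibly merged) "
                "detection"
            )
            coords.append((region.centroid[1], region.centroid[0]))
    return np.array(coords).reshape(-1, 2)


def build_contact_graph(
    fibers: list[FiberROI],
    capillaries: np.ndarray,
    contact_tolerance_um: float = 1.5,
    *,
    area_mm2: float | None = None,
    pixel_size: float | None = None,
) -> CapillaryMap:
    """Contact graph: edge (c, f) iff capillary c lies within
    ``contact_tolerance_um`` of fiber f's boundary (0 distance if inside).

    When no explicit ``area_mm2`` is given, the analyzed area is the convex
    hull of the fibers (the empty margins of the field are not "analyzed
    area") and capillaries outside that hull are dropped, so densities divide
    counts and area of the same region.
    """
    if contact_tolerance_um < 0:
        raise ValueError("contact tolerance must be >= 0")
    if pixel_size is None:
        if not fibers:
            raise ValueError("need fibers or an explicit pixel_size")
        pixel_size = _infer_pixel_size(fibers)
    tol_px = contact_tolerance_um / pixel_size
    capillaries = np.asarray(capillaries, dtype=float).reshape(-1, 2)
    if area_mm2 is None:
        hull = analyzed_hull(fibers)
        area_mm2 = hull.area * pixel_size**2 / 1e6
        if len(capillaries):
            keep = np.array([hull.distance(Point(x, y)) <= tol_px
                             for x, y in capillaries])
            capillaries = capillaries[keep]
    polys = [f.polygon for f in fibers]
    edges: list[tuple[int, int]] = []
    if polys and len(capillaries):
        tree = STRtree(polys)
        for ci, (x, y) in enumerate(capillaries):
            pt = Point(x, y)
            for pi in tree.query(pt.buffer(tol_px + 1e-9)):
                if polys[pi].distance(pt) <= tol_px:
                    edges.append((ci, fibers[pi].fiber_id))
    return CapillaryMap(
        capillaries=capillaries,
        edges=sorted(edges),
        area_mm2=area_mm2,
        fiber_ids=[f.fiber_id for f in fibers],
    )


def _infer_pixel_size(fibers: list[FiberROI]) -> float:
    f = fibers[0]
    return float(np.sqrt(f.area_um2 / len(f.coords)))


def analyzed_hull(fibers: list[FiberROI]):
    """Convex hull of the fibers' polygons (pixel units)."""
    from shapely.ops import unary_union

    if not fibers:
        raise ValueError("no fibers")
    return unary_union([f.polygon for f in fibers]).convex_hull


def analyzed_area_mm2(fibers: list[FiberROI], pixel_size: float) -> float:
    """Convex hull of the fibers' polygons, in mm2."""
    return analyzed_hull(fibers).area * pixel_size**2 / 1e6


def points_in_analyzed_region(points: np.ndarray,
                              fibers: list[FiberROI]) -> np.ndarray:
    """Subset of (x, y) points lying inside the fibers' convex hull.

    Use this to restrict nucleus (or capillary) counts to the same region
    whose area normalizes the densities.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(points) == 0:
        return points
    hull = analyzed_hull(fibers)
    keep = np.array([hull.covers(Point(x, y)) for x, y in points])
    return points[keep]


def capillary_panel(
    cap_map: CapillaryMap,
    fibers: list[FiberROI],
    *,
    n_nuclei: int | None = None,
) -> CapillaryPanel:
    """Compute the section-level capillarization panel.

    CD = N_cap / area; C:F = N_cap / N_fibers; CC = mean fiber contact degree;
    SF = CC / C:F (missing when no capillaries); CC/FA = mean over fibers of
    (degree / fiber area µm2) x 1,000. A capillary with zero fiber contacts
    (edge of field) still counts in CD and C:F. Diffusion distances are filled
    separately.
    """
    if not fibers:
        raise ValueError("zero fibers")
    n_cap = len(cap_map.capillaries)
    n_fib = len(fibers)
    cd = n_cap / cap_map.area_mm2
    cf = n_cap / n_fib
    deg = cap_map.fiber_degree()
    cc = float(np.mean([deg[f.fiber_id] for f in fibers]))
    sf = cc / cf if cf > 0 else float("nan")
    cc_fa = float(np.mean([deg[f.fiber_id] / f.area_um2 for f in fibers]) * 1000.0)
    nuc_density = (
        n_nuclei / cap_map.area_mm2 if n_nuclei is not None else float("nan")
    )
    return CapillaryPanel(
        capillary_density=cd,
        cf_ratio=cf,
        cc=cc,
        sharing_factor=sf,
        cc_per_fa=cc_fa,
        max_dd=float("nan"),
        avg_dd=float("nan"),
        nuclei_density=nuc_density,
    )


def diffusion_distances_geometric(
    fibers: list[FiberROI] | FiberROI,
    capillaries: np.ndarray,
    image_shape: tuple[int, int],
    pixel_size: float,
) -> tuple[float, float]:
    """Geometric O2 diffusion distances from the distance transform.

    For every interior pixel of the given fiber(s) the Euclidean distance to
    the nearest capillary center is computed; the maximal diffusion distance
    is the 95th percentile of that distribution (95% of fiber area served
    within it) and the average diffusion distance the 50th, both in µm.
    Returns (NaN, NaN) when the section has no capillaries.
    """
    if isinstance(fibers, FiberROI):
        fibers = [fibers]
    capillaries = np.asarray(capillaries, dtype=float).reshape(-1, 2)
    if len(capillaries) == 0:
        return float("nan"), float("nan")
    seed = np.ones(image_shape, dtype=bool)
    cap_rc = np.round(capillaries[:, ::-1]).astype(int)
    cap_rc[:, 0] = np.clip(cap_rc[:, 0], 0, image_shape[0] - 1)
    cap_rc[:, 1] = np.clip(cap_rc[:, 1], 0, image_shape[1] - 1)
    seed[cap_rc[:, 0], cap_rc[:, 1]] = False
    dist = ndimage.distance_transform_edt(seed)
    all_d = np.concatenate([dist[f.coords[:, 0], f.coords[:, 1]] for f in fibers])
    max_dd = float(np.percentile(all_d, 95.0) * pixel_size)
    avg_dd = float(np.percentile(all_d, 50.0) * pixel_size)
    return max_dd, avg_dd


@dataclass
class DiffusionRegressionCoefficients:
    """Coefficients of the legacy regression form dd = a + b * C:F * FA**power.

    The printed source equations for this form are typographically ambiguous,
    so no default coefficients ship with the package: users must supply the
    exact algebraic form from the original source. Until they do, the
    regression estimate is disabled.
    """

    a: float
    b: float
    power: float = 1.0


def diffusion_distances_regression(
    cf_ratio: float,
    mean_fa_um2: float,
    max_coeffs: DiffusionRegressionCoefficients | None = None,
    avg_coeffs: DiffusionRegressionCoefficients | None = None,
) -> tuple[float, float]:
    """Evaluate the configured regression form of the diffusion distances.

    Raises unless coefficients are explicitly configured (see
    :class:`DiffusionRegressionCoefficients`); the result is reported in a
    separate labeled column, never merged with the geometric estimate.
    """
    if max_coeffs is None or avg_coeffs is None:
        raise ValueError(
            "diffusion-distance regression is disabled: supply explicit "
            "coefficients for the exact published functional form (the printed "
            "equations are ambiguous and are not guessed here)"
        )

    def _eval(c: DiffusionRegressionCoefficients) -> float:
        return c.a + c.b * cf_ratio * mean_fa_um2**c.power

    return _eval(max_coeffs), _eval(avg_coeffs)


def nuclei_count(
    dapi: ChannelImage,
    *,
    threshold: float | None = None,
    min_diameter_um: float = 3.0,
    max_diameter_um: float = 10.0,
) -> np.ndarray:
    """Detect DAPI-stained nuclei; returns (n, 2) centroids in (x, y) px."""
    return detect_capillaries(
        dapi,
        threshold=threshold,
        min_diameter_um=min_diameter_um,
        max_diameter_um=max_diameter_um,
    )
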