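"""Core containers shared across the pipeline: channel images and fiber ROIs."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

#: Channel labels understood by the pipeline.
CHANNELS = ("NADH", "Fp", "MHC1", "MHC2a", "DAPI", "CAP", "COLLAGEN", "SDHA", "CS")

#: Fiber-type labels. IIx is defined by double negativity for MHC I and MHC IIa.
FIBER_TYPES = ("I", "IIa", "IIx")


@dataclass
class ChannelImage:
    """One 2-D intensity grid with channel identity and acquisition metadata.

    Parameters
    ----------
    pixels : ndarray
        2-D nonnegative intensity grid in arbitrary units (a.u.).
    channel : str
        Channel label, one of :data:`CHANNELS`.
    pixel_size : float
        Physical pixel size in µm/px.
    exposure : float
        Exposure time in ms. Intensities can only be pooled across images
        acquired with identical exposure and gain.
    gain : float
        Instrument gain (a.u.).
    """

    pixels: np.ndarray
    channel: str
    pixel_size: float
    exposure: float = 1.0
    gain: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        if self.pixels.size == 0:
            raise ValueError("empty image")
        if np.any(self.pixels < 0):
            raise ValueError("intensities must be >= 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class FiberROI:
    """One segmented myofiber region.

    ``coords`` holds interior pixel indices as an (n, 2) array of (row, col);
    ``polygon`` is the fiber outline in pixel units with shapely's (x, y) =
    (col, row) convention. ``area_um2`` is the interior area converted through
    ``pixel_size**2``. Fibers clipped by the field of view carry
    ``touches_border=True`` and are excluded from area/intensity statistics.
    """

    fiber_id: int
    coords: np.ndarray
    polygon: Polygon
    area_um2: float
    centroid: tuple[float, float]
    touches_border: bool = False
    included: bool = True

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.intp)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2 or len(self.coords) == 0:
            raise ValueError("coords must be a nonempty (n, 2) array of (row, col)")
        if self.area_um2 <= 0:
            raise ValueError("area must be > 0")

    @property
    def n_pixels(self) -> int:
        return len(self.coords)

    def interior_values(self, image: ChannelImage) -> np.ndarray:
        """Return the channel intensities of the fiber's interior pixels."""
        h, w = image.shape
        r, c = self.coords[:, 0], self.coords[:, 1]
        if r.min() < 0 or c.min() < 0 or r.max() >= h or c.max() >= w:
            raise ValueError(f"fiber {self.fiber_id} lies outside the image bounds")
        return image.pixels[r, c]


def roi_from_mask(
    fiber_id: int,
    mask: np.ndarray,
    pixel_size: float,
    *,
    image_shape: tuple[int, int] | None = None,
) -> FiberROI:
    """Build a :class:`FiberROI` from a boolean mask.

    The outline polygon is traced with a half-pixel-contour around the mask so
    that interior pixels lie strictly inside it.
    """
    from skimage import measure

    mask = np.asarray(mask, dtype=bool)
    coords = np.argwhere(mask)
    if len(coords) == 0:
        raise ValueError("empty mask")
    shape = image_shape if image_shape is not None else mask.shape
    padded = np.pad(mask, 1)
    contours = measure.find_contours(padded.astype(float), 0.5)
    contour = max(contours, key=len) - 1.0  # undo padding offset
    polygon = Polygon(np.column_stack([contour[:, 1], contour[:, 0]]))
    if not polygon.is_valid:
        polygon = polygon.buffer(0)
    centroid_rc = coords.mean(axis=0)
    touches = bool(
        coords[:, 0].min() == 0
        or coords[:, 1].min() == 0
        or coords[:, 0].max() == shape[0] - 1
        or coords[:, 1].max() == shape[1] - 1
    )
    return FiberROI(
        fiber_id=fiber_id,
        coords=coords,
        polygon=polygon,
        area_um2=float(len(coords)) * pixel_size**2,
        centroid=(float(centroid_rc[1]), float(centroid_rc[0])),
        touches_border=touches,
        included=not touches,
    )
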