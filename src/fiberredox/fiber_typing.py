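"""Myofiber segmentation and MHC-based fiber typing.

Typing follows the standard double-stain positivity rules: positive for MHC I
and negative for MHC IIa -> type I; negative/positive -> type IIa; negative
for both -> type IIx; positive for both -> hybrid, which is excluded from all
downstream statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology, segmentation

from fiberredox.types import ChannelImage, FiberROI, roi_from_mask

__all__ = [
    "FiberTypeCall",
    "segment_fibers",
    "classify_fiber",
    "classify_fibers",
    "auto_threshold",
    "otsu_cutoff",
    "UnimodalDistributionWarning",
]


class UnimodalDistributionWarning(UserWarning):
    """Raised when a positivity threshold cannot be found automatically."""


def otsu_cutoff(values: np.ndarray) -> float:
    """Exact Otsu threshold of a small 1-D sample.

    Scores every midpoint between consecutive sorted values by between-class
    variance and returns the best separator. Unlike histogram-based Otsu this
    is exactly equivariant under positive affine rescaling: otsu_cutoff(a*x+b)
    = a*otsu_cutoff(x) + b for a > 0.
    """
    order = np.sort(np.asarray(values, dtype=float))
    n = len(order)
    if n < 2:
        raise ValueError("need >= 2 values")
    best_var, best_cut = -np.inf, 0.5 * (order[0] + order[-1])
    for i in range(1, n):
        lo, hi = order[:i], order[i:]
        bcv = (i / n) * ((n - i) / n) * (hi.mean() - lo.mean()) ** 2
        if bcv > best_var:
            best_var = bcv
            best_cut = 0.5 * (order[i - 1] + order[i])
    return float(best_cut)


@dataclass
class FiberTypeCall:
    """Type call for one fiber. Hybrids are never included downstream."""

    fiber_id: int
    type: str  # "I" | "IIa" | "IIx" | "hybrid"
    mhc1_score: float
    mhc2a_score: float
    included: bool

    def __post_init__(self) -> None:
        if self.type == "hybrid" and self.included:
            raise ValueError("hybrid fibers must be excluded")


def segment_fibers(
    mhc1: ChannelImage,
    mhc2a: ChannelImage,
    hint: ChannelImage | None = None,
    *,
    min_area_um2: float = 500.0,
    threshold: float | None = None,
    split_touching: bool = True,
    border_margin_px: int = 3,
) -> list[FiberROI]:
    """Segment individual myofibers from co-registered MHC channels.

    Fibers tile the section and are separated by thin dark boundaries, so the
    max-projection of the MHC channels (plus an optional ``hint`` channel such
    as an autofluorescence image, which lights up MHC-double-negative IIx
    fibers) is thresholded, holes are filled, and touching fibers are split by
    a watershed on the distance transform. Fibers clipped by the field of view
    are flagged ``touches_border`` and excluded; regions below
    ``min_area_um2`` are rejected as debris.
    """
    if mhc1.shape != mhc2a.shape:
        raise ValueError(f"channel shapes differ: {mhc1.shape} vs {mhc2a.shape}")
    stack = [mhc1.pixels, mhc2a.pixels]
    if hint is not None:
        if hint.shape != mhc1.shape:
            raise ValueError("hint channel shape differs from MHC channels")
        stack.append(hint.pixels)
    proj = np.max(stack, axis=0)

    if threshold is None:
        threshold = _tissue_threshold(proj)
        if threshold is None:
            return []
    binary = proj > threshold
    if not binary.any():
        return []
    binary = ndimage.binary_fill_holes(binary)
    min_px = max(1, int(round(min_area_um2 / mhc1.pixel_size**2)))

    if split_touching:
        dist = ndimage.distance_transform_edt(binary)
        # markers from h-maxima of the lightly smoothed distance transform:
        # the EDT of a (near-)convex fiber is concave, so one fiber yields one
        # marker (smoothing removes discretization wiggles on the ridge);
        # merged fibers show a neck (a dip deeper than h) and get split
        smooth = ndimage.gaussian_filter(dist, 2.0)
        hmax = morphology.h_maxima(smooth, 2.0)
        markers, _ = ndimage.label(hmax, structure=np.ones((3, 3)))
        labels = segmentation.watershed(-dist, markers, mask=binary)
        # components that received no marker survive as themselves
        orphan = binary & (labels == 0)
        if orphan.any():
            extra, _ = ndimage.label(orphan)
            labels = labels + np.where(extra > 0, extra + labels.max(), 0)
    else:
        labels, _ = ndimage.label(binary)

    rois: list[FiberROI] = []
    fid = 0
    for lab in np.unique(labels):
        if lab == 0:
            continue
        mask = labels == lab
        if mask.sum() < min_px:
            continue
        fid += 1
        roi = roi_from_mask(fid, mask, mhc1.pixel_size)
        h, w = mhc1.shape
        clipped = bool(
            roi.coords[:, 0].min() < border_margin_px
            or roi.coords[:, 1].min() < border_margin_px
            or roi.coords[:, 0].max() >= h - border_margin_px
            or roi.coords[:, 1].max() >= w - border_margin_px
        )
        if clipped:
            roi.touches_border = True
            roi.included = False
        rois.append(roi)
    return rois


def _tissue_threshold(proj: np.ndarray) -> float | None:
    """Tissue/background cutoff for a max-projection of stained channels.

    The projection is generally trimodal — dark boundaries/background, dim
    MHC-double-negative (IIx) fibers, bright MHC-positive fibers — so the
    lowest of the two 3-class Otsu thresholds separates tissue from
    background. Falls back to plain Otsu when the histogram is too coarse for
    three classes; returns None for a constant (blank) image.
    """
    from skimage.filters import threshold_multiotsu, threshold_otsu

    if proj.max() <= proj.min():
        return None
    try:
        return float(threshold_multiotsu(proj, classes=3)[0])
    except ValueError:  # fewer distinct values than classes
        return float(threshold_otsu(proj))


def auto_threshold(
    channel: ChannelImage,
    rois: list[FiberROI],
    *,
    fallback: float | None = None,
    min_separation: float = 2.0,
) -> float:
    """Positivity cutoff separating the bimodal per-ROI median distribution.

    Computes an exact Otsu threshold on the vector of per-ROI median
    intensities: every midpoint between consecutive sorted medians is scored
    by between-class variance and the best separator is returned. This
    small-sample form is exactly equivariant under positive affine rescaling
    of the channel. If the medians do not separate into two groups at least
    ``min_separation`` pooled-SDs apart, the distribution is deemed unimodal:
    a warning is issued and ``fallback`` is returned (error if absent).
    """
    if len(rois) < 2:
        raise ValueError("need >= 2 ROIs to threshold")
    medians = np.array([np.median(r.interior_values(channel)) for r in rois])
    order = np.sort(medians)
    n = len(order)
    best_cut = otsu_cutoff(medians)
    lo = order[order <= best_cut]
    hi = order[order > best_cut]
    if len(lo) > 0 and len(hi) > 0:
        pooled_sd = np.sqrt((np.var(lo) * len(lo) + np.var(hi) * len(hi)) / n)
        separated = bool(
            hi.mean() > lo.mean()
            and (pooled_sd == 0.0
                 or (hi.mean() - lo.mean()) > min_separation * pooled_sd)
        )
    else:
        separated = False
    if not separated:
        warnings.warn(
            "per-ROI median distribution looks unimodal; falling back to the "
            "user-supplied cutoff",
            UnimodalDistributionWarning,
        )
        if fallback is None:
            raise ValueError(
                "no bimodal separation found and no fallback cutoff supplied"
            )
        return float(fallback)
    return float(best_cut)


def classify_fiber(
    roi: FiberROI,
    mhc1: ChannelImage,
    mhc2a: ChannelImage,
    mhc1_cutoff: float,
    mhc2a_cutoff: float,
) -> FiberTypeCall:
    """Assign a fiber type from MHC I / MHC IIa positivity.

    The per-ROI score is the median interior intensity (robust to nucleus
    hotspots). A score exactly at the cutoff counts as negative. Positivity
    pattern (MHC I, MHC IIa): (+,-) -> I, (-,+) -> IIa, (-,-) -> IIx,
    (+,+) -> hybrid, excluded.
    """
    s1 = float(np.median(roi.interior_values(mhc1)))
    s2 = float(np.median(roi.interior_values(mhc2a)))
    pos1, pos2 = s1 > mhc1_cutoff, s2 > mhc2a_cutoff
    if pos1 and pos2:
        ftype, included = "hybrid", False
    elif pos1:
        ftype, included = "I", True
    elif pos2:
        ftype, included = "IIa", True
    else:
        ftype, included = "IIx", True
    included = included and roi.included
    if ftype == "hybrid":
        included = False
    return FiberTypeCall(roi.fiber_id, ftype, s1, s2, included)


def classify_fibers(
    rois: list[FiberROI],
    mhc1: ChannelImage,
    mhc2a: ChannelImage,
    *,
    mhc1_cutoff: float | None = None,
    mhc2a_cutoff: float | None = None,
    fallback: float | None = None,
) -> list[FiberTypeCall]:
    """Classify every ROI, auto-thresholding each MHC channel when no cutoff
    is given."""
    if mhc1_cutoff is None:
        mhc1_cutoff = auto_threshold(mhc1, rois, fallback=fallback)
    if mhc2a_cutoff is None:
        mhc2a_cutoff = auto_threshold(mhc2a, rois, fallback=fallback)
    return [classify_fiber(r, mhc1, mhc2a, mhc1_cutoff, mhc2a_cutoff) for r in rois]
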