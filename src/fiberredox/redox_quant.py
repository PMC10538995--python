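"""Per-fiber intensity quantification and the optical redox ratio.

The redox ratio Fp/(Fp + NADH) compares oxidized flavoprotein (Fp)
autofluorescence against the reduced NADH pool; higher values indicate a more
oxidized cellular state. All intensities are background-subtracted arbitrary
units measured on sections acquired at one standardized exposure/gain; the
module refuses to pool across mismatched acquisitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from fiberredox.types import ChannelImage, FiberROI

__all__ = [
    "FiberRedox",
    "CalibrationSeries",
    "estimate_background",
    "quantify_fiber",
    "redox_ratio",
    "fit_calibration",
    "collagen_fraction",
    "quantify_section",
]


@dataclass
class FiberRedox:
    """Background-subtracted NADH/Fp intensities and redox ratio of one fiber."""

    fiber_id: int
    type: str
    nadh: float
    fp: float
    redox_ratio: float
    saturated: bool = False

    def __post_init__(self) -> None:
        if self.nadh < 0 or self.fp < 0:
            raise ValueError("background-subtracted intensities are floored at 0")
        if not np.isnan(self.redox_ratio) and not 0.0 <= self.redox_ratio <= 1.0:
            raise ValueError("redox ratio must lie in [0, 1]")


@dataclass
class CalibrationSeries:
    """A serial-dilution calibration (e.g., beta-NADH from 1 mM to 0.01 mM).

    ``intensities`` holds one row per concentration level with the replicate
    intensities (triplicates in the reference assay). After fitting, ``slope``
    / ``intercept`` describe the least-squares line of mean intensity on
    concentration, ``r_squared`` its coefficient of determination, and
    ``interassay_cv`` the mean over levels of the replicate CV in percent.
    """

    concentrations: np.ndarray
    intensities: np.ndarray
    slope: float | None = None
    intercept: float | None = None
    r_squared: float | None = None
    interassay_cv: float | None = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be strictly positive")
        if len(np.unique(self.concentrations)) != len(self.concentrations):
            raise ValueError("concentrations must be distinct")
        if self.intensities.shape[0] != len(self.concentrations):
            raise ValueError("one row of replicate intensities per concentration")


def estimate_background(channel: ChannelImage, rois: list[FiberROI],
                        *, dilate_px: int = 2) -> float:
    """Median intensity of pixels outside all fiber ROIs.

    ROIs are dilated by ``dilate_px`` so boundary bleed-through does not
    contaminate the estimate. Raises if the ROIs (after dilation) tile the
    whole image, in which case an explicit background value must be supplied.
    """
    h, w = channel.shape
    fg = np.zeros((h, w), dtype=bool)
    for roi in rois:
        fg[roi.coords[:, 0], roi.coords[:, 1]] = True
    if dilate_px > 0:
        fg = ndimage.binary_dilation(fg, iterations=dilate_px)
    bg = ~fg
    if not bg.any():
        raise ValueError(
            "ROIs tile the whole image; supply an explicit background level"
        )
    if bg.sum() < 0.02 * bg.size:
        warnings.warn(
            "fewer than 2% of pixels lie outside the (dilated) ROIs; the "
            "background estimate may be unreliable"
        )
    return float(np.median(channel.pixels[bg]))


def quantify_fiber(
    channel: ChannelImage,
    roi: FiberROI,
    background: float,
    *,
    statistic: str = "mean",
    saturation_cap: float | None = None,
    reference_exposure: float | None = None,
    reference_gain: float | None = None,
    rescale_factor: float | None = None,
) -> tuple[float, bool]:
    """Background-subtracted interior intensity of one fiber.

    Returns ``(intensity, saturated)`` where intensity = statistic of interior
    pixels minus ``background``, floored at 0 (a.u. cannot be negative; the
    floor event itself is visible as a 0), and ``saturated`` flags any interior
    pixel at ``saturation_cap``. If reference exposure/gain metadata is given
    and differs from the channel's, the function refuses unless an explicit
    ``rescale_factor`` is configured (acquisitions are standardized at the
    microscope, not corrected computationally).
    """
    if reference_exposure is not None and channel.exposure != reference_exposure:
        if rescale_factor is None:
            raise ValueError(
                f"exposure mismatch ({channel.exposure} ms vs reference "
                f"{reference_exposure} ms); refusing to pool without an "
                "explicit rescale_factor"
            )
    if reference_gain is not None and channel.gain != reference_gain:
        if rescale_factor is None:
            raise ValueError(
                f"gain mismatch ({channel.gain} vs reference {reference_gain}); "
                "refusing to pool without an explicit rescale_factor"
            )
    values = roi.interior_values(channel)
    if rescale_factor is not None:
        values = values * rescale_factor
    if statistic == "mean":
        raw = float(values.mean())
    elif statistic == "median":
        raw = float(np.median(values))
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    saturated = bool(saturation_cap is not None and np.any(values >= saturation_cap))
    return max(raw - background, 0.0), saturated


def redox_ratio(fp: float, nadh: float) -> float:
    """Oxidation-to-reduction redox ratio Fp / (Fp + NADH).

    Scale-invariant (ratio(k*fp, k*nadh) = ratio(fp, nadh) for k > 0) and
    bounded in [0, 1]. Returns NaN with a warning when both signals are zero,
    where the ratio is undefined and the fiber should be dropped.
    """
    if fp < 0 or nadh < 0:
        raise ValueError("fp and nadh must be >= 0")
    total = fp + nadh
    if total == 0:
        warnings.warn("Fp + NADH = 0: redox ratio undefined, fiber dropped")
        return float("nan")
    return fp / total


def fit_calibration(series: CalibrationSeries) -> CalibrationSeries:
    """Least-squares fit of the calibration line and the interassay CV.

    Fits mean replicate intensity on concentration; ``r_squared`` is the
    coefficient of determination of that fit, and ``interassay_cv`` is the
    mean over concentration levels of (replicate SD / replicate mean) x 100.
    """
    conc = series.concentrations
    if len(conc) < 3:
        raise ValueError("need >= 3 concentration levels")
    level_means = series.intensities.mean(axis=1)
    fit = stats.linregress(conc, level_means)
    with np.errstate(invalid="ignore", divide="ignore"):
        level_cv = series.intensities.std(axis=1, ddof=1) / series.intensities.mean(axis=1)
    if series.intensities.shape[1] < 2:
        cv = 0.0
    else:
        cv = float(np.nanmean(level_cv) * 100.0)
    series.slope = float(fit.slope)
    series.intercept = float(fit.intercept)
    series.r_squared = float(fit.rvalue**2)
    series.interassay_cv = cv
    return series


def collagen_fraction(
    collagen: ChannelImage,
    tissue_mask: np.ndarray,
    *,
    cutoff: float | None = None,
    background: float = 0.0,
) -> tuple[float, float]:
    """Collagen staining inside the tissue: (relative intensity, area ratio).

    ``stained area`` counts tissue pixels above ``cutoff`` (default: halfway
    between the background and the tissue maximum); the ratio stained/tissue
    lies in [0, 1]. The relative intensity is the background-subtracted mean
    over tissue pixels.
    """
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    if not tissue_mask.any():
        raise ValueError("empty tissue mask")
    vals = collagen.pixels[tissue_mask]
    if cutoff is None:
        cutoff = background + 0.5 * (vals.max() - background)
        if vals.max() <= background:  # nothing above background: nothing stained
            cutoff = np.inf
    stained = vals > cutoff
    ratio = float(stained.sum() / tissue_mask.sum())
    rel_intensity = float(max(vals.mean() - background, 0.0))
    return rel_intensity, ratio


def quantify_section(
    rois: list[FiberROI],
    type_calls,
    nadh: ChannelImage,
    fp: ChannelImage,
    *,
    background_nadh: float | None = None,
    background_fp: float | None = None,
    statistic: str = "mean",
    saturation_cap: float | None = None,
) -> pd.DataFrame:
    """Quantify NADH, Fp and the redox ratio for every included fiber.

    The ratio is computed per fiber and only then summarized (mean-of-ratios,
    not ratio-of-means); the returned frame has one row per fiber with columns
    fiber_id, type, nadh, fp, redox_ratio, saturated, included.
    """
    if background_nadh is None:
        background_nadh = estimate_background(nadh, rois)
    if background_fp is None:
        background_fp = estimate_background(fp, rois)
    calls = {c.fiber_id: c for c in type_calls}
    rows = []
    for roi in rois:
        call = calls.get(roi.fiber_id)
        if call is None:
            continue
        n_val, n_sat = quantify_fiber(nadh, roi, background_nadh,
                                      statistic=statistic,
                                      saturation_cap=saturation_cap)
        f_val, f_sat = quantify_fiber(fp, roi, background_fp,
                                      statistic=statistic,
                                      saturation_cap=saturation_cap)
        if f_val + n_val > 0:
            ratio = redox_ratio(f_val, n_val)
        else:
            ratio = float("nan")
        rows.append(
            dict(fiber_id=roi.fiber_id, type=call.type, nadh=n_val, fp=f_val,
                 redox_ratio=ratio, saturated=n_sat or f_sat,
                 included=call.included and roi.included)
        )
    return pd.DataFrame(rows)
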