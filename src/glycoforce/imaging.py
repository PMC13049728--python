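"""Fluorescence and migration image quantification.

* Corrected total cell fluorescence:
  ``CTCF = integrated density - area * mean background``, with the
  background mean pooled over all background ROIs (per-ROI averaging is
  available via ``background_mode="per_roi"``).
* Scratch-assay quantification: texture-based wound segmentation (windowed
  variance + Otsu threshold + morphological cleanup) and percentage gap
  closure ``100 * (A0 - A_t) / A0`` over a time series of open-area masks.

Images and masks travel as 2-D numpy arrays; TIFF I/O helpers wrap
``tifffile`` for single- and multi-page files.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import closing, footprint_rectangle, opening

from .errors import GlycoforceError

__all__ = [
    "ROISet",
    "CTCFResult",
    "ScratchSeries",
    "WoundSegmentationConfig",
    "ctcf",
    "segment_wound",
    "gap_closure",
    "read_tiff",
    "write_tiff",
]


def read_tiff(path: str | os.PathLike) -> np.ndarray:
    return tifffile.imread(path)


def write_tiff(path: str | os.PathLike, array: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(array))


@dataclass(frozen=True)
class ROISet:
    """An intensity image with a labelled cell-ROI mask (0 = none, 1..n =
    cell ids) and one or more boolean background ROI masks."""

    image: np.ndarray
    cell_rois: np.ndarray
    background_rois: tuple

    def __post_init__(self) -> None:
        img = np.asarray(self.image, dtype=float)
        cells = np.asarray(self.cell_rois)
        bgs = tuple(np.asarray(b, dtype=bool) for b in self.background_rois)
        if cells.shape != img.shape:
            raise GlycoforceError("cell ROI mask shape must match image")
        for b in bgs:
            if b.shape != img.shape:
                raise GlycoforceError("background ROI shape must match image")
            if np.any(b & (cells > 0)):
                raise GlycoforceError("cell and background ROIs must be disjoint")
        object.__setattr__(self, "image", img)
        object.__setattr__(self, "cell_rois", cells)
        object.__setattr__(self, "background_rois", bgs)


@dataclass(frozen=True)
class CTCFResult:
    roi_id: int
    integrated_density: float
    area_px: int
    background_mean: float
    ctcf: float


def ctcf(rois: ROISet, background_mode: str = "pooled") -> list[CTCFResult]:
    """Corrected total cell fluorescence per cell ROI.

    ``integrated density`` is the intensity sum over the ROI, ``area`` its
    pixel count, and the background mean is taken over all background ROIs
    pooled (default) or averaged per ROI.  CTCF may be negative.
    """
    ids = sorted(int(i) for i in np.unique(rois.cell_rois) if i > 0)
    if not ids:
        raise GlycoforceError("no cell ROIs in the labelled mask")
    if not rois.background_rois:
        raise GlycoforceError("need at least one background ROI")
    for j, b in enumerate(rois.background_rois):
        if not b.any():
            raise GlycoforceError(f"background ROI {j} is empty")
    if background_mode == "pooled":
        pooled = np.zeros(rois.image.shape, dtype=bool)
        for b in rois.background_rois:
            pooled |= b
        bg_mean = float(rois.image[pooled].mean())
    elif background_mode == "per_roi":
        bg_mean = float(np.mean([rois.image[b].mean()
                                 for b in rois.background_rois]))
    else:
        raise GlycoforceError(f"unknown background_mode {background_mode!r}")
    out = []
    for i in ids:
        mask = rois.cell_rois == i
        if not mask.any():
            raise GlycoforceError(f"cell ROI {i} is empty")
        integ = float(rois.image[mask].sum())
        area = int(mask.sum())
        out.append(CTCFResult(roi_id=i, integrated_density=integ, area_px=area,
                              background_mean=bg_mean,
                              ctcf=integ - area * bg_mean))
    return out


# ---------------------------------------------------------------------------
# Scratch assay
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WoundSegmentationConfig:
    """Texture segmentation tunables: local-variance window (px), minimum
    wound area (px) and the morphological cleanup footprint (px)."""

    window_px: int = 15
    min_area_px: int = 64
    cleanup_px: int = 5
    #: maximum (low-class variance)/(high-class variance) ratio for the
    #: low-texture class to count as a genuine wound rather than noise
    contrast_max: float = 0.3


def _local_variance(image: np.ndarray, window: int) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    mean = ndimage.uniform_filter(img, size=window, mode="reflect")
    mean_sq = ndimage.uniform_filter(img * img, size=window, mode="reflect")
    return np.maximum(mean_sq - mean * mean, 0.0)


def segment_wound(image: np.ndarray,
                  config: WoundSegmentationConfig | None = None) -> np.ndarray:
    """Cell-free (wound) mask of a phase/fluorescence frame.

    Cells are textured, the open wound is smooth: the windowed-variance
    image is thresholded with Otsu, the low-variance side cleaned up
    morphologically, and the largest connected low-texture component is
    returned.  Invariant under intensity offsets.  Returns an empty mask
    (with a warning) when no low-texture component reaches the minimum area.
    """
    cfg = config or WoundSegmentationConfig()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise GlycoforceError("segment_wound expects a single-channel 2-D frame")
    var = _local_variance(img, cfg.window_px)
    spread = float(var.max() - var.min())
    if spread <= 1e-12 * max(1.0, float(var.max())):
        warnings.warn("frame has uniform texture; returning empty wound mask")
        return np.zeros(img.shape, dtype=bool)
    thresh = threshold_otsu(var)
    low = var < thresh
    if low.any() and low.sum() < low.size:
        # a genuine wound is nearly texture-free; if the "low" class still
        # carries a sizeable share of the texture variance the frame has no
        # smooth region (closed wound)
        if float(var[low].mean()) > cfg.contrast_max * float(var[~low].mean()):
            warnings.warn("no texture-free region found; returning empty "
                          "wound mask")
            return np.zeros(img.shape, dtype=bool)
    foot = footprint_rectangle((cfg.cleanup_px, cfg.cleanup_px))
    low = closing(opening(low, foot), foot)
    labels = cc_label(low, connectivity=2)
    if labels.max() == 0:
        warnings.warn("no low-texture component found; returning empty wound mask")
        return np.zeros(img.shape, dtype=bool)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    biggest = int(sizes.argmax())
    if sizes[biggest] < cfg.min_area_px:
        warnings.warn("largest low-texture component below min area; "
                      "returning empty wound mask")
        return np.zeros(img.shape, dtype=bool)
    return labels == biggest


@dataclass(frozen=True)
class ScratchSeries:
    """Hourly time series of open-wound masks; times in hours starting at 0."""

    times_h: np.ndarray
    open_masks: tuple

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        masks = tuple(np.asarray(m, dtype=bool) for m in self.open_masks)
        if t.size != len(masks):
            raise GlycoforceError("times and masks length mismatch")
        if t.size == 0 or t[0] != 0:
            raise GlycoforceError("first time point must be 0")
        if np.any(np.diff(t) <= 0):
            raise GlycoforceError("times must be strictly increasing")
        shapes = {m.shape for m in masks}
        if len(shapes) > 1:
            raise GlycoforceError("all masks must share one shape")
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "open_masks", masks)


def gap_closure(series: ScratchSeries) -> np.ndarray:
    """Percentage gap closure per time point, ``100 * (A0 - A_t) / A0``.

    Warns when the open masks are not nested (closure would be
    non-monotone), which flags segmentation problems.
    """
    areas = np.array([int(m.sum()) for m in series.open_masks], dtype=float)
    if areas[0] == 0:
        raise GlycoforceError("initial open area is zero")
    closure = 100.0 * (areas[0] - areas) / areas[0]
    for prev, cur in zip(series.open_masks, series.open_masks[1:]):
        if np.any(cur & ~prev):
            warnings.warn("open masks are not nested; closure may be non-monotone")
            break
    return closure
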