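"""Stain separation and region delineation for two-stain RGB sections.

The processing chain mirrors classical color-image histomorphometry:

1. contrast enhancement by the excess-color transformation
   (``2*target - other - other``, clipped to [0, 255]), giving one grey-level
   component per chromogen — blue excess for the vessel stain, red excess for
   the tumor-cell stain;
2. thresholding of each grey component to a binary mask, automatically (Otsu,
   maximum between-class variance over the 8-bit histogram) or with a manual
   per-image threshold override;
3. noise elimination by removing small connected components and (optionally)
   filling holes;
4. delineation of the tissue silhouette, the compact tumor mass
   (morphological closing + hole filling of the tumor-cell mask) and the
   peritumoral region (tissue minus tumor).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.morphology import closing as _closing, disk as _disk_footprint

from .errors import NoTissueError, ShapeError
from .types import RegionPartition, SectionImage

_STRUCT8 = np.ones((3, 3), bool)
_STRUCT4 = ndimage.generate_binary_structure(2, 1)


def excess_channel(image: SectionImage, target: str,
                   weights: Optional[tuple[float, float, float]] = None) -> np.ndarray:
    """Excess-color grey component for one chromogen.

    ``target='blue'`` computes ``clip(2B - R - G, 0, 255)``; ``'red'``
    computes ``clip(2R - G - B, 0, 255)``. ``weights`` optionally replaces the
    (R, G, B) coefficient vector entirely.
    """
    px = image.pixels.astype(np.int32)
    if weights is None:
        if target == "blue":
            weights = (-1.0, -1.0, 2.0)
        elif target == "red":
            weights = (2.0, -1.0, -1.0)
        else:
            raise ValueError(f"unknown excess target {target!r}")
    grey = (weights[0] * px[..., 0] + weights[1] * px[..., 1]
            + weights[2] * px[..., 2])
    return np.clip(grey, 0, 255).astype(np.uint8)


def otsu_threshold(grey: np.ndarray) -> Optional[int]:
    """Otsu's threshold over the 8-bit histogram, or None if constant.

    Exhaustive search over the 256 candidate thresholds for the value ``t``
    maximizing the between-class variance of the split ``grey <= t`` /
    ``grey > t``; the first maximum wins on ties.
    """
    grey = np.asarray(grey)
    hist = np.bincount(grey.ravel().astype(np.uint8), minlength=256).astype(float)
    total = hist.sum()
    if total == 0 or np.count_nonzero(hist) < 2:
        return None
    p = hist / total
    omega = np.cumsum(p)
    mu = np.cumsum(p * np.arange(256))
    mu_total = mu[-1]
    valid = (omega > 0) & (omega < 1)
    sigma_b = np.zeros(256)
    num = (mu_total * omega - mu) ** 2
    den = omega * (1.0 - omega)
    sigma_b[valid] = num[valid] / den[valid]
    return int(np.argmax(sigma_b))


def binarize(grey: np.ndarray, method: str = "otsu",
             threshold: Optional[float] = None) -> np.ndarray:
    """Threshold a grey image: mask is 1 where ``grey > threshold``.

    ``method='fixed'`` requires an explicit threshold (the manual-override
    mode); ``method='otsu'`` selects it automatically. A constant grey image
    in Otsu mode yields an empty mask with a warning, since no foreground is
    detectable.
    """
    grey = np.asarray(grey)
    if grey.size == 0:
        raise ShapeError("grey image is empty")
    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed-threshold binarization needs a threshold")
        return grey > threshold
    if method == "otsu":
        t = otsu_threshold(grey)
        if t is None:
            warnings.warn("constant grey image: no foreground detectable",
                          stacklevel=2)
            return np.zeros(grey.shape, bool)
        return grey > t
    raise ValueError(f"unknown binarization method {method!r}")


def clean_mask(mask: np.ndarray, min_object_px: int = 20,
               fill_holes: bool = False) -> np.ndarray:
    """Noise elimination: drop small 8-connected components, optionally fill holes."""
    if min_object_px < 0:
        raise ValueError("min_object_px must be >= 0")
    mask = np.asarray(mask, bool)
    out = mask.copy()
    if min_object_px > 0 and out.any():
        labels, n = ndimage.label(out, structure=_STRUCT8)
        counts = np.bincount(labels.ravel())
        small = counts < min_object_px
        small[0] = False
        out[small[labels]] = False
    if fill_holes and out.any():
        out = ndimage.binary_fill_holes(out)
    return out


def tissue_region(image: SectionImage, white_cut: int = 235) -> np.ndarray:
    """Tissue silhouette: non-white pixels, hole-filled, largest component.

    A pixel is candidate tissue when its minimum channel is below
    ``white_cut`` (the scanner background is near-white in every channel).
    """
    candidate = image.pixels.min(axis=2) < white_cut
    if not candidate.any():
        raise NoTissueError("no non-white pixels: blank slide")
    filled = ndimage.binary_fill_holes(candidate)
    labels, n = ndimage.label(filled, structure=_STRUCT8)
    if n == 1:
        return filled
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))


def tumor_region(tumor_cell_mask: np.ndarray, closing_radius_px: int = 10,
                 min_area_px: int = 500) -> np.ndarray:
    """Compact tumor mass from the scattered tumor-cell mask.

    Morphological closing with a disc footprint merges nearby positive cells,
    hole filling solidifies the mass, and components below ``min_area_px``
    are discarded. Empty input gives an empty region (control sections).
    """
    mask = np.asarray(tumor_cell_mask, bool)
    if not mask.any():
        return np.zeros(mask.shape, bool)
    if closing_radius_px > 0:
        mask = _closing(mask, _disk_footprint(closing_radius_px)).astype(bool)
    mask = ndimage.binary_fill_holes(mask)
    return clean_mask(mask, min_object_px=min_area_px)


def partition_regions(tissue: np.ndarray, tumor: np.ndarray) -> RegionPartition:
    """Split the tissue into intratumoral and peritumoral regions.

    The tumor mask is clipped to the tissue, and the peritumoral region is
    the remainder, so ``|tumor| + |peritumoral| == |tissue|`` exactly.
    """
    tissue = np.asarray(tissue, bool)
    tumor = np.asarray(tumor, bool)
    if tissue.shape != tumor.shape:
        raise ShapeError("tissue and tumor masks differ in shape")
    tumor_in = tumor & tissue
    return RegionPartition(tissue=tissue, tumor=tumor_in,
                           peritumoral=tissue & ~tumor_in)


@dataclass
class SegmentationParams:
    """Tunable parameters of :func:`segment_section`.

    ``vessel_threshold`` / ``tumor_threshold`` are the manual per-image
    overrides; when None the threshold is chosen by Otsu's method, computed
    over tissue pixels only (``threshold_within_tissue``) and floored at
    ``stain_floor`` so that a section genuinely devoid of one stain does not
    binarize its counterstained tissue as foreground.
    """

    vessel_threshold: Optional[float] = None
    tumor_threshold: Optional[float] = None
    min_vessel_px: int = 20
    min_tumor_cell_px: int = 20
    fill_vessel_holes: bool = False
    closing_radius_px: int = 10
    tumor_min_area_px: int = 500
    white_cut: int = 235
    stain_floor: int = 60
    threshold_within_tissue: bool = True
    use_excess: bool = True  # False thresholds the raw stain channel instead


@dataclass
class SegmentationResult:
    vessel_mask: np.ndarray
    tumor_cell_mask: np.ndarray
    partition: RegionPartition
    vessel_threshold: float
    tumor_threshold: float


def _auto_threshold(grey: np.ndarray, tissue: np.ndarray,
                    params: SegmentationParams) -> float:
    values = grey[tissue] if params.threshold_within_tissue else grey
    t = otsu_threshold(values)
    if t is None:
        return float(params.stain_floor)
    return float(max(t, params.stain_floor))


def segment_section(
    image: SectionImage, params: Optional[SegmentationParams] = None
) -> SegmentationResult:
    """Full per-section segmentation.

    Composes the excess transformation, binarization and noise elimination
    for each stain, then tissue delineation, tumor-mass construction and
    region partitioning. Stain masks are restricted to the tissue.
    """
    params = params or SegmentationParams()
    tissue = tissue_region(image, white_cut=params.white_cut)

    if params.use_excess:
        grey_v = excess_channel(image, "blue")
        grey_t = excess_channel(image, "red")
    else:
        grey_v = image.pixels[..., 2]
        grey_t = image.pixels[..., 0]

    thr_v = (params.vessel_threshold if params.vessel_threshold is not None
             else _auto_threshold(grey_v, tissue, params))
    thr_t = (params.tumor_threshold if params.tumor_threshold is not None
             else _auto_threshold(grey_t, tissue, params))

    vessel = binarize(grey_v, "fixed", thr_v) & tissue
    vessel = clean_mask(vessel, params.min_vessel_px,
                        fill_holes=params.fill_vessel_holes)
    tcell = binarize(grey_t, "fixed", thr_t) & tissue
    tcell = clean_mask(tcell, params.min_tumor_cell_px)

    tregion = tumor_region(tcell, params.closing_radius_px,
                           params.tumor_min_area_px)
    partition = partition_regions(tissue, tregion)
    return SegmentationResult(vessel, tcell, partition, thr_v, thr_t)
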