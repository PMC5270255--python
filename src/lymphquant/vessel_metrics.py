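"""Vessel histomorphometry: LVD, count densities and size-split counts.

Implements the per-region quantification parameters of the assay:
(i) lymphatic vessel density (LVD), the stained-area fraction of the
reference region; (ii) the number of vessel sections per mm^2; (iii) counts
of vessel sections smaller/larger than a percentile-derived size cutoff.
"""
from __future__ import annotations

import warnings
from dataclasses import replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .errors import InsufficientDataError, ShapeError, UndefinedRegionError
from .types import RegionMetrics, RegionPartition, VesselSectionRecord

_STRUCT = {
    8: np.ones((3, 3), bool),
    4: ndimage.generate_binary_structure(2, 1),
}


def _label(mask: np.ndarray, connectivity: int) -> tuple[np.ndarray, int]:
    if connectivity not in _STRUCT:
        raise ValueError("connectivity must be 4 or 8")
    return ndimage.label(np.asarray(mask, bool), structure=_STRUCT[connectivity])


def label_components(mask: np.ndarray, pixel_size_mm: float,
                     connectivity: int = 8) -> list[VesselSectionRecord]:
    """One record per connected vessel profile; areas in mm^2."""
    labels, n = _label(mask, connectivity)
    if n == 0:
        return []
    ids = list(range(1, n + 1))
    counts = np.bincount(labels.ravel())[1:]
    centroids = ndimage.center_of_mass(np.asarray(mask, bool), labels, ids)
    px_area = pixel_size_mm ** 2
    return [
        VesselSectionRecord(
            id=i,
            pixel_count=int(counts[i - 1]),
            area_mm2=float(counts[i - 1]) * px_area,
            centroid=(float(centroids[i - 1][0]), float(centroids[i - 1][1])),
        )
        for i in ids
    ]


def assign_vessels(records: Sequence[VesselSectionRecord], mask: np.ndarray,
                   partition: RegionPartition,
                   connectivity: int = 8) -> list[VesselSectionRecord]:
    """Label each vessel section peritumoral or intratumoral.

    A component is intratumoral iff strictly more than half of its pixels lie
    in the tumor mask; ties go to peritumoral. Components with no tissue
    overlap are excluded with a warning.
    """
    mask = np.asarray(mask, bool)
    if partition.tissue.shape != mask.shape:
        raise ShapeError("partition and vessel mask differ in shape")
    labels, n = _label(mask, connectivity)
    ids = [r.id for r in records]
    if not ids:
        return []
    tumor_overlap = ndimage.sum_labels(partition.tumor, labels, ids)
    tissue_overlap = ndimage.sum_labels(partition.tissue, labels, ids)
    out = []
    for rec, in_tumor, in_tissue in zip(records, tumor_overlap, tissue_overlap):
        if in_tissue == 0:
            warnings.warn(
                f"vessel component {rec.id} has no tissue overlap; excluded",
                stacklevel=2,
            )
            continue
        region = ("intratumoral" if in_tumor > 0.5 * rec.pixel_count
                  else "peritumoral")
        out.append(replace(rec, region=region))
    return out


def lvd(vessel_mask: np.ndarray, region_mask: np.ndarray) -> float:
    """Lymphatic vessel density: vessel area over region area (fraction)."""
    vessel_mask = np.asarray(vessel_mask, bool)
    region_mask = np.asarray(region_mask, bool)
    if vessel_mask.shape != region_mask.shape:
        raise ShapeError("vessel and region masks differ in shape")
    region_px = int(region_mask.sum())
    if region_px == 0:
        raise UndefinedRegionError("LVD undefined on an empty region")
    return float((vessel_mask & region_mask).sum()) / region_px


def count_density(records: Sequence[VesselSectionRecord],
                  region_area_mm2: float,
                  region: Optional[str] = None) -> float:
    """Number of vessel sections per mm^2 of the reference region."""
    if not region_area_mm2 > 0:
        raise UndefinedRegionError("region area must be positive")
    n = sum(1 for r in records if region is None or r.region == region)
    return n / region_area_mm2


def percentile_cutoff(areas_mm2: Sequence[float], q: float = 75.0) -> float:
    """Size cutoff at the q-th percentile (linear interpolation)."""
    areas = np.asarray(list(areas_mm2), float)
    if areas.size == 0:
        raise InsufficientDataError("no vessel areas to take a percentile of")
    if not 0 < q < 100:
        raise ValueError("q must lie strictly between 0 and 100")
    return float(np.percentile(areas, q))


def size_partition_counts(records: Sequence[VesselSectionRecord],
                          cutoff_mm2: float,
                          region_area_mm2: float) -> tuple[float, float]:
    """(small, large) vessel-section counts per mm^2; small means area <= cutoff."""
    if not region_area_mm2 > 0:
        raise UndefinedRegionError("region area must be positive")
    small = sum(1 for r in records if r.area_mm2 <= cutoff_mm2)
    large = len(records) - small
    return small / region_area_mm2, large / region_area_mm2


def region_metrics(records: Sequence[VesselSectionRecord],
                   vessel_mask: np.ndarray, partition: RegionPartition,
                   region: str, pixel_size_mm: float,
                   cutoff_mm2: float) -> RegionMetrics:
    """Assemble all per-region readouts for one section."""
    region_mask = partition.tumor if region == "intratumoral" else partition.peritumoral
    area_mm2 = float(region_mask.sum()) * pixel_size_mm ** 2
    in_region = [r for r in records if r.region == region]
    small, large = size_partition_counts(in_region, cutoff_mm2, area_mm2)
    return RegionMetrics(
        region=region,
        lvd=lvd(vessel_mask, region_mask),
        n_per_mm2=count_density(in_region, area_mm2),
        n_small_per_mm2=small,
        n_large_per_mm2=large,
        cutoff_mm2=cutoff_mm2,
        region_area_mm2=area_mm2,
    )
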