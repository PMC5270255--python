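"""Spatial distribution of vessels relative to the tissue border.

The quantity of interest is the Euclidean distance from each vessel (pixel or
section) to the border of the tissue, summarized as a Parzen (kernel density)
estimate — a normalized distribution with unit area under the curve — plus
point readouts at chosen distances and the maximal reached distance Lmax.

Distances are computed on a per-pixel Euclidean distance map of the tissue
mask. Border pixels are tissue pixels with at least one 4-neighbor outside
the tissue; tissue pixels on the grid edge also count as border (a section
cut at the image edge is not interior tissue).
"""
from __future__ import annotations

import math
import warnings
from typing import Optional, Sequence, Union

import numpy as np
from scipy import ndimage

from .errors import InsufficientDataError, NoTissueError
from .types import SpatialDensity, VesselSectionRecord

_SQRT_2PI = np.sqrt(2.0 * np.pi)

#: lower bound on the kernel bandwidth (mm); applied when the observations
#: are too few or too concentrated for Silverman's rule to give a positive
#: width (e.g. all distances identical).
BANDWIDTH_FLOOR_MM = 1e-3


def border_distance_map(tissue_mask: np.ndarray,
                        pixel_size_mm: float) -> np.ndarray:
    """Euclidean distance (mm) from each tissue pixel to the tissue border.

    Non-tissue pixels are NaN. Border pixels have distance zero.
    """
    tissue = np.asarray(tissue_mask, bool)
    if not tissue.any():
        raise NoTissueError("empty tissue mask")
    padded = np.pad(tissue, 1, constant_values=False)
    interior4 = (padded[:-2, 1:-1] & padded[2:, 1:-1]
                 & padded[1:-1, :-2] & padded[1:-1, 2:])
    border = tissue & ~interior4
    dist = ndimage.distance_transform_edt(~border) * pixel_size_mm
    out = np.where(tissue, dist, np.nan)
    return out


def vessel_distances(
    vessels: Union[np.ndarray, Sequence[VesselSectionRecord]],
    distance_map: np.ndarray,
    mode: str = "pixels",
    connectivity: int = 8,
) -> np.ndarray:
    """Border distances of the vessels, one per pixel or one per section.

    ``pixels`` mode reads the distance map at every vessel pixel; ``sections``
    mode reads it once per connected component, at the component pixel nearest
    its centroid. Vessel pixels falling outside the tissue (NaN on the map)
    are dropped with a warning.
    """
    if mode not in ("pixels", "sections"):
        raise ValueError("mode must be 'pixels' or 'sections'")
    if isinstance(vessels, (list, tuple)) and len(vessels) == 0:
        return np.asarray([], float)
    mask = np.asarray(vessels, bool) if not _is_records(vessels) else None
    if mode == "pixels":
        if mask is None:
            raise ValueError("pixels mode requires a vessel mask")
        vals = distance_map[mask]
        bad = np.isnan(vals)
        if bad.any():
            warnings.warn(f"{int(bad.sum())} vessel pixels outside the tissue "
                          "were dropped", stacklevel=2)
        return vals[~bad]

    if mask is None:
        # records: fall back to the map value at the rounded centroid
        out = []
        dropped = 0
        for rec in vessels:  # type: ignore[union-attr]
            r = int(round(rec.centroid[0]))
            c = int(round(rec.centroid[1]))
            r = min(max(r, 0), distance_map.shape[0] - 1)
            c = min(max(c, 0), distance_map.shape[1] - 1)
            d = distance_map[r, c]
            if np.isnan(d):
                dropped += 1
                continue
            out.append(float(d))
        if dropped:
            warnings.warn(f"{dropped} vessel sections outside the tissue were "
                          "dropped", stacklevel=2)
        return np.asarray(out, float)
    struct = (np.ones((3, 3), bool) if connectivity == 8
              else ndimage.generate_binary_structure(2, 1))
    labels, n = ndimage.label(mask, structure=struct)
    out = []
    dropped = 0
    for i in range(1, n + 1):
        coords = np.argwhere(labels == i)
        centroid = coords.mean(axis=0)
        nearest = coords[np.argmin(((coords - centroid) ** 2).sum(axis=1))]
        d = distance_map[tuple(nearest)]
        if np.isnan(d):
            dropped += 1
            continue
        out.append(float(d))
    if dropped:
        warnings.warn(f"{dropped} vessel sections outside the tissue were "
                      "dropped", stacklevel=2)
    return np.asarray(out, float)


def _is_records(obj) -> bool:
    return (isinstance(obj, (list, tuple)) and len(obj) > 0
            and isinstance(obj[0], VesselSectionRecord))


def silverman_bandwidth(distances: np.ndarray,
                        floor: float = BANDWIDTH_FLOOR_MM) -> float:
    """Silverman's rule 0.9*min(sd, IQR/1.34)*n^(-1/5), floored positive."""
    d = np.asarray(distances, float)
    n = d.size
    if n >= 2:
        sd = float(d.std(ddof=1))
        q75, q25 = np.percentile(d, [75, 25])
        spread = min(sd, (q75 - q25) / 1.34)
        h = 0.9 * spread * n ** (-0.2)
    else:
        h = 0.0
    return max(h, floor)


def parzen_density(distances: Sequence[float],
                   bandwidth_mm: Optional[float] = None,
                   grid: Optional[np.ndarray] = None,
                   mode: str = "pixels") -> SpatialDensity:
    """Parzen estimate of the border-distance distribution.

    Gaussian kernels with reflection at zero: probability mass that a kernel
    places below zero (distances cannot be negative) is folded back, so the
    area under the curve on [0, inf) is one. The default evaluation grid is
    512 points on [0, lmax + 4*bandwidth], wide enough that the truncated
    tail mass stays below the 1e-3 normalization tolerance.
    """
    d = np.asarray(list(distances), float)
    if d.size == 0:
        raise InsufficientDataError("no distance observations")
    if np.any(d < 0):
        raise ValueError("distances must be >= 0")
    h = bandwidth_mm if bandwidth_mm is not None else silverman_bandwidth(d)
    if not h > 0:
        raise ValueError("bandwidth must be positive")
    lmax_mm = float(d.max())
    if grid is None:
        # at least 512 points, refined so the spacing resolves the kernel
        # (trapezoidal integration needs a few nodes per bandwidth)
        upper = lmax_mm + 4.0 * h
        n_pts = int(min(max(512, math.ceil(upper / (0.25 * h)) + 1), 16384))
        grid = np.linspace(0.0, upper, n_pts)
    else:
        grid = np.asarray(grid, float)
    # reflected Gaussian kernel density, evaluated in chunks to bound memory
    dens = np.zeros_like(grid)
    for start in range(0, d.size, 4096):
        chunk = d[start:start + 4096]
        z1 = (grid[:, None] - chunk[None, :]) / h
        z2 = (grid[:, None] + chunk[None, :]) / h
        dens += (np.exp(-0.5 * z1 ** 2) + np.exp(-0.5 * z2 ** 2)).sum(axis=1)
    dens /= d.size * h * _SQRT_2PI
    return SpatialDensity(
        support=grid, density=dens, bandwidth_mm=float(h),
        lmax_mm=lmax_mm, n_obs=int(d.size), mode=mode,
    )


def density_at(sd: SpatialDensity, d_mm: float) -> float:
    """Density value at a given distance; linear interpolation, 0 off-support."""
    if d_mm < 0:
        raise ValueError("distance must be >= 0")
    return float(np.interp(d_mm, sd.support, sd.density, right=0.0))


def lmax(distances: Sequence[float]) -> float:
    """Maximal distance reached by any vessel (mm)."""
    d = np.asarray(list(distances), float)
    if d.size == 0:
        raise InsufficientDataError("no distance observations")
    return float(d.max())
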