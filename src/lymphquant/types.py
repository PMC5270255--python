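"""Shared container types.

Binary masks are plain boolean numpy arrays throughout the package, with the
immunohistochemistry convention that ``True``/1 marks the object of interest
(vessel, tumor cells, or tissue) and ``False``/0 the background.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ShapeError


@dataclass
class SectionMeta:
    """Provenance of one histological section within a study."""

    group: Optional[str] = None
    entity: Optional[str] = None  # one sponge or lymph node
    section: Optional[int] = None  # serial section index within the entity
    slice_thickness_um: Optional[float] = None


@dataclass
class SectionImage:
    """An RGB histological section with a known physical pixel size.

    Parameters
    ----------
    pixels
        ``(rows, cols, 3)`` uint8 array, full-color RGB.
    pixel_size_mm
        Physical edge length of one pixel in millimetres.
    meta
        Group/entity/section bookkeeping.
    """

    pixels: np.ndarray
    pixel_size_mm: float
    meta: SectionMeta = field(default_factory=SectionMeta)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ShapeError("SectionImage expects a (rows, cols, 3) array")
        if self.pixels.shape[0] == 0 or self.pixels.shape[1] == 0:
            raise ShapeError("SectionImage pixel grid is empty")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if not self.pixel_size_mm > 0:
            raise ValueError("pixel_size_mm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class RegionPartition:
    """Disjoint cover of the tissue into tumor and peritumoral regions.

    Invariants: ``tumor ⊆ tissue``; ``peritumoral = tissue & ~tumor``; the two
    regions are disjoint and together cover the tissue exactly.
    """

    tissue: np.ndarray
    tumor: np.ndarray
    peritumoral: np.ndarray

    def __post_init__(self) -> None:
        for name in ("tissue", "tumor", "peritumoral"):
            setattr(self, name, np.asarray(getattr(self, name), bool))
        if not (self.tissue.shape == self.tumor.shape == self.peritumoral.shape):
            raise ShapeError("partition masks must share dimensions")


@dataclass
class VesselSectionRecord:
    """One connected vessel profile in a 2D section."""

    id: int
    pixel_count: int
    area_mm2: float
    centroid: tuple[float, float]  # (row, col), pixel coordinates
    region: Optional[str] = None  # "peritumoral" | "intratumoral"
    border_distance_mm: Optional[float] = None


@dataclass
class RegionMetrics:
    """Histomorphometric readouts for one region of one section."""

    region: str
    lvd: float
    n_per_mm2: float
    n_small_per_mm2: float
    n_large_per_mm2: float
    cutoff_mm2: float
    region_area_mm2: float


@dataclass
class SpatialDensity:
    """Parzen-normalized distribution of vessel distance to the tissue border.

    ``support`` is an ascending grid of distances in mm; ``density`` the
    estimated probability density (mm^-1) on that grid, with trapezoidal area
    within 1e-3 of one. ``mode`` records whether each observation was one
    vessel pixel or one vessel section.
    """

    support: np.ndarray
    density: np.ndarray
    bandwidth_mm: float
    lmax_mm: float
    n_obs: int
    mode: str = "pixels"

    @property
    def auc(self) -> float:
        return float(np.trapezoid(self.density, self.support))


@dataclass
class RigidTransform:
    """Rotation (degrees, about the section centroid) plus translation (px)."""

    rotation_deg: float
    translation: tuple[float, float]  # (d_row, d_col)


@dataclass
class VolumeStack:
    """Aligned serial sections stacked at a known z spacing."""

    sections: list[dict]  # each: {"tissue": mask, "vessel": mask, ["tumor": mask]}
    z_spacing_um: float
    transforms: list[RigidTransform]
    pixel_size_mm: Optional[float] = None

    @property
    def thickness_um(self) -> float:
        return len(self.sections) * self.z_spacing_um


@dataclass
class GroupSummary:
    """Mean ± SEM over the independent entities of one experimental group."""

    group: str
    values: list[float]
    n: int
    mean: float
    sem: Optional[float]  # undefined (None) for n = 1


@dataclass
class ComparisonResult:
    """Two-sample Wilcoxon–Mann–Whitney comparison between groups."""

    groups: tuple[str, str]
    U: float
    p_value: float
    significance: str  # "ns", "*", "**", "***"


def as_bool_mask(mask: Sequence | np.ndarray) -> np.ndarray:
    """Coerce any 0/1 grid to a boolean mask."""
    return np.asarray(mask).astype(bool)
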