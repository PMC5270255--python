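"""Seeded synthetic two-stain histology sections with exact ground truth.

Real slides in this assay are whole-mount sections double-immunostained for a
lymphatic endothelium marker (LYVE-1, revealed with a blue chromogen) and a
melanoma-cell marker (tyrosinase, pink chromogen) on a hematoxylin
counterstain, scanned over a white background. This module emulates that
measurement setting: a counterstained tissue silhouette (ellipse or polygon)
on a white canvas, vessel profiles rendered as stained rings (the endothelium
is the stained structure, the lumen is not) or filled discs, an optional
compact tumor mass, and i.i.d. per-channel Gaussian noise clipped to [0, 255].

Ground-truth masks are taken from the pre-noise geometry, so every downstream
stage (stain separation, binarization, region delineation, vessel metrics,
border-distance distributions, 3D stacking) can be scored against a known
answer. Identical specs (including the seed) produce bit-identical output.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, GeometryError
from .types import SectionImage, SectionMeta

_STRUCT8 = np.ones((3, 3), bool)


# ---------------------------------------------------------------------------
# geometry descriptors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Ellipse:
    """Filled ellipse: center (row, col), semi-axes (px), in-plane rotation."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    rotation_deg: float = 0.0

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        dr = rr - self.center[0]
        dc = cc - self.center[1]
        th = math.radians(self.rotation_deg)
        u = dr * math.cos(th) + dc * math.sin(th)
        v = -dr * math.sin(th) + dc * math.cos(th)
        a, b = self.semi_axes
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0

    def transformed(self, rotation_deg: float, translation: tuple[float, float],
                    pivot: tuple[float, float]) -> "Ellipse":
        center = _rotate_point(self.center, pivot, rotation_deg)
        center = (center[0] + translation[0], center[1] + translation[1])
        return replace(self, center=center,
                       rotation_deg=self.rotation_deg + rotation_deg)

    def contains_disc(self, center: tuple[float, float], radius: float,
                      margin: float = 1.0) -> bool:
        """Conservative test that a disc lies inside the ellipse."""
        a = self.semi_axes[0] - radius - margin
        b = self.semi_axes[1] - radius - margin
        if a <= 0 or b <= 0:
            return False
        dr = center[0] - self.center[0]
        dc = center[1] - self.center[1]
        th = math.radians(self.rotation_deg)
        u = dr * math.cos(th) + dc * math.sin(th)
        v = -dr * math.sin(th) + dc * math.cos(th)
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0


@dataclass(frozen=True)
class Polygon:
    """Filled simple polygon given by its (row, col) vertices."""

    vertices: tuple[tuple[float, float], ...]

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        from skimage.draw import polygon as _draw_polygon

        verts = np.asarray(self.vertices, float)
        rr, cc = _draw_polygon(verts[:, 0], verts[:, 1], shape)
        out = np.zeros(shape, bool)
        out[rr, cc] = True
        return out

    @property
    def center(self) -> tuple[float, float]:
        verts = np.asarray(self.vertices, float)
        return (float(verts[:, 0].mean()), float(verts[:, 1].mean()))

    def transformed(self, rotation_deg: float, translation: tuple[float, float],
                    pivot: tuple[float, float]) -> "Polygon":
        verts = tuple(
            tuple(np.add(_rotate_point(v, pivot, rotation_deg), translation))
            for v in self.vertices
        )
        return Polygon(verts)


Geometry = Union[Ellipse, Polygon]


def disc(center: tuple[float, float], radius: float) -> Ellipse:
    """A disc is an ellipse with equal semi-axes."""
    return Ellipse(center, (radius, radius))


def _rotate_point(p, pivot, deg: float) -> tuple[float, float]:
    th = math.radians(deg)
    dr = p[0] - pivot[0]
    dc = p[1] - pivot[1]
    return (
        pivot[0] + dr * math.cos(th) - dc * math.sin(th),
        pivot[1] + dr * math.sin(th) + dc * math.cos(th),
    )


# ---------------------------------------------------------------------------
# spec
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VesselSpec:
    """One vessel profile: ring (default) or filled disc."""

    center: tuple[float, float]
    outer_radius_px: float
    wall_thickness_px: float = 2.0
    filled: bool = False


@dataclass(frozen=True)
class StainPalette:
    """RGB triplets mimicking Ferangi Blue / Permanent Red / hematoxylin."""

    vessel: tuple[int, int, int] = (40, 60, 200)
    tumor: tuple[int, int, int] = (230, 90, 150)
    counterstain: tuple[int, int, int] = (200, 170, 210)
    background: tuple[int, int, int] = (245, 245, 245)


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of one synthetic section.

    ``pixel_size_mm`` defaults to 0.005 (5 um per pixel edge), a conventional
    slide-scanner working resolution. ``noise_sd`` is the per-channel standard
    deviation of additive Gaussian noise in 8-bit intensity units.
    """

    seed: int
    canvas: tuple[int, int] = (512, 512)
    pixel_size_mm: float = 0.005
    tissue_geometry: Optional[Geometry] = None
    vessels: tuple[VesselSpec, ...] = ()
    tumor_geometry: Optional[Geometry] = None
    stain: StainPalette = field(default_factory=StainPalette)
    noise_sd: float = 0.0

    def tissue(self) -> Geometry:
        if self.tissue_geometry is not None:
            return self.tissue_geometry
        r, c = self.canvas
        return Ellipse((r / 2.0, c / 2.0), (0.42 * r, 0.42 * c))

    def validate(self) -> None:
        if self.canvas[0] < 64 or self.canvas[1] < 64:
            raise ConfigurationError("canvas dimensions must be >= 64")
        if not self.pixel_size_mm > 0:
            raise ConfigurationError("pixel_size_mm must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        for v in self.vessels:
            if v.outer_radius_px <= 0:
                raise ConfigurationError("vessel outer radius must be positive")


@dataclass
class GroundTruth:
    """Pre-noise geometry of a generated section.

    ``vessel_components`` lists ``(component id, (n, 2) pixel coordinates)``
    for each 8-connected component of the vessel mask.
    """

    vessel_mask: np.ndarray
    tumor_mask: np.ndarray
    tissue_mask: np.ndarray
    vessel_components: list[tuple[int, np.ndarray]]


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _vessel_mask(shape: tuple[int, int], v: VesselSpec) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    d2 = (rr - v.center[0]) ** 2 + (cc - v.center[1]) ** 2
    outer = d2 <= v.outer_radius_px ** 2
    if v.filled or v.wall_thickness_px >= v.outer_radius_px:
        return outer
    inner_r = v.outer_radius_px - v.wall_thickness_px
    return outer & (d2 > inner_r ** 2)


def _check_in_canvas(v: VesselSpec, shape: tuple[int, int]) -> None:
    r, c = v.center
    if (r - v.outer_radius_px < -0.5 or c - v.outer_radius_px < -0.5
            or r + v.outer_radius_px > shape[0] - 0.5
            or c + v.outer_radius_px > shape[1] - 0.5):
        raise GeometryError(
            f"vessel at {v.center} with radius {v.outer_radius_px} exceeds "
            f"the {shape} canvas"
        )


def generate_section(
    spec: SyntheticSpec, meta: Optional[SectionMeta] = None
) -> tuple[SectionImage, GroundTruth]:
    """Render one section and its exact ground truth.

    Layers are painted back to front — white background, counterstained
    tissue, tumor mass, vessel walls — and seeded Gaussian noise is added
    last, clipped to [0, 255]. Ground-truth masks reflect the pre-noise
    geometry.

    Raises
    ------
    GeometryError
        If a vessel or tumor shape extends beyond the canvas, or a vessel is
        not fully contained in the tissue.
    """
    spec.validate()
    shape = tuple(spec.canvas)
    tissue = spec.tissue().mask(shape)
    if not tissue.any():
        raise GeometryError("tissue geometry rasterizes to an empty mask")

    if spec.tumor_geometry is not None:
        tmask = spec.tumor_geometry.mask(shape)
        if not tmask.any():
            raise GeometryError("tumor geometry rasterizes to an empty mask")
        _check_geometry_in_canvas(spec.tumor_geometry, shape)
        tumor = tmask & tissue
    else:
        tumor = np.zeros(shape, bool)

    vessel = np.zeros(shape, bool)
    for v in spec.vessels:
        _check_in_canvas(v, shape)
        m = _vessel_mask(shape, v)
        if (m & ~tissue).any():
            raise GeometryError(f"vessel at {v.center} lies outside the tissue")
        vessel |= m

    pal = spec.stain
    img = np.empty(shape + (3,), float)
    img[:, :] = pal.background
    img[tissue] = pal.counterstain
    img[tumor] = pal.tumor
    img[vessel] = pal.vessel
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    labels, n = ndimage.label(vessel, structure=_STRUCT8)
    components = [(i, np.argwhere(labels == i)) for i in range(1, n + 1)]
    truth = GroundTruth(vessel, tumor, tissue, components)
    image = SectionImage(pixels, spec.pixel_size_mm, meta or SectionMeta())
    return image, truth


def _check_geometry_in_canvas(geom: Geometry, shape: tuple[int, int]) -> None:
    if isinstance(geom, Ellipse):
        r, c = geom.center
        reach = max(geom.semi_axes)
        if (r - reach < -0.5 or c - reach < -0.5
                or r + reach > shape[0] - 0.5 or c + reach > shape[1] - 0.5):
            raise GeometryError("tumor geometry exceeds the canvas")
    else:
        verts = np.asarray(geom.vertices, float)
        if (verts[:, 0].min() < -0.5 or verts[:, 1].min() < -0.5
                or verts[:, 0].max() > shape[0] - 0.5
                or verts[:, 1].max() > shape[1] - 0.5):
            raise GeometryError("tumor geometry exceeds the canvas")


# ---------------------------------------------------------------------------
# serial stacks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Drift:
    """Per-section rigid drift applied cumulatively along a serial stack."""

    translation_px: tuple[float, float] = (0.0, 0.0)  # (d_row, d_col)
    rotation_deg: float = 0.0


@dataclass
class SyntheticStack:
    """Serial sections plus the rigid offsets actually applied to each."""

    sections: list[tuple[SectionImage, GroundTruth]]
    offsets: list[tuple[float, tuple[float, float]]]  # (rotation_deg, (dr, dc))


def _section_seed(seed: int, k: int) -> int:
    if k == 0:
        return seed
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2 ** 31))


def generate_stack(
    spec: SyntheticSpec, n_sections: int, drift: Drift = Drift()
) -> SyntheticStack:
    """Generate serially drifted sections with recorded rigid offsets.

    Section ``k`` carries the base geometry rotated by ``k * rotation_deg``
    about the tissue center and translated by ``k * translation_px``; with
    zero drift and ``n_sections == 1`` the output is identical to
    :func:`generate_section`.
    """
    if n_sections < 1:
        raise ConfigurationError("n_sections must be >= 1")
    base_tissue = spec.tissue()
    pivot = base_tissue.center
    sections = []
    offsets = []
    for k in range(n_sections):
        rot = k * drift.rotation_deg
        tr = (k * drift.translation_px[0], k * drift.translation_px[1])
        tissue_k = base_tissue.transformed(rot, tr, pivot)
        vessels_k = tuple(
            replace(v, center=tuple(np.add(_rotate_point(v.center, pivot, rot), tr)))
            for v in spec.vessels
        )
        tumor_k = (spec.tumor_geometry.transformed(rot, tr, pivot)
                   if spec.tumor_geometry is not None else None)
        spec_k = replace(
            spec,
            seed=_section_seed(spec.seed, k),
            tissue_geometry=tissue_k,
            vessels=vessels_k,
            tumor_geometry=tumor_k,
        )
        meta = SectionMeta(section=k)
        sections.append(generate_section(spec_k, meta))
        offsets.append((rot, tr))
    return SyntheticStack(sections, offsets)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortTemplate:
    """Per-group sampling ranges for a synthetic cohort.

    Each entity (sponge or lymph node) draws its own vessel count and vessel
    sizes from the stated ranges; each of its serial sections jitters the
    vessel centers slightly and receives fresh noise, emulating sections taken
    at different levels of the same specimen.
    """

    canvas: tuple[int, int] = (256, 256)
    pixel_size_mm: float = 0.005
    tissue_geometry: Optional[Geometry] = None
    n_vessels: tuple[int, int] = (8, 16)
    outer_radius_px: tuple[float, float] = (4.0, 10.0)
    wall_thickness_px: tuple[float, float] = (2.0, 3.0)
    section_jitter_px: float = 2.0
    tumor_geometry: Optional[Geometry] = None
    vessels_avoid_tumor: bool = False
    tumor_margin_px: float = 14.0
    noise_sd: float = 5.0
    stain: StainPalette = field(default_factory=StainPalette)
    density_scale: float = 1.0  # multiplies the drawn vessel count


@dataclass(frozen=True)
class GroupSpec:
    n_entities: int
    sections_per_entity: int
    template: CohortTemplate


@dataclass
class CohortRecord:
    group: str
    entity: str
    section: int
    image: SectionImage
    truth: GroundTruth


@dataclass
class Cohort:
    records: list[CohortRecord]

    def manifest(self):
        import pandas as pd

        return pd.DataFrame(
            [{"group": r.group, "entity": r.entity, "section": r.section}
             for r in self.records]
        )


def _tissue_for(template: CohortTemplate) -> Ellipse:
    if template.tissue_geometry is not None:
        if not isinstance(template.tissue_geometry, Ellipse):
            raise ConfigurationError(
                "cohort sampling supports elliptical tissue geometries only"
            )
        return template.tissue_geometry
    r, c = template.canvas
    return Ellipse((r / 2.0, c / 2.0), (0.42 * r, 0.42 * c))


def _sample_entity_vessels(
    template: CohortTemplate, rng: np.random.Generator
) -> list[VesselSpec]:
    tissue = _tissue_for(template)
    lo, hi = template.n_vessels
    n = int(round(rng.integers(lo, hi + 1) * template.density_scale))
    n = max(1, n)
    tumor = template.tumor_geometry
    placed: list[VesselSpec] = []
    for _ in range(n):
        radius = float(rng.uniform(*template.outer_radius_px))
        wall = float(rng.uniform(*template.wall_thickness_px))
        wall = min(wall, radius - 0.5) if radius > 1.0 else radius
        for _try in range(200):
            dr = rng.uniform(-tissue.semi_axes[0], tissue.semi_axes[0])
            dc = rng.uniform(-tissue.semi_axes[1], tissue.semi_axes[1])
            center = (tissue.center[0] + dr, tissue.center[1] + dc)
            if not tissue.contains_disc(center, radius, margin=2.0):
                continue
            if (template.vessels_avoid_tumor and tumor is not None
                    and isinstance(tumor, Ellipse)):
                gap = math.hypot(center[0] - tumor.center[0],
                                 center[1] - tumor.center[1])
                if gap < radius + max(tumor.semi_axes) + template.tumor_margin_px:
                    continue
            if any(math.hypot(center[0] - p.center[0], center[1] - p.center[1])
                   < radius + p.outer_radius_px + 1.0 for p in placed):
                continue
            placed.append(VesselSpec(center, radius, wall))
            break
    return placed


def _jitter_vessels(
    vessels: Sequence[VesselSpec], template: CohortTemplate,
    rng: np.random.Generator,
) -> tuple[VesselSpec, ...]:
    tissue = _tissue_for(template)
    out = []
    for v in vessels:
        d = rng.normal(0.0, template.section_jitter_px, 2)
        cand = (v.center[0] + d[0], v.center[1] + d[1])
        if tissue.contains_disc(cand, v.outer_radius_px, margin=2.0):
            out.append(replace(v, center=cand))
        else:
            out.append(v)
    return tuple(out)


def generate_cohort(
    group_specs: Mapping[str, GroupSpec], seed: int
) -> Cohort:
    """Generate a labeled multi-group cohort of synthetic sections.

    Every entity receives an independent sub-seed derived from the master
    seed, so the same master seed reproduces the cohort bit-for-bit.
    """
    if not group_specs:
        raise ConfigurationError("group_specs mapping is empty")
    records: list[CohortRecord] = []
    for gi, (label, gs) in enumerate(group_specs.items()):
        if gs.n_entities < 1:
            raise ConfigurationError(f"group {label!r} needs >= 1 entity")
        if gs.sections_per_entity < 1:
            raise ConfigurationError(f"group {label!r} needs >= 1 section")
        t = gs.template
        for e in range(gs.n_entities):
            rng = np.random.default_rng(np.random.SeedSequence([seed, gi, e]))
            layout = _sample_entity_vessels(t, rng)
            entity = f"{label}-{e:02d}"
            for s in range(gs.sections_per_entity):
                vessels = _jitter_vessels(layout, t, rng)
                spec = SyntheticSpec(
                    seed=int(rng.integers(2 ** 31)),
                    canvas=t.canvas,
                    pixel_size_mm=t.pixel_size_mm,
                    tissue_geometry=_tissue_for(t),
                    vessels=vessels,
                    tumor_geometry=t.tumor_geometry,
                    stain=t.stain,
                    noise_sd=t.noise_sd,
                )
                meta = SectionMeta(group=label, entity=entity, section=s)
                image, truth = generate_section(spec, meta)
                records.append(CohortRecord(label, entity, s, image, truth))
    return Cohort(records)
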