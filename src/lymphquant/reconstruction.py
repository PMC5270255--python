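"""Serial-section re-orientation and 3D stacking.

Serially cut sections land on slides with arbitrary in-plane placement. To
rebuild a volume, every section is rigidly re-oriented to the first
section's frame — translation to the reference tissue centroid plus rotation
aligning the tissue mask's principal axis — and stacked at a known z
spacing. The 180-degree ambiguity of the principal axis is resolved by
choosing the rotation minimizing the symmetric-difference pixel count with
the previously aligned section. Resampling is nearest-neighbor, so binary
masks stay binary and per-section pixel counts are preserved up to
rasterization error.
"""
from __future__ import annotations

import json
import math
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .errors import AlignmentError, InsufficientDataError, ShapeError
from .types import RigidTransform, VolumeStack

MaskSet = dict  # {"tissue": mask, "vessel": mask, optionally "tumor": mask}

_ENCODE_ORDER = ("tissue", "tumor", "vessel")  # later layers overwrite
_ENCODE_VALUE = {"tissue": 1, "tumor": 3, "vessel": 2}


def _centroid_and_axis(mask: np.ndarray) -> tuple[np.ndarray, float]:
    """Centroid and principal-axis angle (radians, in the row/col plane)."""
    ys, xs = np.nonzero(mask)
    r0, c0 = ys.mean(), xs.mean()
    dr = ys - r0
    dc = xs - c0
    mu20 = (dr ** 2).mean()
    mu02 = (dc ** 2).mean()
    mu11 = (dr * dc).mean()
    angle = 0.5 * math.atan2(2.0 * mu11, mu20 - mu02)
    return np.array([r0, c0]), angle


def apply_rigid(mask: np.ndarray, rotation_deg: float,
                in_center: Sequence[float],
                out_center: Sequence[float]) -> np.ndarray:
    """Rotate about ``in_center`` and move it onto ``out_center`` (nearest-neighbor)."""
    th = math.radians(rotation_deg)
    rot = np.array([[math.cos(th), -math.sin(th)],
                    [math.sin(th), math.cos(th)]])
    inv = rot.T  # inverse rotation, output -> input
    offset = np.asarray(in_center, float) - inv @ np.asarray(out_center, float)
    out = ndimage.affine_transform(
        np.asarray(mask, bool).astype(np.uint8), inv, offset=offset,
        order=0, mode="constant", cval=0,
    )
    return out.astype(bool)


def align_sections(
    mask_sets: Sequence[MaskSet],
) -> tuple[list[MaskSet], list[RigidTransform]]:
    """Rigidly align each section's masks to the first section's frame.

    Returns the aligned mask sets and, per section, the transform that was
    applied (rotation about the section's tissue centroid, then translation
    of that centroid onto the reference centroid).
    """
    if len(mask_sets) == 0:
        raise InsufficientDataError("no sections to align")
    shapes = {m["tissue"].shape for m in mask_sets}
    if len(shapes) != 1:
        raise ShapeError("all sections must share dimensions")
    for i, ms in enumerate(mask_sets):
        if not np.asarray(ms["tissue"], bool).any():
            raise AlignmentError(f"section {i} has an empty tissue mask")

    ref_center, ref_axis = _centroid_and_axis(np.asarray(mask_sets[0]["tissue"], bool))
    aligned: list[MaskSet] = []
    transforms: list[RigidTransform] = []
    prev_tissue: Optional[np.ndarray] = None
    for i, ms in enumerate(mask_sets):
        tissue = np.asarray(ms["tissue"], bool)
        center, axis = _centroid_and_axis(tissue)
        base_deg = math.degrees(ref_axis - axis)
        candidates = [_wrap_angle(base_deg), _wrap_angle(base_deg + 180.0)]
        target = prev_tissue if prev_tissue is not None else tissue
        best_deg, best_tissue, best_cost = None, None, None
        for deg in candidates:
            moved = apply_rigid(tissue, deg, center, ref_center)
            cost = int(np.logical_xor(moved, target).sum())
            if best_cost is None or cost < best_cost:
                best_deg, best_tissue, best_cost = deg, moved, cost
        tf = RigidTransform(
            rotation_deg=float(best_deg),
            translation=(float(ref_center[0] - center[0]),
                         float(ref_center[1] - center[1])),
        )
        out: MaskSet = {"tissue": best_tissue}
        for key, m in ms.items():
            if key == "tissue":
                continue
            out[key] = apply_rigid(np.asarray(m, bool), best_deg, center, ref_center)
        aligned.append(out)
        transforms.append(tf)
        prev_tissue = best_tissue
    return aligned, transforms


def _wrap_angle(deg: float) -> float:
    """Wrap to (-180, 180]."""
    deg = (deg + 180.0) % 360.0 - 180.0
    return 180.0 if deg == -180.0 else deg


def build_stack(aligned_sections: Sequence[MaskSet], z_spacing_um: float,
                pixel_size_mm: Optional[float] = None,
                transforms: Optional[Sequence[RigidTransform]] = None) -> VolumeStack:
    """Stack aligned sections into a volume with known slice spacing."""
    if len(aligned_sections) == 0:
        raise InsufficientDataError("no sections to stack")
    if not z_spacing_um > 0:
        raise ValueError("z_spacing_um must be positive")
    tf = (list(transforms) if transforms is not None
          else [RigidTransform(0.0, (0.0, 0.0)) for _ in aligned_sections])
    return VolumeStack(
        sections=list(aligned_sections),
        z_spacing_um=float(z_spacing_um),
        transforms=tf,
        pixel_size_mm=pixel_size_mm,
    )


def vessel_volume_mm3(stack: VolumeStack) -> float:
    """Vessel volume: sum of per-section vessel areas times the z spacing."""
    if stack.pixel_size_mm is None:
        raise ValueError("stack has no pixel size; pass pixel_size_mm to build_stack")
    px_area = stack.pixel_size_mm ** 2
    z_mm = stack.z_spacing_um / 1000.0
    total_area = sum(float(np.asarray(s["vessel"], bool).sum()) * px_area
                     for s in stack.sections)
    return total_area * z_mm


def encode_labels(section: MaskSet) -> np.ndarray:
    """Encode one section's masks as a uint8 label image (tissue=1, vessel=2, tumor=3)."""
    out = np.zeros(section["tissue"].shape, np.uint8)
    for key in _ENCODE_ORDER:
        if key in section and section[key] is not None:
            out[np.asarray(section[key], bool)] = _ENCODE_VALUE[key]
    return out


def export_stack(stack: VolumeStack, path) -> None:
    """Write the stack as a multi-page TIFF, one label page per section.

    The z spacing (and pixel size, when known) is recorded as JSON in the
    TIFF image description.
    """
    import tifffile

    vol = np.stack([encode_labels(s) for s in stack.sections])
    desc = {"z_spacing_um": stack.z_spacing_um}
    if stack.pixel_size_mm is not None:
        desc["pixel_size_mm"] = stack.pixel_size_mm
    tifffile.imwrite(path, vol, photometric="minisblack",
                     description=json.dumps(desc))


def read_stack(path) -> VolumeStack:
    """Read a stack written by :func:`export_stack`."""
    import tifffile

    with tifffile.TiffFile(path) as tif:
        vol = tif.asarray()
        desc = tif.pages[0].description
    meta = json.loads(desc)
    if vol.ndim == 2:
        vol = vol[None]
    sections = []
    for page in vol:
        sections.append({
            "tissue": page > 0,
            "vessel": page == _ENCODE_VALUE["vessel"],
            "tumor": page == _ENCODE_VALUE["tumor"],
        })
    return build_stack(sections, meta["z_spacing_um"],
                       pixel_size_mm=meta.get("pixel_size_mm"))
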