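"""Reading and writing images, masks and cohort manifests.

Images are 8-bit RGB TIFF or PNG; masks are written as single-channel 0/255
TIFF (or PNG) so they stay viewable in any image tool.
"""
from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np

from .errors import ShapeError
from .types import SectionImage, SectionMeta


def _is_tiff(path: Path) -> bool:
    return path.suffix.lower() in (".tif", ".tiff")


def read_image(path, pixel_size_mm: float,
               meta: Optional[SectionMeta] = None) -> SectionImage:
    """Read an RGB section image from TIFF or PNG."""
    path = Path(path)
    if _is_tiff(path):
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[..., :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ShapeError(f"{path} is not an RGB image")
    return SectionImage(arr.astype(np.uint8), pixel_size_mm,
                        meta or SectionMeta())


def write_image(path, image: SectionImage) -> None:
    path = Path(path)
    if _is_tiff(path):
        import tifffile

        tifffile.imwrite(path, image.pixels, photometric="rgb")
    else:
        import imageio.v3 as iio

        iio.imwrite(path, image.pixels)


def write_mask(path, mask: np.ndarray) -> None:
    """Write a binary mask as a 0/255 single-channel image."""
    path = Path(path)
    data = (np.asarray(mask, bool).astype(np.uint8)) * 255
    if _is_tiff(path):
        import tifffile

        tifffile.imwrite(path, data, photometric="minisblack")
    else:
        import imageio.v3 as iio

        iio.imwrite(path, data)


def read_mask(path) -> np.ndarray:
    path = Path(path)
    if _is_tiff(path):
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 0


def write_cohort(cohort, outdir, image_format: str = "png"):
    """Write cohort images, ground-truth masks and a CSV manifest.

    Returns the manifest DataFrame (columns: group, entity, section, path,
    plus the truth-mask paths).
    """
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort.records:
        stem = f"{rec.group}_{rec.entity}_s{rec.section:03d}"
        img_path = outdir / f"{stem}.{image_format}"
        write_image(img_path, rec.image)
        paths = {}
        for name, mask in (("vessel", rec.truth.vessel_mask),
                           ("tumor", rec.truth.tumor_mask),
                           ("tissue", rec.truth.tissue_mask)):
            p = outdir / f"{stem}_truth_{name}.tif"
            write_mask(p, mask)
            paths[f"truth_{name}"] = p.name
        rows.append({"group": rec.group, "entity": rec.entity,
                     "section": rec.section, "path": img_path.name, **paths})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest
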