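"""Independent oracles and fixture builders shared across the test suite.

Everything here is deliberately written as naive brute force, independent of
the library's implementation path, so the tests check the implementation
against a second route rather than against itself.
"""
from __future__ import annotations

import itertools
import math

import numpy as np

import lymphquant as lq


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * (a & b).sum() / denom


def brute_force_border_distance(tissue: np.ndarray,
                                pixel_size_mm: float) -> np.ndarray:
    """O(N^2) nearest-border scan: per tissue pixel, min over all border px."""
    tissue = np.asarray(tissue, bool)
    rows, cols = tissue.shape
    border = []
    for r in range(rows):
        for c in range(cols):
            if not tissue[r, c]:
                continue
            if r == 0 or r == rows - 1 or c == 0 or c == cols - 1:
                border.append((r, c))
                continue
            if not (tissue[r - 1, c] and tissue[r + 1, c]
                    and tissue[r, c - 1] and tissue[r, c + 1]):
                border.append((r, c))
    border = np.asarray(border, float)
    out = np.full(tissue.shape, np.nan)
    for r, c in np.argwhere(tissue):
        d2 = ((border - (r, c)) ** 2).sum(axis=1)
        out[r, c] = math.sqrt(d2.min()) * pixel_size_mm
    return out


def brute_force_otsu(grey: np.ndarray):
    """Exhaustive 256-way search for the max between-class-variance split."""
    g = np.asarray(grey).ravel().astype(float)
    best_t, best_var = None, -1.0
    for t in range(256):
        lo = g[g <= t]
        hi = g[g > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0 = lo.size / g.size
        var = w0 * (1.0 - w0) * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


def pairwise_u(xs, ys) -> float:
    """U statistic by direct pair counting (wins + half-ties)."""
    return sum(1.0 if x > y else 0.5 if x == y else 0.0
               for x in xs for y in ys)


def mwu_enumeration_p(a, b) -> float:
    """Exact two-sided p by enumerating every group labeling of the pool."""
    pooled = list(a) + list(b)
    n1, n = len(a), len(a) + len(b)
    mu = n1 * len(b) / 2.0
    obs = abs(pairwise_u(a, b) - mu)
    hits = total = 0
    for idx in itertools.combinations(range(n), n1):
        chosen = set(idx)
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n) if i not in chosen]
        if abs(pairwise_u(xs, ys) - mu) >= obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


def random_section_spec(seed: int, canvas=(192, 192), n_vessels: int = 6,
                        noise_sd: float = 0.0, with_tumor: bool = False,
                        pixel_size_mm: float = 0.005) -> lq.SyntheticSpec:
    """A random valid section: rotated elliptical tissue, non-overlapping
    vessel rings kept clear of the tumor mass (so segmentation can recover
    every mask exactly in the noise-free case)."""
    rng = np.random.default_rng(seed)
    tissue = lq.Ellipse(
        (canvas[0] / 2.0, canvas[1] / 2.0),
        (0.42 * canvas[0], 0.36 * canvas[1]),
        rotation_deg=float(rng.uniform(0, 180)),
    )
    tumor = lq.disc(tissue.center, 0.12 * min(canvas)) if with_tumor else None
    vessels: list[lq.VesselSpec] = []
    tries = 0
    while len(vessels) < n_vessels and tries < 800:
        tries += 1
        radius = float(rng.uniform(4, 9))
        wall = float(rng.uniform(2, 3))
        center = (
            tissue.center[0] + float(rng.uniform(-1, 1)) * tissue.semi_axes[0],
            tissue.center[1] + float(rng.uniform(-1, 1)) * tissue.semi_axes[1],
        )
        if not tissue.contains_disc(center, radius, margin=2.0):
            continue
        if tumor is not None:
            gap = math.hypot(center[0] - tumor.center[0],
                             center[1] - tumor.center[1])
            if gap < radius + tumor.semi_axes[0] + 16:
                continue
        if any(math.hypot(center[0] - v.center[0], center[1] - v.center[1])
               < radius + v.outer_radius_px + 2 for v in vessels):
            continue
        vessels.append(lq.VesselSpec(center, radius, wall))
    return lq.SyntheticSpec(
        seed=seed, canvas=canvas, pixel_size_mm=pixel_size_mm,
        tissue_geometry=tissue, vessels=tuple(vessels),
        tumor_geometry=tumor, noise_sd=noise_sd,
    )


def random_blob_mask(rng: np.random.Generator, shape=(48, 48)) -> np.ndarray:
    """A random smooth blob mask (possibly with holes), never empty."""
    from scipy import ndimage

    while True:
        field = ndimage.gaussian_filter(rng.normal(size=shape), sigma=4)
        mask = field > np.percentile(field, 60)
        if mask.sum() >= 10:
            return mask
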