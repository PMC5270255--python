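# lymphquant

Computer-assisted quantification of lymphatic vasculature in two-stain
immunohistochemistry sections.

## The problem

Lymphangiogenesis — the outgrowth of new lymphatic vessels — accompanies
tumor growth both around the primary tumor and in the draining (sentinel)
lymph nodes, where it helps prepare a pre-metastatic niche before tumor
cells arrive. Assessing it on tissue sections means turning whole-slide RGB
scans of double-immunostained sections (a lymphatic endothelium marker such
as LYVE-1 revealed in blue, a tumor-cell marker such as tyrosinase in pink,
on a hematoxylin counterstain) into reproducible numbers: how much vessel,
how many vessel profiles, of what size, and how deep into the tissue they
reach.

`lymphquant` implements that measurement chain as a tested Python library
plus CLI, for image analysts and vascular-biology labs. Because original
slides are rarely shareable, it ships a seeded synthetic-slide generator
with exact ground truth, so every stage is verifiable end to end.

## The method

For each section the pipeline computes:

1. **Stain separation** — excess-color transforms
   `clip(2B − R − G)` (vessel stain) and `clip(2R − G − B)` (tumor stain),
   thresholded automatically (Otsu's maximum between-class variance) or
   with a manual per-image override, followed by small-object removal.
2. **Region delineation** — the tissue silhouette (largest non-white
   component, hole-filled), the compact tumor mass (morphological closing +
   hole filling of the tumor-cell mask), and the peritumoral region
   (tissue ∖ tumor), a disjoint cover of the tissue.
3. **Vessel metrics**, per region *S* with vessel mask *V*:
   - lymphatic vessel density `LVD = |V ∩ S| / |S|` (area fraction),
   - vessel-section count density `N / area(S)` (mm⁻²),
   - counts of sections with area ≤ / > a size cutoff, the cutoff taken at
     the 75th percentile of the pooled size distribution (or fixed, e.g.
     2×10⁻² mm² peritumoral / 1×10⁻² mm² intratumoral).
4. **Spatial distribution** — Euclidean distance from each vessel pixel (or
   section) to the tissue border, summarized by a Parzen estimate
   `f(x) = (nh)⁻¹ Σᵢ [φ((x−dᵢ)/h) + φ((x+dᵢ)/h)]` (Gaussian kernel,
   reflection at zero, Silverman bandwidth) with unit area under the curve;
   point readouts `f(d)` at chosen depths; and the maximal reached distance
   `Lmax = max dᵢ`.
5. **3D reconstruction** — serial binary sections rigidly re-oriented
   (centroid + principal axis, nearest-neighbor resampling) and stacked at
   a known z spacing (e.g. 40 sections × 5 μm ≈ 200 μm).
6. **Statistics** — section values averaged per entity (sponge / lymph
   node), groups summarized as mean ± SEM, and compared with the two-sided
   Wilcoxon–Mann–Whitney test (exact by enumeration for pooled n ≤ 12).

## Worked example

```python
import numpy as np
import lymphquant as lq

spec = lq.SyntheticSpec(
    seed=7, canvas=(512, 512),
    tissue_geometry=lq.Ellipse((256, 256), (215, 185)),
    vessels=tuple(
        lq.VesselSpec((256 + 150*np.sin(t), 256 + 150*np.cos(t)), 8, 3)
        for t in np.linspace(0, 2*np.pi, 10, endpoint=False)),
    tumor_geometry=lq.disc((256, 256), 60),
    noise_sd=5.0,
)
image, truth = lq.generate_section(spec)
seg = lq.segment_section(image)
records = lq.assign_vessels(
    lq.label_components(seg.vessel_mask, image.pixel_size_mm),
    seg.vessel_mask, seg.partition)

lq.lvd(seg.vessel_mask, seg.partition.peritumoral)   # 0.0106
lq.lvd(seg.vessel_mask, seg.partition.tumor)         # 0.0000

dmap = lq.border_distance_map(seg.partition.tissue, image.pixel_size_mm)
d = lq.vessel_distances(seg.vessel_mask, dmap, mode="pixels")
sd = lq.parzen_density(d)
lq.lmax(d)        # 0.341  (mm)
sd.auc            # 1.0000
```

The section is a metastatic-node-like geometry: a ring of ten vessel
profiles around a central vessel-free tumor mass. Peritumoral LVD is ~1% of
the peritumoral area; intratumoral LVD is exactly zero because no vessel
pixel falls inside the delineated tumor region; the deepest vessel pixel
sits 0.341 mm from the tissue border; and the border-distance distribution
integrates to one, as a Parzen estimate must.

Cohort-scale runs go through a YAML config:

```sh
lymphquant quantify --config run.yaml
```

which writes `per_section.csv`, `per_entity.csv`, `group_summary.csv`
(mean ± SEM), `comparisons.csv` (U, p, significance tier), density-curve
CSVs and a JSON run manifest. Other subcommands: `simulate`, `segment`,
`spatial`, `stack3d`, `compare`.

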