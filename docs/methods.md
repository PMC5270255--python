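# Methods

This note documents the models, defaults and numerical choices behind
`lymphquant`, and what the synthetic validation does and does not
demonstrate about real slides.

## Synthetic sections

The generator emulates the measurement setting of double-chromogen
immunohistochemistry on a white-background slide scan: a counterstained
tissue silhouette (ellipse or polygon), vessel profiles drawn as stained
rings — the endothelium carries the marker, the lumen does not — or filled
discs, an optional compact tumor mass, and i.i.d. per-channel Gaussian
noise clipped to [0, 255]. Ground truth is the pre-noise geometry.
Identical specs (including the seed) are bit-reproducible; all cohort
randomness derives from one master seed through `numpy` seed sequences.

Defaults and why:

- **Stain palette** — vessel (40, 60, 200), tumor (230, 90, 150),
  counterstain (200, 170, 210), background (245, 245, 245): blue/pink
  chromogens on hematoxylin over scanner white. Fully configurable.
- **Pixel size 0.005 mm** (5 μm/px): a conventional working resolution for
  slide scanners; every physical quantity scales through this single value.
- **Noise sd 5** (8-bit units) for "realistic" cohorts: large enough to
  exercise thresholding, small enough that chromogen and counterstain
  populations stay separable, as they are on well-stained slides.
- **Cohorts**: each entity (sponge/node) draws its vessel count and sizes
  from the template's ranges; each serial section jitters vessel centers
  (sd 2 px) and takes fresh noise, emulating sections cut at different
  levels. `density_scale` multiplies the drawn count for effect-size
  experiments.

Not emulated, deliberately: optical blur, chromatic aliasing, staining
gradients, folds and bubbles, scanner compression. Passing tests therefore
demonstrate correctness of the measurement chain — not robustness to every
real-slide artifact; on difficult slides the manual threshold override
exists for exactly that reason.

## Stain separation and thresholds

The excess-color transform (`2·target − other − other`, clipped to [0, 255])
is the classical linear contrast enhancement for a chromogen over a mixed
background; stain weight vectors are configurable as an escape hatch for
other chromogen pairs. Thresholding is Otsu's criterion, implemented as an
exhaustive 256-bin search for the maximum between-class variance (first
maximum wins on ties), with a fixed-threshold manual mode for per-image
overrides.

Two choices in `segment_section` matter in practice:

- **Thresholds are computed over tissue pixels only** (default). The
  whole-image excess histogram has three classes — background ~0,
  counterstained tissue ~20–50, chromogen ≥ 200 — and when the stained
  fraction is small (sparse vessels are the norm: LVD of a few percent),
  the global two-class criterion collapses onto the background/tissue
  boundary and labels the whole tissue as foreground. Restricting the
  histogram to tissue removes the dominant background mode and makes the
  split stain-vs-counterstain regardless of vessel abundance.
- **A positivity floor (default 60)** bounds the automatic threshold from
  below. On a section genuinely devoid of one stain the within-tissue
  histogram is unimodal counterstain noise, and an unconstrained Otsu split
  would flag its upper tail; the floor sits several noise standard
  deviations above the counterstain excess level, so such sections
  binarize empty (correct for control sponges and tumor-free nodes).

Noise elimination removes 8-connected components below 20 px (vessel and
tumor-cell masks) — 8-connectivity throughout, so that diagonally adjacent
wall pixels of thin vessel rings stay one profile. Hole filling is off for
vessels (the lumen is real) and on for tissue and tumor masses. The tumor
mass is built from the tumor-cell mask by closing with a 10 px disc,
filling, and dropping components under 500 px; these two parameters shape
how aggressively scattered positive cells merge into one "well-established
tumor area" and are exposed in the config.

## Vessel metrics

Per region (peritumoral = tissue ∖ tumor, intratumoral = tumor):

- `LVD = |vessel ∩ region| / |region|` — a pixel-count ratio, so the pixel
  size cancels.
- Count density: profiles per mm² of the region.
- Size split at a cutoff: *small* means area ≤ cutoff so the two classes
  partition the counts exactly. The cutoff defaults to the 75th percentile
  (linear interpolation between order statistics) of the pooled per-region
  size distribution of the run; fixed cutoffs (e.g. 2×10⁻² mm²
  peritumoral, 1×10⁻² mm² intratumoral) can be supplied instead when
  comparability with published values matters.
- A profile straddling the tumor boundary is intratumoral iff strictly
  more than half its pixels lie in the tumor; ties go peritumoral. The
  choice is a convention; the majority rule keeps the assignment stable
  under small boundary perturbations.

## Border-distance distribution

Border pixels are tissue pixels with at least one 4-neighbor outside the
tissue; tissue pixels on the grid edge also count as border, because a
section cut off at the image edge is not interior tissue there. The
distance map is the exact Euclidean distance transform to that border set;
no sub-pixel interpolation is done (distances are read at pixels).

The distribution of distances is a Parzen (kernel density) estimate with a
Gaussian kernel and **reflection at zero**: mass the kernel would place at
negative distances is folded back, which is what makes the area under the
curve equal one on [0, ∞) even when many vessels hug the border. Bandwidth
is Silverman's rule `0.9·min(sd, IQR/1.34)·n^(−1/5)` with a positive floor
of 10⁻³ mm (engaged when observations are few or all identical). The
default evaluation grid spans [0, Lmax + 4h] — wide enough that the
truncated tail is below the 10⁻³ normalization tolerance — with at least
512 points, refined so the spacing stays under h/4 (trapezoidal
integration must resolve the kernel; with the floor bandwidth a fixed
512-point grid visibly underestimates the area).

Two observation modes exist because the two natural readouts differ: the
full distribution curve is computed from **per-pixel** distances (every
vessel pixel contributes), while point readouts like "normalized number of
vessel sections at 0.4 mm" use **per-section** distances (one observation
per profile, read at the profile pixel nearest its centroid). The reported
readout is the density value itself (mm⁻¹); multiplying by the total count
is left to the caller since the y-axis convention varies between studies.

## 3D reconstruction

Alignment is rigid: translate each section's tissue centroid onto the
reference (first) section's centroid and rotate by the difference of
principal-axis orientations (image second moments). The 180° ambiguity of
the principal axis is resolved by picking the candidate minimizing the
symmetric difference with the previously aligned section, which assumes
adjacent sections resemble each other — true for serial histology.
Resampling is nearest-neighbor so masks stay binary; pixel-count error
scales with the object perimeter (≲1% for tissue-scale objects, a few
pixels for thin rings). Recovery on synthetic stacks is ≤1 px translation
and ≤2° rotation for drifts up to ~20 px / 20°.

Thickness is `n_sections × z_spacing_um` and vessel volume is
`Σ section area × z spacing`, both exact by construction. The z spacing is
an explicit parameter (default 5 μm, the section thickness); when only
every k-th section is stained, the represented spacing is for the caller to
set.

## Statistics

Aggregation order is fixed: per-section values → per-entity arithmetic
means (density curves averaged pointwise on a common grid) → group
mean ± SEM (sample sd, n−1, over √n; undefined at n = 1) → two-sided
Wilcoxon–Mann–Whitney on the per-entity means. Pooling sections across
entities would fake sample size and is not offered.

The U statistic uses midranks for ties. For pooled n ≤ 12 the p-value is
exact: all C(n₁+n₂, n₁) labelings are enumerated and those with
|U − n₁n₂/2| at least the observed deviation are counted — at the
assay-typical group size of 6 + 6 this is 924 labelings. Larger samples
use the normal approximation with tie-corrected variance and a 0.5
continuity correction. Under the null (identical generator parameters for
both groups) the type-I error at α = 0.05, measured over the suite's 200
seeded replicates, is 0.04: conservative, as expected from the
discreteness of the exact distribution at small n.

## Problem sizes used in validation

The test suite validates at the study's own scale where that is cheap
(cohorts of 2 groups × 6 entities × 12 sections at 512×512 px; 40-section
stacks) and at reduced canvas sizes (96–256 px) for properties that are
resolution-independent, such as conservation laws and calibration of the
rank-sum test. Brute-force oracles (exhaustive nearest-border scans,
full labeling enumerations, 256-way threshold searches) are kept to masks
≤ 64×64 and pooled samples ≤ 12, where exhaustive computation is exact and
fast.

## Known limitations

- Color separation is linear excess-color, not optical-density
  deconvolution; heavily overlapping chromogens would need different
  weights or a different method.
- Rigid alignment only; warped or folded sections are out of scope.
- The synthetic generator's realism bounds what green tests prove (see
  above); parameters chosen on synthetic data should be sanity-checked on
  a few real slides with the manual threshold mode.
- The cohort sampler places vessels in elliptical tissues only; arbitrary
  polygon tissues are supported for single sections.
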