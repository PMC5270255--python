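"""End-to-end quantification workflow.

Orchestrates the full analysis: segment every section, measure the vessel
parameters per region, estimate the border-distance distribution, average
per entity, summarize per group (mean ± SEM) and compare groups with the
Wilcoxon–Mann–Whitney test. Inputs are either a synthetic cohort generated
in-process or a CSV manifest of image files; outputs are CSV tables plus a
JSON run manifest capturing every parameter and seed, written so that a
rerun with the same configuration is byte-identical.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as lio
from .errors import ConfigurationError, UndefinedRegionError
from .segmentation import SegmentationParams, segment_section
from .spatial import (border_distance_map, density_at, parzen_density,
                      vessel_distances)
from .stats import mann_whitney_u, summarize_group
from .synthetic import (Cohort, CohortRecord, CohortTemplate, Ellipse,
                        GroupSpec, Polygon, StainPalette, generate_cohort)
from .types import SectionMeta
from .vessel_metrics import (assign_vessels, label_components,
                             percentile_cutoff, region_metrics)

REGIONS = ("peritumoral", "intratumoral")


@dataclass
class QuantParams:
    """Quantification settings.

    The size cutoff defaults to the 75th percentile of the pooled vessel-size
    distribution per region; ``fixed_cutoffs`` (mm^2 per region) overrides it
    with externally chosen values such as the conventional 2e-2 mm^2
    peritumoral / 1e-2 mm^2 intratumoral cutoffs.
    """

    percentile_q: float = 75.0
    fixed_cutoffs: Optional[dict] = None
    readout_distances_mm: tuple = (0.4,)
    curve_points: int = 512
    curve_mode: str = "pixels"
    readout_mode: str = "sections"


@dataclass
class _SectionData:
    group: str
    entity: str
    section: int
    tissue_area_mm2: float
    records: list
    vessel_mask: np.ndarray
    partition: object
    pixel_size_mm: float
    dist_curve: np.ndarray
    dist_readout: np.ndarray


@dataclass
class RunResult:
    per_section: pd.DataFrame
    per_entity: pd.DataFrame
    group_summary: pd.DataFrame
    comparisons: pd.DataFrame
    curves: Optional[pd.DataFrame]
    manifest: dict


def _analyze_section(rec: CohortRecord, seg_params: SegmentationParams,
                     qp: QuantParams) -> _SectionData:
    image = rec.image
    seg = segment_section(image, seg_params)
    px = image.pixel_size_mm
    records = label_components(seg.vessel_mask, px)
    records = assign_vessels(records, seg.vessel_mask, seg.partition)
    dmap = border_distance_map(seg.partition.tissue, px)
    dist_curve = vessel_distances(seg.vessel_mask, dmap, mode=qp.curve_mode)
    dist_readout = vessel_distances(seg.vessel_mask, dmap, mode=qp.readout_mode)
    return _SectionData(
        group=rec.group, entity=rec.entity, section=rec.section,
        tissue_area_mm2=float(seg.partition.tissue.sum()) * px ** 2,
        records=records, vessel_mask=seg.vessel_mask,
        partition=seg.partition, pixel_size_mm=px,
        dist_curve=dist_curve, dist_readout=dist_readout,
    )


def _cutoffs(sections: Sequence[_SectionData], qp: QuantParams) -> dict:
    out = {}
    for region in REGIONS:
        if qp.fixed_cutoffs and region in qp.fixed_cutoffs:
            out[region] = float(qp.fixed_cutoffs[region])
            continue
        areas = [r.area_mm2 for s in sections for r in s.records
                 if r.region == region]
        out[region] = (percentile_cutoff(areas, qp.percentile_q)
                       if areas else float("nan"))
    return out


def _section_row(s: _SectionData, cutoffs: dict, qp: QuantParams) -> dict:
    row: dict = {"group": s.group, "entity": s.entity, "section": s.section,
                 "tissue_area_mm2": s.tissue_area_mm2}
    if s.dist_curve.size:
        row["lmax_mm"] = float(s.dist_curve.max())
    else:
        row["lmax_mm"] = np.nan
    if s.dist_readout.size:
        sd = parzen_density(s.dist_readout, mode=qp.readout_mode)
        for d in qp.readout_distances_mm:
            row[f"density_at_{d:g}_mm"] = density_at(sd, d)
    else:
        for d in qp.readout_distances_mm:
            row[f"density_at_{d:g}_mm"] = np.nan
    for region in REGIONS:
        prefix = region
        try:
            m = region_metrics(s.records, s.vessel_mask, s.partition, region,
                               s.pixel_size_mm,
                               cutoffs[region] if np.isfinite(cutoffs[region])
                               else float("inf"))
            row[f"{prefix}_lvd"] = m.lvd
            row[f"{prefix}_n_per_mm2"] = m.n_per_mm2
            row[f"{prefix}_n_small_per_mm2"] = m.n_small_per_mm2
            row[f"{prefix}_n_large_per_mm2"] = m.n_large_per_mm2
            row[f"{prefix}_cutoff_mm2"] = cutoffs[region]
            row[f"{prefix}_region_area_mm2"] = m.region_area_mm2
        except UndefinedRegionError:
            for suffix in ("lvd", "n_per_mm2", "n_small_per_mm2",
                           "n_large_per_mm2", "cutoff_mm2", "region_area_mm2"):
                row[f"{prefix}_{suffix}"] = np.nan
    return row


def quantify_cohort(cohort: Cohort,
                    seg_params: Optional[SegmentationParams] = None,
                    quant_params: Optional[QuantParams] = None) -> RunResult:
    """Quantify every section of a cohort and aggregate per entity and group."""
    seg_params = seg_params or SegmentationParams()
    qp = quant_params or QuantParams()
    if not cohort.records:
        raise ConfigurationError("cohort has no sections")

    sections = [_analyze_section(r, seg_params, qp) for r in cohort.records]
    cutoffs = _cutoffs(sections, qp)

    per_section = pd.DataFrame([_section_row(s, cutoffs, qp) for s in sections])
    per_section = per_section.sort_values(
        ["group", "entity", "section"]).reset_index(drop=True)

    metric_cols = [c for c in per_section.columns
                   if c not in ("group", "entity", "section")]
    per_entity = (per_section.groupby(["group", "entity"], sort=True)[metric_cols]
                  .mean().reset_index())

    summaries = []
    for metric in metric_cols:
        for group, sub in per_entity.groupby("group", sort=True):
            vals = sub[metric].dropna().tolist()
            if not vals:
                continue
            gs = summarize_group(group, vals)
            summaries.append({"metric": metric, "group": group, "n": gs.n,
                              "mean": gs.mean, "sem": gs.sem})
    group_summary = pd.DataFrame(summaries)

    groups = sorted(per_entity["group"].unique())
    comparisons = []
    for metric in metric_cols:
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                a = per_entity.loc[per_entity["group"] == groups[i],
                                   metric].dropna().tolist()
                b = per_entity.loc[per_entity["group"] == groups[j],
                                   metric].dropna().tolist()
                if not a or not b:
                    continue
                res = mann_whitney_u(a, b, labels=(groups[i], groups[j]))
                comparisons.append({
                    "metric": metric, "group_a": groups[i],
                    "group_b": groups[j], "n_a": len(a), "n_b": len(b),
                    "U": res.U, "p_value": res.p_value,
                    "significance": res.significance,
                })
    comparisons_df = pd.DataFrame(comparisons)

    curves = _entity_curves(sections, qp)
    manifest = {
        "n_sections": len(sections),
        "n_entities": int(per_entity.shape[0]),
        "groups": groups,
        "cutoffs_mm2": {k: (None if not np.isfinite(v) else v)
                        for k, v in cutoffs.items()},
        "segmentation": dataclasses.asdict(seg_params),
        "quantification": {**dataclasses.asdict(qp),
                           "readout_distances_mm": list(qp.readout_distances_mm)},
    }
    return RunResult(per_section, per_entity, group_summary, comparisons_df,
                     curves, manifest)


def _entity_curves(sections: Sequence[_SectionData],
                   qp: QuantParams) -> Optional[pd.DataFrame]:
    with_obs = [s for s in sections if s.dist_curve.size > 0]
    if not with_obs:
        return None
    gmax = max(float(s.dist_curve.max()) for s in with_obs)
    grid = np.linspace(0.0, gmax * 1.1 + 1e-6, qp.curve_points)
    rows = []
    keys = sorted({(s.group, s.entity) for s in with_obs})
    for group, entity in keys:
        secs = [s for s in with_obs
                if s.group == group and s.entity == entity]
        stack = np.stack([
            parzen_density(s.dist_curve, grid=grid, mode=qp.curve_mode).density
            for s in secs
        ])
        mean_curve = stack.mean(axis=0)
        for d, v in zip(grid, mean_curve):
            rows.append({"group": group, "entity": entity,
                         "distance_mm": d, "density": v})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# configuration loading
# ---------------------------------------------------------------------------

def _geometry_from_dict(d: Optional[dict]):
    if d is None:
        return None
    if "ellipse" in d:
        e = d["ellipse"]
        return Ellipse(tuple(e["center"]), tuple(e["semi_axes"]),
                       float(e.get("rotation_deg", 0.0)))
    if "disc" in d:
        e = d["disc"]
        r = float(e["radius"])
        return Ellipse(tuple(e["center"]), (r, r))
    if "polygon" in d:
        return Polygon(tuple(tuple(v) for v in d["polygon"]["vertices"]))
    raise ConfigurationError(f"unknown geometry descriptor: {sorted(d)}")


def _template_from_dict(d: dict) -> CohortTemplate:
    kwargs = dict(d)
    for key in ("tissue_geometry", "tumor_geometry"):
        if key in kwargs:
            kwargs[key] = _geometry_from_dict(kwargs[key])
    if "stain" in kwargs:
        kwargs["stain"] = StainPalette(**{k: tuple(v)
                                          for k, v in kwargs["stain"].items()})
    for key in ("canvas", "n_vessels", "outer_radius_px", "wall_thickness_px"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return CohortTemplate(**kwargs)


def cohort_from_config(config: dict) -> Cohort:
    """Build a synthetic cohort from the ``synthetic`` block of a run config."""
    syn = config.get("synthetic")
    if not syn or "groups" not in syn:
        raise ConfigurationError("config lacks a synthetic.groups block")
    group_specs = {}
    for label, g in syn["groups"].items():
        group_specs[label] = GroupSpec(
            n_entities=int(g["n_entities"]),
            sections_per_entity=int(g["sections_per_entity"]),
            template=_template_from_dict(g.get("template", {})),
        )
    return generate_cohort(group_specs, seed=int(config.get("seed", 0)))


def cohort_from_manifest(manifest_path, pixel_size_mm: float) -> Cohort:
    """Load a cohort from a CSV manifest (group, entity, section, path)."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    required = {"group", "entity", "section", "path"}
    if not required.issubset(df.columns):
        raise ConfigurationError(
            f"manifest needs columns {sorted(required)}")
    records = []
    for _, row in df.iterrows():
        path = manifest_path.parent / row["path"]
        if not path.exists():
            raise ConfigurationError(f"image file missing: {path}")
        meta = SectionMeta(group=str(row["group"]), entity=str(row["entity"]),
                           section=int(row["section"]))
        image = lio.read_image(path, pixel_size_mm, meta)
        records.append(CohortRecord(meta.group, meta.entity, meta.section,
                                    image, truth=None))
    return Cohort(records)


def run_quantification(config: dict | str | Path,
                       outdir: Optional[str | Path] = None) -> RunResult:
    """Run the full workflow from a config dict or YAML file and write outputs.

    The config lists either a ``synthetic`` cohort description or a
    ``manifest`` of images with a ``pixel_size_mm``, plus optional
    ``segmentation`` and ``quantification`` parameter blocks and an
    ``outdir``.
    """
    if isinstance(config, (str, Path)):
        import yaml

        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigurationError("config must be a mapping")

    if "synthetic" in config:
        cohort = cohort_from_config(config)
    elif "manifest" in config:
        if "pixel_size_mm" not in config:
            raise ConfigurationError("manifest input requires pixel_size_mm")
        cohort = cohort_from_manifest(config["manifest"],
                                      float(config["pixel_size_mm"]))
    else:
        raise ConfigurationError("config needs a 'synthetic' or 'manifest' block")

    seg_params = SegmentationParams(**config.get("segmentation", {}))
    q = dict(config.get("quantification", {}))
    if "readout_distances_mm" in q:
        q["readout_distances_mm"] = tuple(q["readout_distances_mm"])
    quant_params = QuantParams(**q)

    result = quantify_cohort(cohort, seg_params, quant_params)
    result.manifest["seed"] = config.get("seed")
    result.manifest["config"] = _jsonable(config)

    outdir = Path(outdir or config.get("outdir", "."))
    outdir.mkdir(parents=True, exist_ok=True)
    result.per_section.to_csv(outdir / "per_section.csv", index=False)
    result.per_entity.to_csv(outdir / "per_entity.csv", index=False)
    result.group_summary.to_csv(outdir / "group_summary.csv", index=False)
    result.comparisons.to_csv(outdir / "comparisons.csv", index=False)
    if result.curves is not None:
        result.curves.to_csv(outdir / "density_curves.csv", index=False)
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return result


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
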