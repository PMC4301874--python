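"""Cohort orchestration: manifest -> per-image measurements -> per-animal
aggregation -> group statistics -> serialized report.

The unit of replication for statistics is the animal: fields/sections are
averaged with unweighted means up to one value per (animal, muscle, metric).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from PIL import Image

from . import __version__
from .annotations_io import read_annotations, write_annotations
from .cnf import DEFAULT_BAND_FRAC, FiberAnnotation, NucleusAnnotation, percent_cnf
from .segmentation import (ClassMask, RgbImage, SegmentationConfig,
                           render_overlay, segment_image)
from .synthetic import GroupSpec, SyntheticSpec, generate_cohort

log = logging.getLogger("fibroquant")

MANIFEST_COLUMNS = ["group", "animal", "muscle", "section", "image_path"]


class ManifestError(ValueError):
    pass


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return validate_manifest(df, base_dir=Path(path).parent)


def validate_manifest(df: pd.DataFrame,
                      base_dir: Optional[Path] = None) -> pd.DataFrame:
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest missing columns: {missing}")
    key = df[["group", "animal", "muscle", "section"]].astype(str).agg("|".join, axis=1)
    dup = key[key.duplicated()]
    if not dup.empty:
        raise ManifestError(f"duplicate (group, animal, muscle, section) keys: "
                            f"{sorted(dup.unique())[:5]}")
    if base_dir is not None:
        df = df.copy()
        for col in ("image_path", "annotation_path", "gt_path"):
            if col in df.columns:
                df[col] = df[col].map(
                    lambda p: str((base_dir / p)) if isinstance(p, str)
                    and not Path(p).is_absolute() else p)
    return df


def load_image(path: str | Path) -> RgbImage:
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGBA") if im.mode == "RGBA" else im)
    if arr.ndim == 2:
        raise ValueError(f"{path}: grayscale input rejected; the segmentation is colour-based")
    return RgbImage(pixels=arr.astype(np.uint8))


def run_quantify(manifest: pd.DataFrame, cfg: SegmentationConfig,
                 out_dir: str | Path, band_frac: float = DEFAULT_BAND_FRAC,
                 write_overlays: bool = True) -> pd.DataFrame:
    """Segment every manifest row; CNF is computed when annotation_path is
    present.  Per-row failures are recorded, not raised."""
    out_dir = Path(out_dir)
    overlay_dir = out_dir / "overlays"
    if write_overlays:
        overlay_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in manifest.to_dict("records"):
        row = {k: rec.get(k) for k in MANIFEST_COLUMNS}
        row.update(status="ok", reason="", config_hash=cfg.hash())
        try:
            img = load_image(rec["image_path"])
            mask, meas = segment_image(img, cfg)
            row.update(blue_px=meas.blue_px, red_px=meas.red_px,
                       white_px=meas.white_px, total_px=meas.total_px,
                       percent_collagen=meas.percent_collagen,
                       degenerate=meas.degenerate)
            if write_overlays:
                name = f"{rec['group']}_{rec['animal']}_{rec['muscle']}_{rec['section']}.png"
                overlay = render_overlay(img, mask)
                Image.fromarray(overlay).save(overlay_dir / name)
                row["overlay_path"] = str(overlay_dir / name)
            ann = rec.get("annotation_path")
            if isinstance(ann, str) and ann:
                fibers, nuclei = read_annotations(ann)
                cnf = percent_cnf(fibers, nuclei, band_frac)
                row.update(n_fibers=cnf.n_fibers,
                           n_central=cnf.n_central_fibers,
                           percent_cnf=cnf.percent_cnf)
        except Exception as exc:  # per-row isolation is the contract
            log.warning("row failed (%s/%s/%s/%s): %s", rec.get("group"),
                        rec.get("animal"), rec.get("muscle"),
                        rec.get("section"), exc)
            row.update(status="failed", reason=str(exc))
        rows.append(row)
    return pd.DataFrame(rows)


METRICS = ("percent_collagen", "percent_cnf")


def aggregate(per_image: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean over sections per (group, animal, muscle, metric).

    Animals with zero successful rows are excluded with a warning.
    """
    ok = per_image[per_image["status"] == "ok"].copy()
    dropped = set(map(tuple, per_image[["group", "animal", "muscle"]].values)) - \
        set(map(tuple, ok[["group", "animal", "muscle"]].values))
    for key in sorted(dropped, key=str):
        log.warning("animal %s excluded: no successful rows", key)
    metrics = [m for m in METRICS if m in ok.columns]
    agg = (ok.groupby(["group", "animal", "muscle"], sort=True)
             .agg(n_sections=("section", "size"),
                  **{m: (m, "mean") for m in metrics})
             .reset_index())
    return agg


def run_stats(per_animal: pd.DataFrame,
              alpha: float = 0.05) -> dict:
    """ANOVA + Tukey + stars per (muscle, metric); metrics with fewer than
    two groups of >= 2 animals are skipped with a warning."""
    from . import stats as gs

    report: dict = {"version": __version__, "alpha": alpha, "muscles": {}}
    for muscle, sub in per_animal.groupby("muscle"):
        muscle_block: dict = {}
        for metric in METRICS:
            if metric not in sub.columns:
                continue
            vals = sub.dropna(subset=[metric])
            groups = []
            for gname, gsub in vals.groupby("group"):
                if len(gsub) >= 2:
                    groups.append(gs.summarize(gsub[metric].tolist(), label=str(gname)))
            if len(groups) < 2:
                log.warning("skipping %s/%s: fewer than 2 groups with n>=2",
                            muscle, metric)
                continue
            anova = gs.anova_oneway_summary(groups)
            tukey = gs.tukey_hsd(groups)
            muscle_block[metric] = {
                "groups": [asdict(g) for g in groups],
                "anova": asdict(anova),
                "anova_stars": gs.stars(anova.p).code,
                "tukey": [
                    {**asdict(t), "pair": list(t.pair),
                     "stars": gs.stars(t.p_adj).code}
                    for t in tukey
                ],
            }
        if muscle_block:
            report["muscles"][str(muscle)] = muscle_block
    return report


def write_report(report: dict, per_image: pd.DataFrame,
                 per_animal: pd.DataFrame, out_dir: str | Path,
                 cfg: Optional[SegmentationConfig] = None) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    per_image.to_csv(out_dir / "per_image.csv", index=False)
    per_animal.to_csv(out_dir / "per_animal.csv", index=False)
    full = dict(report)
    if cfg is not None:
        full["segmentation_config"] = asdict(cfg)
    path = out_dir / "report.json"
    path.write_text(json.dumps(full, indent=1, sort_keys=True))
    return path


def simulate_cohort_to_dir(group_specs: Mapping[str, GroupSpec],
                           out_dir: str | Path, base_seed: int = 0,
                           base_spec: Optional[SyntheticSpec] = None,
                           muscle: str = "synthetic") -> pd.DataFrame:
    """Generate a synthetic cohort on disk: image PNGs, ground-truth label
    PNGs, GeoJSON annotations, and a manifest CSV.  Returns the manifest."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "gt").mkdir(exist_ok=True)
    (out_dir / "annotations").mkdir(exist_ok=True)
    rows = []
    for item in generate_cohort(group_specs, base_seed=base_seed,
                                base_spec=base_spec):
        stem = f"{item.group}_a{item.animal}_s{item.section}"
        img_path = out_dir / "images" / f"{stem}.png"
        gt_path = out_dir / "gt" / f"{stem}_labels.png"
        ann_path = out_dir / "annotations" / f"{stem}.geojson"
        Image.fromarray(item.image).save(img_path)
        Image.fromarray(item.ground_truth.label_mask).save(gt_path)
        fibers = [FiberAnnotation(fiber_id=fid, polygon=poly)
                  for fid, poly in sorted(item.ground_truth.fiber_polygons.items())]
        nuclei = [NucleusAnnotation(point=n.point, fiber_id=n.fiber_id,
                                    is_central=n.is_central)
                  for n in item.ground_truth.nuclei]
        write_annotations(ann_path, fibers, nuclei)
        rows.append({
            "group": item.group, "animal": item.animal, "muscle": muscle,
            "section": item.section, "image_path": str(img_path),
            "gt_path": str(gt_path), "annotation_path": str(ann_path),
            "true_fraction": item.ground_truth.true_collagen_fraction,
            "cnf_rate": item.spec.cnf_rate, "seed": item.seed,
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def run_all(manifest: pd.DataFrame, cfg: SegmentationConfig,
            out_dir: str | Path,
            band_frac: float = DEFAULT_BAND_FRAC,
            write_overlays: bool = True) -> dict:
    """quantify -> aggregate -> stats -> report, returning the report dict."""
    per_image = run_quantify(manifest, cfg, out_dir, band_frac=band_frac,
                             write_overlays=write_overlays)
    per_animal = aggregate(per_image)
    report = run_stats(per_animal)
    write_report(report, per_image, per_animal, out_dir, cfg=cfg)
    return report
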