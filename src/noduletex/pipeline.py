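"""Pipeline orchestration: simulate -> segment -> features -> classify -> evaluate.

The pipeline consumes either an in-memory phantom cohort or a manifest CSV
referencing archived volumes, runs every nodule through segmentation,
histogram statistics and shape classification with per-nodule fault
isolation, and evaluates the cohort with ROC curves (KUR and SKW), the
peak/plateau 2x2 table, and summary statistics.  Identical config + inputs
+ seed produce identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diagnostics, histogram_shape, texture_stats
from .segmentation import SeedPoint, region_grow_3d, subtract_structures
from .synthetic_data import PhantomTruth, generate_cohort
from .volume_io import load_archive, save_archive, validate_protocol

log = logging.getLogger("noduletex")


@dataclass
class PipelineConfig:
    hu_lo: float = -450.0
    hu_hi: float = 1500.0
    connectivity: int = 6
    bin_width: float = 1.0
    shape_rule: str = "ratio"
    shape_threshold: float = histogram_shape.DEFAULT_THRESHOLD
    shape_window: int = histogram_shape.DEFAULT_SMOOTH_WINDOW
    published_cutoffs: bool = False
    out_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"
    write_pngs: bool = False

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Plain key=value config file; '#' starts a comment."""
        cfg = cls()
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if not hasattr(cfg, key):
                raise KeyError(f"unknown config key: {key}")
            current = getattr(cfg, key)
            if isinstance(current, bool):
                setattr(cfg, key, value.lower() in ("1", "true", "yes"))
            elif isinstance(current, int):
                setattr(cfg, key, int(value))
            elif isinstance(current, float):
                setattr(cfg, key, float(value))
            else:
                setattr(cfg, key, value)
        return cfg

    def echo(self) -> str:
        return " ".join(f"{k}={v}" for k, v in dataclasses.asdict(self).items())


FEATURE_COLUMNS = ["id", "label", "n_voxels", "volume_mm3", "MEN", "VAR",
                   "SKW", "KUR", "shape_label", "peakedness"]


def measure_phantom(truth: PhantomTruth, config: PipelineConfig | None = None,
                    nodule_id: str = "phantom") -> dict:
    """Run one phantom through the full measurement chain.

    Segmentation starts from the nodule centre, attached structures are
    subtracted using the ground-truth vessel mask, and first-order
    statistics plus the shape label are computed from the unit-width HU
    histogram.
    """
    config = config or PipelineConfig()
    seed = SeedPoint(*truth.spec.center)
    seg = region_grow_3d(truth.volume, seed,
                         hu_interval=(config.hu_lo, config.hu_hi),
                         connectivity=config.connectivity)
    if truth.vessel_mask.any():
        seg = subtract_structures(seg, truth.vessel_mask)
    hist = texture_stats.build_histogram(
        truth.volume, seg, bin_width=config.bin_width,
        hu_range=(config.hu_lo, config.hu_hi))
    stats = texture_stats.stats_from_histogram(hist)
    shape = histogram_shape.classify_shape(
        hist, smooth_window=config.shape_window,
        threshold=config.shape_threshold, rule=config.shape_rule)
    return {
        "id": nodule_id, "label": truth.label,
        "n_voxels": seg.voxel_count, "volume_mm3": seg.volume_mm3,
        "MEN": stats.MEN, "VAR": stats.VAR, "SKW": stats.SKW,
        "KUR": stats.KUR, "shape_label": shape.label,
        "peakedness": shape.peakedness,
        "_hist": hist, "_shape": shape,
    }


@dataclass
class PipelineResult:
    features: pd.DataFrame
    roc: dict                  # feature name -> diagnostics.ROCResult
    shape_table: diagnostics.ConfusionTable | None
    shape_stats: diagnostics.ConfusionStats | None
    failures: list[tuple[str, str, str]] = field(default_factory=list)

    def summary(self) -> dict:
        out = {"n_nodules": int(len(self.features)),
               "n_failures": len(self.failures)}
        for name, roc in self.roc.items():
            out[f"auc_{name}"] = roc.auc
            out[f"cutoff_{name}"] = roc.cutoff
            out[f"cutoff_sensitivity_{name}"] = roc.cutoff_sensitivity
            out[f"cutoff_specificity_{name}"] = roc.cutoff_specificity
        if self.shape_table is not None:
            t = self.shape_table
            out["shape_table"] = {"tp": t.tp, "fn": t.fn, "tn": t.tn, "fp": t.fp}
            out.update({f"shape_{k}": v
                        for k, v in self.shape_stats.as_floats().items()})
        return out


def _evaluate(rows: list[dict], failures) -> PipelineResult:
    features = pd.DataFrame([{k: r[k] for k in FEATURE_COLUMNS} for r in rows])
    roc = {}
    shape_table = shape_stats = None
    labels = features["label"].to_numpy()
    if len(set(labels)) == 2:
        for name in ("KUR", "SKW", "peakedness"):
            data = diagnostics.LabeledScores(features[name].to_numpy(), labels)
            roc[name] = diagnostics.roc_curve(data)
        shape_table = diagnostics.shape_confusion(
            labels, features["shape_label"].to_numpy())
        try:
            shape_stats = diagnostics.confusion_stats(shape_table)
        except ZeroDivisionError:
            shape_stats = None
    return PipelineResult(features=features, roc=roc, shape_table=shape_table,
                          shape_stats=shape_stats, failures=failures)


def run_cohort(cohort: list[PhantomTruth],
               config: PipelineConfig | None = None) -> PipelineResult:
    """Measure and evaluate an in-memory phantom cohort."""
    config = config or PipelineConfig()
    rows, failures = [], []
    for i, truth in enumerate(cohort):
        nodule_id = f"{truth.label}_{i:04d}"
        try:
            rows.append(measure_phantom(truth, config, nodule_id))
        except Exception as exc:   # fault isolation: keep going
            log.error("nodule %s failed at measurement: %s", nodule_id, exc)
            failures.append((nodule_id, "measure", str(exc)))
    return _evaluate(rows, failures)


# ---------------------------------------------------------------------------
# Manifest-driven runs (on-disk cohorts)
# ---------------------------------------------------------------------------

def simulate_to_dir(n_benign: int, n_malignant: int, master_seed: int,
                    out_dir: str | Path) -> Path:
    """Write a phantom cohort as fixture archives + ground-truth masks and a
    manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(n_benign, n_malignant, master_seed)
    rows = []
    for i, truth in enumerate(cohort):
        nodule_id = f"{truth.label}_{i:04d}"
        vol_path = save_archive(truth.volume, out_dir / f"{nodule_id}_vol.npz")
        np.savez_compressed(out_dir / f"{nodule_id}_vessel.npz",
                            mask=truth.vessel_mask)
        spec = truth.spec
        rows.append({
            "id": nodule_id, "label": truth.label, "seed": spec.rng_seed,
            "radius_mm": spec.radius_mm, "body": spec.texture.body,
            "skew_target": spec.texture.skew, "kurt_target": spec.texture.kurt,
            "loc_hu": spec.texture.loc_hu, "scale_hu": spec.texture.scale_hu,
            "seed_x": spec.center[0], "seed_y": spec.center[1],
            "seed_z": spec.center[2],
            "volume_path": str(vol_path),
            "vessel_path": str(out_dir / f"{nodule_id}_vessel.npz"),
        })
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def run_pipeline(config: PipelineConfig,
                 manifest_path: str | Path) -> PipelineResult:
    """Run the full pipeline over a manifest of archived volumes.

    Writes the feature CSV, optional histogram PNGs, ROC point CSVs and a
    summary JSON under ``config.out_dir``; failures are reported per nodule
    and do not stop the run.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(config.log_level)
    log.info("config: %s", config.echo())

    manifest = pd.read_csv(manifest_path)
    rows, failures = [], []
    for _, entry in manifest.iterrows():
        nodule_id = str(entry["id"])
        t0 = time.perf_counter()
        try:
            volume = load_archive(entry["volume_path"])
            report = validate_protocol(volume)
            if not report.conformant:
                log.warning("nodule %s protocol violations: %s",
                            nodule_id, report.violations)
            seed = SeedPoint(int(entry["seed_x"]), int(entry["seed_y"]),
                             int(entry["seed_z"]))
            seg = region_grow_3d(volume, seed,
                                 hu_interval=(config.hu_lo, config.hu_hi),
                                 connectivity=config.connectivity)
            vessel_path = entry.get("vessel_path", "")
            if isinstance(vessel_path, str) and vessel_path:
                with np.load(vessel_path) as data:
                    vessel = data["mask"]
                if vessel.any():
                    seg = subtract_structures(seg, vessel)
            hist = texture_stats.build_histogram(
                volume, seg, bin_width=config.bin_width,
                hu_range=(config.hu_lo, config.hu_hi))
            stats = texture_stats.stats_from_histogram(hist)
            shape = histogram_shape.classify_shape(
                hist, smooth_window=config.shape_window,
                threshold=config.shape_threshold, rule=config.shape_rule)
            rows.append({
                "id": nodule_id, "label": str(entry["label"]),
                "n_voxels": seg.voxel_count, "volume_mm3": seg.volume_mm3,
                "MEN": stats.MEN, "VAR": stats.VAR, "SKW": stats.SKW,
                "KUR": stats.KUR, "shape_label": shape.label,
                "peakedness": shape.peakedness, "_hist": hist, "_shape": shape,
            })
            if config.write_pngs:
                histogram_shape.export_histogram_png(
                    hist, shape, out_dir / "histograms" / f"{nodule_id}.png")
            log.info("nodule %s done in %.3fs", nodule_id,
                     time.perf_counter() - t0)
        except Exception as exc:
            stage = "load" if not rows or "volume" not in dir() else "measure"
            log.error("nodule %s failed (%s): %s", nodule_id, stage, exc)
            failures.append((nodule_id, stage, str(exc)))

    result = _evaluate(rows, failures)
    result.features.to_csv(out_dir / "features.csv", index=False,
                           float_format="%.10g")
    for name, roc in result.roc.items():
        pd.DataFrame(roc.points, columns=["fpr", "tpr"]).to_csv(
            out_dir / f"roc_{name}.csv", index=False, float_format="%.10g")
    (out_dir / "summary.json").write_text(
        json.dumps(result.summary(), indent=1, default=str))
    log.removeHandler(handler)
    handler.close()
    return result
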