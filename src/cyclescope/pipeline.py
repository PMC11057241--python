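"""Staged, reproducible orchestration of the whole workflow.

Stages (``simulate -> segment -> extract -> gate -> split -> train ->
evaluate -> report``) communicate exclusively through files under one
output directory, so any stage can be re-run from its upstream
artifacts.  A single master seed fans out to per-stage seeds through
``numpy.random.SeedSequence``, and a run manifest records the
configuration, software version, wall-clock and SHA-256 hash of every
artifact, so identical config + seed reproduces identical outputs for
the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .features import FieldFeatureExtractor, catalog_names, default_catalog
from .gating import (FucciGatingConfig, apoptotic_filter, gate_table,
                     sample_and_normalize)
from .modeling import (FAMILIES, ModelSpec, cross_validate, evaluate,
                       feature_importance, select_best, train)
from .reporting import (condition_barplot, summaries_frame,
                        summarize_conditions, top_feature_boxplot_table,
                        write_html_report)
from .segmentation import (NucleusROI, SPFilterConfig, find_nuclei,
                           measure_channel_means, sliding_parabola)
from .synthetic_data import (ConditionPreset, FieldGeometry, NoiseParams,
                             default_presets, load_field, simulate_plate)

__all__ = ["RunConfig", "DependencyError", "run", "STAGES"]

log = logging.getLogger("cyclescope")

STAGES = ("simulate", "segment", "extract", "gate", "split", "train",
          "evaluate", "report")
TASKS = ("G1", "earlyS", "SG2M")


class DependencyError(FileNotFoundError):
    """An upstream artifact required by the requested stage is missing."""


@dataclass
class RunConfig:
    """Everything a run needs; YAML-serializable.

    ``cv_subsample`` caps the number of training rows used during
    cross-validation for the expensive families (full training data is
    always used for the final fit of the selected model); 0 means no
    cap.
    """

    seed: int = 1
    out_dir: str = "runs/default"
    cell_line: str = "HeLa"
    fields_per_condition: int = 20
    nuclei_per_field: int = 100
    presets: list[dict] | None = None        # None -> built-in panel
    geometry: dict = field(default_factory=dict)
    noise: dict = field(default_factory=dict)
    sp_curvature: float = 0.005
    smoothing_sigma: float = 2.0
    min_area: int = 50
    min_peak_distance: int = 7
    gating: dict | None = None               # None -> cell-line default
    n_train: int = 7500
    n_val: int = 2500
    fit_bounds_on: str = "train"
    families: list[str] = field(default_factory=lambda: list(FAMILIES))
    tasks: list[str] = field(default_factory=lambda: list(TASKS))
    cv_folds: int = 10
    rf_trees: int = 100
    cv_subsample: dict = field(default_factory=lambda: {
        "svm": 2500, "logreg_backward": 2500, "neural_net": 2500})
    comparison_features: list[str] = field(default_factory=lambda: [
        "Intensity Nucleus Sum", "Nucleus Area"])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    # -- derived objects ----------------------------------------------------

    def stage_seed(self, stage: str) -> int:
        ss = np.random.SeedSequence([self.seed, STAGES.index(stage)])
        return int(ss.generate_state(1)[0] % (2 ** 31))

    def build_presets(self) -> list[ConditionPreset]:
        if self.presets is None:
            return default_presets(self.cell_line)
        return [ConditionPreset(
            cell_line=p.get("cell_line", self.cell_line), drug=p["drug"],
            concentration_m=float(p.get("concentration_m", 0.0)),
            phase_probs=tuple(p["phase_probs"]),
            apoptotic_frac=float(p.get("apoptotic_frac", 0.0)),
            name=p.get("name", "")) for p in self.presets]

    def build_gating(self) -> FucciGatingConfig:
        if self.gating is None:
            return FucciGatingConfig.for_cell_line(self.cell_line)
        return FucciGatingConfig(**{"cell_line": self.cell_line,
                                    **self.gating})

    def model_spec(self, family: str) -> ModelSpec:
        hp = {}
        if family == "random_forest":
            hp["n_estimators"] = self.rf_trees
        return ModelSpec(family=family, hyperparameters=hp,
                         seed=self.stage_seed("train"))


# ---------------------------------------------------------------------------
# manifest helpers


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _record_stage(out: Path, stage: str, seconds: float,
                  outputs: list[Path], config: RunConfig) -> None:
    manifest_path = out / "manifest.json"
    manifest = (json.loads(manifest_path.read_text())
                if manifest_path.exists() else
                {"version": __version__, "config": asdict(config),
                 "stages": {}})
    manifest["stages"][stage] = {
        "seconds": round(seconds, 3),
        "outputs": {str(p.relative_to(out)): _sha256(p)
                    for p in sorted(outputs) if p.is_file()},
    }
    manifest_path.write_text(json.dumps(manifest, indent=1))


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise DependencyError(
            f"missing upstream artifact {path}; run the '{producer}' "
            "stage first")
    return path


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: RunConfig, out: Path) -> list[Path]:
    raw = out / "raw"
    simulate_plate(
        config.build_presets(), config.fields_per_condition, raw,
        seed=config.stage_seed("simulate"),
        nuclei_per_field=config.nuclei_per_field,
        geometry=FieldGeometry(**config.geometry),
        noise=NoiseParams(**config.noise))
    return sorted(raw.iterdir())


def _rois_from_labels(labels: np.ndarray) -> list[NucleusROI]:
    """Rebuild ROI objects from a label-mask raster."""
    from scipy import ndimage as ndi
    rois = []
    for lab, sl in enumerate(ndi.find_objects(labels), start=1):
        if sl is None:
            continue
        mask = labels[sl] == lab
        rows, cols = np.nonzero(mask)
        rois.append(NucleusROI(
            label=lab, bbox=(sl[0].start, sl[1].start, sl[0].stop,
                             sl[1].stop),
            mask=mask, centroid=(sl[0].start + rows.mean(),
                                 sl[1].start + cols.mean()),
            area_px=int(mask.sum())))
    return rois


def stage_segment(config: RunConfig, out: Path) -> list[Path]:
    raw = _require(out / "raw" / "metadata.csv", "simulate").parent
    metadata = pd.read_csv(raw / "metadata.csv")
    seg_dir = out / "segmentation"
    seg_dir.mkdir(parents=True, exist_ok=True)
    sp = SPFilterConfig(curvature=config.sp_curvature)
    rows = []
    outputs = []
    for field_id in metadata["field_id"]:
        fld = load_field(raw / f"{field_id}.tiff")
        corrected = sliding_parabola(fld.pixels[0], sp)
        rois = find_nuclei(corrected, smoothing_sigma=config.smoothing_sigma,
                           min_area=config.min_area,
                           min_peak_distance=config.min_peak_distance)
        labels = np.zeros(corrected.shape, dtype=np.int32)
        for roi in rois:
            r0, c0, r1, c1 = roi.bbox
            labels[r0:r1, c0:c1][roi.mask] = roi.label
            means = measure_channel_means(roi, fld)
            vals = roi.pixel_values(corrected)
            cv = 100.0 * vals.std() / vals.mean() if vals.mean() > 0 else 0.0
            rows.append({
                "field_id": field_id, "label": roi.label,
                "centroid_row": roi.centroid[0],
                "centroid_col": roi.centroid[1],
                "area_px": roi.area_px, "red_mean": means["red"],
                "green_mean": means["green"], "dna_cv": cv})
        mask_path = seg_dir / f"{field_id}_labels.tiff"
        tifffile.imwrite(mask_path, labels)
        outputs.append(mask_path)
    nuclei_path = seg_dir / "nuclei.csv"
    pd.DataFrame(rows).to_csv(nuclei_path, index=False)
    return outputs + [nuclei_path]


def stage_extract(config: RunConfig, out: Path) -> list[Path]:
    raw = _require(out / "raw" / "metadata.csv", "simulate").parent
    seg_dir = out / "segmentation"
    _require(seg_dir / "nuclei.csv", "segment")
    metadata = pd.read_csv(raw / "metadata.csv")
    feat_dir = out / "features"
    feat_dir.mkdir(parents=True, exist_ok=True)
    catalog = default_catalog()
    names = catalog_names(catalog)
    sp = SPFilterConfig(curvature=config.sp_curvature)
    rows = []
    for field_id in metadata["field_id"]:
        fld = load_field(raw / f"{field_id}.tiff")
        labels = tifffile.imread(
            _require(seg_dir / f"{field_id}_labels.tiff", "segment"))
        corrected = sliding_parabola(fld.pixels[0], sp)
        extractor = FieldFeatureExtractor(corrected, fld.pixel_size_um,
                                          catalog)
        for roi in _rois_from_labels(labels):
            vec = extractor.features(roi)
            rows.append({"field_id": field_id, "label": roi.label,
                         **dict(zip(names, vec))})
    features_path = feat_dir / "features.csv"
    pd.DataFrame(rows).to_csv(features_path, index=False)
    catalog_path = feat_dir / "catalog.json"
    catalog_path.write_text(json.dumps([asdict(f) for f in catalog],
                                       indent=1))
    return [features_path, catalog_path]


def stage_gate(config: RunConfig, out: Path) -> list[Path]:
    nuclei = pd.read_csv(_require(
        out / "segmentation" / "nuclei.csv", "segment"))
    features = pd.read_csv(_require(
        out / "features" / "features.csv", "extract"))
    metadata = pd.read_csv(_require(out / "raw" / "metadata.csv", "simulate"))
    ref = config.build_gating()

    table = features.merge(nuclei, on=["field_id", "label"],
                           validate="one_to_one")
    table = table.merge(metadata, on="field_id", how="left")
    gated = gate_table(table, ref)
    n_before = len(gated)
    retained = apoptotic_filter(gated[~gated["excluded"]]
                                if ref.cv_exclusion_enabled else gated, ref)

    gate_dir = out / "dataset"
    gate_dir.mkdir(parents=True, exist_ok=True)
    gated_path = gate_dir / "gated.csv"
    retained.to_csv(gated_path, index=False)
    report = {
        "cell_line": ref.cell_line,
        "red_threshold": ref.red_threshold,
        "green_threshold": ref.green_threshold,
        "cv_exclusion_enabled": ref.cv_exclusion_enabled,
        "n_segmented": n_before,
        "n_excluded": int(n_before - len(retained)),
        "class_counts": retained["fucci_class"].value_counts().to_dict(),
    }
    report_path = gate_dir / "gating_report.json"
    report_path.write_text(json.dumps(report, indent=1))
    return [gated_path, report_path]


def stage_split(config: RunConfig, out: Path) -> list[Path]:
    gated = pd.read_csv(_require(out / "dataset" / "gated.csv", "gate"))
    names = catalog_names()
    split = sample_and_normalize(
        gated, names, n_train=config.n_train, n_val=config.n_val,
        seed=config.stage_seed("split"), fit_bounds_on=config.fit_bounds_on)
    ds = out / "dataset"
    train_path, val_path = ds / "train.csv", ds / "validation.csv"
    split.train.to_csv(train_path, index=False)
    split.validation.to_csv(val_path, index=False)
    bounds_path = ds / "norm_bounds.json"
    bounds_path.write_text(split.bounds.to_json(orient="index"))
    return [train_path, val_path, bounds_path]


def _catalog_hash() -> str:
    return hashlib.sha256(
        "\n".join(catalog_names()).encode()).hexdigest()[:16]


def stage_train(config: RunConfig, out: Path) -> list[Path]:
    train_df = pd.read_csv(_require(out / "dataset" / "train.csv", "split"))
    names = catalog_names()
    X = train_df[names].to_numpy(float)
    models_dir = out / "models"
    models_dir.mkdir(parents=True, exist_ok=True)
    seed = config.stage_seed("train")
    rng = np.random.default_rng(seed)

    cv_rows = []
    selection = {}
    outputs = []
    for task in config.tasks:
        y = train_df[f"label_{task}"].to_numpy(int)
        results = []
        for family in config.families:
            spec = config.model_spec(family)
            cap = int(config.cv_subsample.get(family, 0) or 0)
            if cap and cap < len(y):
                idx = rng.permutation(len(y))[:cap]
                Xc, yc = X[idx], y[idx]
            else:
                Xc, yc = X, y
            t0 = time.time()
            res = cross_validate(spec, Xc, yc, k=config.cv_folds,
                                 seed=seed, task=task)
            log.info("CV %s/%s: mean acc %.3f (%.1fs, n=%d)", task, family,
                     res.mean_accuracy, time.time() - t0, len(yc))
            results.append(res)
            for fold, acc in enumerate(res.fold_accuracies):
                cv_rows.append({"task": task, "family": family,
                                "fold": fold, "accuracy": acc,
                                "n_rows": len(yc)})
        best = select_best(results)
        selection[task] = best
        fitted = train(config.model_spec(best), X, y)
        model_path = models_dir / f"{task}_{best}.joblib"
        joblib.dump({"model": fitted, "family": best, "task": task,
                     "catalog_hash": _catalog_hash(),
                     "version": __version__}, model_path)
        outputs.append(model_path)

    cv_path = models_dir / "cv_results.csv"
    pd.DataFrame(cv_rows).to_csv(cv_path, index=False)
    report_path = models_dir / "model_report.json"
    report_path.write_text(json.dumps({"selection": selection}, indent=1))
    return outputs + [cv_path, report_path]


def stage_evaluate(config: RunConfig, out: Path) -> list[Path]:
    models_dir = out / "models"
    report_path = _require(models_dir / "model_report.json", "train")
    val_df = pd.read_csv(_require(
        out / "dataset" / "validation.csv", "split"))
    names = catalog_names()
    X_val = val_df[names].to_numpy(float)
    report = json.loads(report_path.read_text())
    report["validation"] = {}
    imp_rows = []
    outputs = [report_path]
    for task, family in report["selection"].items():
        bundle = joblib.load(
            _require(models_dir / f"{task}_{family}.joblib", "train"))
        if bundle["catalog_hash"] != _catalog_hash():
            raise RuntimeError("model was trained with a different catalog")
        y_val = val_df[f"label_{task}"].to_numpy(int)
        rep = evaluate(bundle["model"], X_val, y_val, task=task,
                       family=family)
        report["validation"][task] = {
            "family": family, "accuracy": rep.accuracy,
            "sensitivity": rep.sensitivity, "specificity": rep.specificity,
            "auc": rep.auc, "confusion": {"tp": rep.tp, "fp": rep.fp,
                                          "tn": rep.tn, "fn": rep.fn}}
        if hasattr(bundle["model"], "feature_importances_"):
            ranking = feature_importance(bundle["model"], names, task=task)
            for rank, (feat, imp) in enumerate(ranking.ranking, start=1):
                imp_rows.append({"task": task, "rank": rank,
                                 "feature": feat, "importance": imp})
    report_path.write_text(json.dumps(report, indent=1))
    if imp_rows:
        imp_path = models_dir / "importance.csv"
        pd.DataFrame(imp_rows).to_csv(imp_path, index=False)
        outputs.append(imp_path)
    return outputs


def stage_report(config: RunConfig, out: Path) -> list[Path]:
    models_dir = out / "models"
    report = json.loads(_require(models_dir / "model_report.json",
                                 "train").read_text())
    if "validation" not in report:
        raise DependencyError(
            f"{models_dir / 'model_report.json'} lacks validation metrics; "
            "run the 'evaluate' stage first")
    val_df = pd.read_csv(_require(
        out / "dataset" / "validation.csv", "split"))
    names = catalog_names()
    X_val = val_df[names].to_numpy(float)
    for task in ("G1", "SG2M"):
        family = report["selection"][task]
        bundle = joblib.load(models_dir / f"{task}_{family}.joblib")
        proba = bundle["model"].predict_proba(X_val)[:, 1]
        val_df[f"pred_{task}"] = (proba >= 0.5).astype(int)

    rep_dir = out / "report"
    rep_dir.mkdir(parents=True, exist_ok=True)
    summaries = summarize_conditions(val_df)
    summary = summaries_frame(summaries)
    summary_path = rep_dir / "condition_summary.csv"
    summary.to_csv(summary_path, index=False)

    comparisons = top_feature_boxplot_table(
        val_df, config.comparison_features, out_dir=rep_dir)
    comp_df = pd.DataFrame([asdict(c) for c in comparisons])
    comp_path = rep_dir / "group_comparisons.csv"
    comp_df.to_csv(comp_path, index=False)
    condition_barplot(summary, rep_dir)
    html = write_html_report(rep_dir, summary, comparisons, extra={
        "selected models": report["selection"],
        "validation metrics": report["validation"]})
    return [summary_path, comp_path, html]


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "segment": stage_segment,
    "extract": stage_extract,
    "gate": stage_gate,
    "split": stage_split,
    "train": stage_train,
    "evaluate": stage_evaluate,
    "report": stage_report,
}


def run(stage: str, config: RunConfig) -> list[Path]:
    """Execute one stage (or ``all``) and update the run manifest."""
    if stage != "all" and stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from "
                         f"{STAGES + ('all',)}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = STAGES if stage == "all" else (stage,)
    outputs: list[Path] = []
    for st in stages:
        t0 = time.time()
        log.info("stage %s starting", st)
        stage_outputs = _STAGE_FUNCS[st](config, out)
        _record_stage(out, st, time.time() - t0, stage_outputs, config)
        log.info("stage %s done in %.1fs (%d artifacts)", st,
                 time.time() - t0, len(stage_outputs))
        outputs.extend(stage_outputs)
    return outputs
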