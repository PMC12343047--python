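"""End-to-end orchestration with reproducibility metadata.

A single :class:`RunConfig` drives the full chain

    simulate -> proximity metrics -> purity scores -> per-image fits ->
    cohort tests -> spillover evaluation -> survival modelling

writing every stage artefact to an output directory together with a
manifest of SHA-256 content hashes and the resolved configuration, so an
identical config + master seed reproduces identical files. Stage seeds
are derived deterministically from the master seed and the stage name.
Each data-dependent filter (the 100-cell regression gate, the 20-cell
image gate, the 5% missingness gate) logs its casualty counts into the
manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import ccm_regression, deconvolution, spatial_metrics, spillover_eval
from . import survival_analysis as surv
from . import synthetic_data as synth
from .io_data import (
    load_cell_table,
    load_clinical,
    load_marker_classification,
    write_cell_table,
    write_clinical,
    write_marker_classification,
    write_results,
)

logger = logging.getLogger("spatialccm")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    return zlib.crc32(f"{master_seed}:{stage}".encode()) % (2**31 - 1)


@dataclass
class RunConfig:
    out_dir: str = "spatialccm_run"
    # input paths; when None the synthetic stage generates them
    cells_path: str | None = None
    expression_path: str | None = None
    clinical_path: str | None = None
    classification_path: str | None = None
    metric_kind: str = "distance"
    radius: float = 200.0
    cap: float = 200.0
    min_cells: int = 100
    correct: bool = True
    n_trees: int = 500
    fp_cutoff: int = 100
    min_cells_image: int = 20
    max_missing: float = 0.05
    cv_repeats: int = 20
    cv_folds: int = 3
    top_k: int = 10
    run_survival: bool = True
    seed: int = 0
    synthetic: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _synthetic_config(config: RunConfig) -> synth.SyntheticConfig:
    kwargs = dict(config.synthetic)
    planted = [synth.PlantedCCM(**p) for p in kwargs.pop("planted_ccms", [])]
    spill = kwargs.pop("spillover", None)
    survival = kwargs.pop("survival", None)
    return synth.SyntheticConfig(
        planted_ccms=planted,
        spillover=synth.SpilloverConfig(**spill) if spill else None,
        survival=synth.SurvivalConfig(**survival) if survival else None,
        radius=config.radius,
        cap=config.cap,
        seed=stage_seed(config.seed, "simulate"),
        **kwargs,
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute every configured stage; return the artefact manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "artefacts": {}, "filters": {}}

    def emit(name: str, path: Path) -> None:
        manifest["artefacts"][name] = {
            "path": str(path), "sha256": _sha256(path)}

    # -- inputs ----------------------------------------------------------
    clinical = None
    classification = None
    try:
        if config.cells_path is None:
            logger.info("stage simulate: generating synthetic cohort")
            scfg = _synthetic_config(config)
            dataset, truth = synth.generate_cohort(scfg)
            classification = synth.default_marker_classification(scfg)
            cells_p, expr_p = out / "cells.csv", out / "expression.csv"
            write_cell_table(dataset, cells_p, expr_p)
            emit("cells", cells_p)
            emit("expression", expr_p)
            cls_p = out / "marker_classification.csv"
            write_marker_classification(classification, cls_p)
            emit("marker_classification", cls_p)
            if config.run_survival:
                clinical = synth.generate_survival(truth, scfg)
                clin_p = out / "clinical.csv"
                write_clinical(clinical, clin_p)
                emit("clinical", clin_p)
            manifest["stages"].append("simulate")
        else:
            if config.expression_path is None:
                raise ValueError("expression_path required with cells_path")
            dataset = load_cell_table(config.cells_path, config.expression_path)
            if config.classification_path:
                classification = load_marker_classification(
                    config.classification_path)
            if config.run_survival:
                if config.clinical_path is None:
                    raise ValueError(
                        "survival stage requested but no clinical file given")
                clinical = load_clinical(config.clinical_path)
            manifest["stages"].append("load")

        # -- proximity metrics ------------------------------------------
        logger.info("stage metrics: %s metric", config.metric_kind)
        proximity = spatial_metrics.compute_proximity(
            dataset, config.metric_kind, config.radius, config.cap)
        prox_p = out / "proximity.csv"
        proximity.to_csv(prox_p)
        emit("proximity", prox_p)
        manifest["stages"].append("metrics")

        # -- purity -------------------------------------------------------
        purity = None
        if config.correct:
            logger.info("stage purity: random forest, %d trees", config.n_trees)
            clf = deconvolution.fit_cell_type_classifier(
                dataset, n_trees=config.n_trees,
                seed=stage_seed(config.seed, "purity"))
            purity = deconvolution.predict_purity(clf, dataset)
            pur_p = out / "purity.csv"
            purity.to_csv(pur_p)
            emit("purity", pur_p)
            manifest["stages"].append("purity")

        # -- regression ---------------------------------------------------
        logger.info("stage ccm: fitting per-image models")
        fits = ccm_regression.fit_all(
            dataset, proximity, purity=purity, min_cells=config.min_cells)
        n_possible = (len(dataset.image_ids) * len(dataset.cell_types) ** 2
                      * len(dataset.markers))
        manifest["filters"]["min_cells_gate"] = {
            "threshold": config.min_cells,
            "fits_kept": int(len(fits)),
            "fits_possible": n_possible,
        }
        fits_p = out / "fits.csv"
        fits.to_csv(fits_p, index=False)
        emit("fits", fits_p)
        results = ccm_regression.aggregate_and_test(fits)
        res_p = out / "results.csv"
        write_results(results, res_p)
        emit("results", res_p)
        manifest["stages"].append("ccm")

        # -- spillover evaluation ----------------------------------------
        if classification is not None and len(results):
            labelled = spillover_eval.label_relationships(results, classification)
            import warnings as _warnings
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                roc = spillover_eval.partial_roc(labelled, config.fp_cutoff)
            roc_p = out / "partial_roc.csv"
            roc.curve.to_csv(roc_p, index=False)
            emit("partial_roc", roc_p)
            manifest["tp_at_fp_cutoff"] = (
                None if roc.tp_at_fp_cutoff != roc.tp_at_fp_cutoff
                else roc.tp_at_fp_cutoff)
            manifest["stages"].append("eval-spillover")

        # -- survival -----------------------------------------------------
        if config.run_survival and clinical is not None:
            logger.info("stage survival")
            feats = surv.build_feature_matrix(
                fits, min_cells_image=config.min_cells_image,
                max_missing=config.max_missing)
            manifest["filters"]["survival_gates"] = {
                "min_cells_image": config.min_cells_image,
                "max_missing": config.max_missing,
                "columns_kept": int(feats.features.shape[1]),
                "columns_dropped_missingness": len(feats.dropped_columns),
            }
            cox = surv.univariate_cox(feats, clinical)
            cox_p = out / "cox_results.csv"
            cox.to_csv(cox_p, index=False)
            emit("cox_results", cox_p)
            cv = surv.cv_survival_forest(
                feats, clinical, repeats=config.cv_repeats,
                folds=config.cv_folds, top_k=config.top_k,
                seed=stage_seed(config.seed, "survival"),
                n_trees=config.n_trees)
            cv_p = out / "cv_results.csv"
            cv.scores.to_csv(cv_p, index=False)
            emit("cv_results", cv_p)
            manifest["summary"] = {
                "cv_mean_concordance": cv.mean_concordance,
                "cv_sd_concordance": cv.sd_concordance,
            }
            manifest["stages"].append("survival")
    except Exception as exc:
        stage = manifest["stages"][-1] if manifest["stages"] else "setup"
        logger.error("pipeline failed after stage %r: %s", stage, exc)
        manifest["failed_after_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    cfg_p = out / "run_config.yaml"
    config.to_yaml(cfg_p)
    emit("run_config", cfg_p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
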