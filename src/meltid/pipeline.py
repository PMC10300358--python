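"""End-to-end workflow: simulate -> signatures -> QC -> features -> model -> report.

One configured, seeded call produces a run directory with every stage
artifact (corpus exports, signature tables, QC report, feature matrix,
model, predictions, confusion matrix, distinguishability and tally reports)
plus a provenance block recording seeds and counts.  Identical configuration
and seeds give identical numeric outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classifier import (GridSearchSpec, NetConfig, Prediction, SplitSpec,
                         TrainedModel, default_search_grid, grid_search,
                         predict, save_model, split_corpus, train_fann)
from .design import CorpusDesign, default_design, generate_corpus
from .evaluate import (accuracy, confusion_matrix, dl_distinguishability,
                       panel_tallies, visual_distinguishability)
from .features import FeatureMatrix, build_matrix, variable_importance
from .io_mic import read_species_status_table, write_melt_export
from .meltsim import AcquisitionGrid, NoiseModel
from .panel import build_default_panel
from .qc import QCReport, QCThresholds, filter_corpus
from .signatures import ProcessedRun, SignatureConfig, process_run

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_config"]

log = logging.getLogger("meltid.pipeline")


@dataclass
class PipelineConfig:
    outdir: str = "meltid_run"
    grid: AcquisitionGrid = field(default_factory=AcquisitionGrid)
    noise: NoiseModel = field(default_factory=NoiseModel)
    signature: SignatureConfig = field(default_factory=SignatureConfig)
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    split: SplitSpec = field(default_factory=SplitSpec)
    net: NetConfig = field(default_factory=NetConfig)
    search: GridSearchSpec | None = None   # set to use grid search over `net`
    panel_seed: int = 1
    corpus_seed: int = 0
    n_species: int | None = None           # reduce the panel for quick runs
    specimens_per_species: int | None = None
    replicates: int = 3
    test_specimens_per_species: int | None = None
    inject_failures: bool = True            # packaged 33-run manifest
    qc_enabled: bool = True
    write_intermediate: bool = True


@dataclass
class PipelineResult:
    config: PipelineConfig
    truth: pd.DataFrame
    qc_report: QCReport | None
    train_matrix: FeatureMatrix
    test_matrix: FeatureMatrix
    model: TrainedModel
    search_summary: pd.DataFrame | None
    predictions: list[Prediction]
    confusion: pd.DataFrame
    test_accuracy: float
    dl_report: pd.DataFrame
    visual_report: pd.DataFrame
    tallies: dict


def load_config(path) -> PipelineConfig:
    """Build a pipeline configuration from a YAML document."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    sections = {"grid": AcquisitionGrid, "noise": NoiseModel,
                "signature": SignatureConfig, "thresholds": QCThresholds,
                "split": SplitSpec, "net": NetConfig}
    kwargs = {}
    for key, value in doc.items():
        if key in sections:
            if key == "net" and "hidden_layers" in value:
                value["hidden_layers"] = tuple(value["hidden_layers"])
            kwargs[key] = sections[key](**value)
        elif key == "search":
            params = value.pop("params", None) or default_search_grid()
            params = {k: [tuple(v) if isinstance(v, list) and k == "hidden_layers"
                          else v for v in vals] if k == "hidden_layers"
                      else vals for k, vals in params.items()}
            kwargs["search"] = GridSearchSpec(params=params, **value)
        else:
            kwargs[key] = value
    return PipelineConfig(**kwargs)


def _write_signature_table(runs: list[ProcessedRun], channel: str, path: Path) -> None:
    temps = getattr(runs[0], channel).grid.temperatures
    frame = pd.DataFrame([getattr(r, channel).values for r in runs],
                         index=pd.Index([r.run_id for r in runs], name="run_id"),
                         columns=[f"{t:.3f}" for t in temps])
    frame.to_csv(path, float_format="%.6f")


def _design_for(config: PipelineConfig, panel) -> tuple[list, CorpusDesign]:
    if config.n_species is not None:
        panel = panel[:config.n_species]
    names = [m.species_name for m in panel]
    if (config.specimens_per_species is None and config.n_species is None
            and config.replicates == 3 and config.test_specimens_per_species is None):
        design = default_design(panel, seed=config.corpus_seed)
        if not config.inject_failures:
            design.failure_manifest = {}
        return panel, design
    n_spec = config.specimens_per_species or 4
    n_test = config.test_specimens_per_species or 2
    design = CorpusDesign(specimens_per_species={s: n_spec for s in names},
                          test_specimens_per_species={s: n_test for s in names},
                          replicates=config.replicates, seed=config.corpus_seed)
    return panel, design


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    panel = build_default_panel(config.panel_seed)
    panel, design = _design_for(config, panel)
    log.info("simulate: %d species, %d training runs, %d test runs",
             len(panel), design.n_training_runs, design.n_test_runs)
    train_runs, test_runs, truth = generate_corpus(panel, design,
                                                   config.grid, config.noise)
    truth.to_csv(outdir / "truth_manifest.csv", index=False)
    if config.write_intermediate:
        write_melt_export(train_runs, outdir / "train_bs1.csv",
                          outdir / "train_bs2.csv", outdir / "train_metadata.csv")
        write_melt_export(test_runs, outdir / "test_bs1.csv",
                          outdir / "test_bs2.csv", outdir / "test_metadata.csv")

    processed_train = [process_run(r, config.signature) for r in train_runs]
    processed_test = [process_run(r, config.signature) for r in test_runs]
    if config.write_intermediate:
        _write_signature_table(processed_train, "bs1", outdir / "signatures_bs1.csv")
        _write_signature_table(processed_train, "bs2", outdir / "signatures_bs2.csv")

    qc_report = None
    retained = processed_train
    if config.qc_enabled:
        retained, qc_report = filter_corpus(processed_train, config.thresholds)
        qc_report.statuses.to_csv(outdir / "qc_report.csv", index=False)
        with open(outdir / "qc_summary.json", "w") as fh:
            json.dump({"n_input": qc_report.n_input,
                       "n_retained": qc_report.n_retained,
                       "removals_by_cause": qc_report.removals_by_cause},
                      fh, indent=2)
        log.info("qc: retained %d of %d runs", qc_report.n_retained, qc_report.n_input)

    train_matrix = build_matrix(retained)
    test_matrix = build_matrix(processed_test)
    if config.write_intermediate:
        train_matrix.to_frame().to_csv(outdir / "features.csv", index=False,
                                       float_format="%.6f")
    log.info("features: %d x %d", len(train_matrix.run_ids), train_matrix.n_features)

    classes = [m.species_name for m in sorted(panel, key=lambda m: m.species_name)]
    summary = None
    if config.search is not None:
        summary, model = grid_search(train_matrix, config.search, config.split,
                                     classes=classes)
        summary.to_csv(outdir / "gridsearch_summary.csv", index=False)
        log.info("grid search: %d candidates, best validation accuracy %.2f%%",
                 len(summary), model.validation_accuracy)
    else:
        tr, va = split_corpus(train_matrix, config.split)
        model = train_fann(config.net, tr, va, classes=classes)
        log.info("train: validation accuracy %.2f%%", model.validation_accuracy)
    save_model(model, outdir / "model.json")
    model.history.to_csv(outdir / "training_history.csv", index=False)
    importance = variable_importance(model, train_matrix.feature_names)
    importance.head(200).to_csv(outdir / "variable_importance.csv", index=False,
                                float_format="%.6g")

    predictions = predict(model, test_matrix)
    pd.DataFrame([{"run_id": p.run_id, "predicted": p.predicted,
                   "score": float(p.scores.max()), "margin": p.margin}
                  for p in predictions]).to_csv(outdir / "predictions.csv",
                                                index=False, float_format="%.6f")

    panel_order = [m.species_name for m in panel]
    truth_map = dict(zip(test_matrix.run_ids,
                         [l or "" for l in test_matrix.labels]))
    cm = confusion_matrix([truth_map[p.run_id] for p in predictions],
                          [p.predicted for p in predictions], panel_order)
    cm.to_csv(outdir / "confusion_matrix.csv")
    test_acc = accuracy(cm)
    log.info("evaluate: test accuracy %.2f%% (%d of %d)", test_acc,
             int(np.trace(cm.to_numpy())), int(cm.to_numpy().sum()))

    dl_report = dl_distinguishability(predictions, truth_map, panel_order)
    visual_report = visual_distinguishability(panel)
    dl_report.to_csv(outdir / "dl_distinguishability.csv", index=False)
    visual_report.to_csv(outdir / "visual_distinguishability.csv", index=False)
    tallies = panel_tallies(read_species_status_table()) if len(panel) == 28 else {}
    with open(outdir / "metrics.json", "w") as fh:
        json.dump({"test_accuracy": test_acc,
                   "train_accuracy": model.train_accuracy,
                   "validation_accuracy": model.validation_accuracy,
                   "validation_rmse": model.validation_rmse,
                   "tallies": tallies}, fh, indent=2)

    provenance = {
        "package_version": __version__,
        "seeds": {"panel": config.panel_seed, "corpus": config.corpus_seed,
                  "split": config.split.seed, "net": config.net.seed,
                  "search": config.search.seed if config.search else None},
        "counts": {"training_runs": len(train_runs), "test_runs": len(test_runs),
                   "retained_runs": len(retained),
                   "features": train_matrix.n_features},
        "config": {k: v for k, v in asdict(config).items()},
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, default=str)

    return PipelineResult(config=config, truth=truth, qc_report=qc_report,
                          train_matrix=train_matrix, test_matrix=test_matrix,
                          model=model, search_summary=summary,
                          predictions=predictions, confusion=cm,
                          test_accuracy=test_acc, dl_report=dl_report,
                          visual_report=visual_report, tallies=tallies)
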