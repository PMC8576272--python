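"""Orchestration: seeded end-to-end train / predict / cross-validate runs.

A :class:`RunConfig` (loadable from YAML) fully determines a run: data
source (a manifest on disk or an inline simulation), encoder choice,
boosting hyperparameters, threshold policy and the root seed.  Per-stage
seeds are derived from the root seed and logged, so a completed run is
reproducible bit-for-bit with the bypass encoder.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import encoder_net, gbtree, io_formats, metrics, synthetic_data
from .io_formats import LABEL_MISSING, ProteinRecord
from .model import InteractionSiteModel, InteractionSiteResults

logger = logging.getLogger("ppisxgb")


@dataclass
class RunConfig:
    """Everything an end-to-end run needs; serialisable to/from YAML."""

    manifest: str | None = None
    sim: dict | None = None
    encoder: str = "bypass"
    include_global: bool = False
    encoder_config: dict = field(default_factory=dict)
    encoder_epochs: int = 5
    encoder_lr: float = 1e-3
    boost: dict = field(default_factory=dict)
    window_size: int = 7
    max_len: int = 500
    test_fraction: float = 0.167
    threshold: float | str = 0.5
    seed: int = 0
    outdir: str = "run_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _load_records(config: RunConfig) -> list[ProteinRecord]:
    if config.manifest:
        records = io_formats.load_manifest(config.manifest)
    elif config.sim is not None:
        sim_kwargs = dict(config.sim)
        sim_kwargs.setdefault("seed", config.seed)
        records = synthetic_data.simulate_proteins(synthetic_data.SimConfig(**sim_kwargs))
    else:
        raise ValueError("config must provide either 'manifest' or 'sim'")
    n_res = sum(len(r) for r in records)
    labelled = np.concatenate(
        [r.labels[r.labels != LABEL_MISSING] for r in records if r.labels is not None]
        or [np.empty(0, dtype=int)]
    )
    logger.info(
        "dataset: %d proteins, %d residues, %d labelled (positive fraction %.4f)",
        len(records), n_res, labelled.size,
        float(np.mean(labelled == 1)) if labelled.size else float("nan"),
    )
    return records


def _build_model(config: RunConfig, train_records: list[ProteinRecord]) -> InteractionSiteModel:
    enc_cfg = None
    if config.encoder == "cnn":
        kwargs = dict(config.encoder_config)
        kwargs.setdefault("window_size", config.window_size)
        kwargs.setdefault("max_len", config.max_len)
        kwargs.setdefault("seed", config.seed + 101)
        enc_cfg = encoder_net.EncoderConfig(**kwargs)
    boost = gbtree.BoostParams(**config.boost)
    return InteractionSiteModel(
        train_records,
        encoder=config.encoder,
        encoder_config=enc_cfg,
        boost_params=boost,
        include_global=config.include_global,
        window_size=config.window_size,
        max_len=config.max_len,
        encoder_epochs=config.encoder_epochs,
        encoder_lr=config.encoder_lr,
    )


def _apply_threshold(config: RunConfig, results: InteractionSiteResults) -> None:
    if config.threshold == "max_f1":
        thr = results.calibrate_threshold()
        logger.info("threshold calibrated on training scores: %.6f", thr)
    else:
        results.threshold = float(config.threshold)


def _report_json(report: metrics.EvaluationReport) -> str:
    return json.dumps(report.to_dict(), sort_keys=True, indent=1)


@dataclass
class TrainArtifacts:
    results: InteractionSiteResults
    report: metrics.EvaluationReport
    outdir: Path


def run_train(config: RunConfig) -> TrainArtifacts:
    """Split -> (train encoder) -> extract -> boost -> evaluate -> write.

    Writes ``model.json`` (boosted trees), ``encoder.json``,
    ``report.json`` (held-out metrics), ``scores.tsv`` (held-out residue
    scores) and ``config.yaml`` under ``config.outdir``.
    """
    records = _load_records(config)
    parts = metrics.split_proteins(
        records,
        {"train": 1.0 - config.test_fraction, "test": config.test_fraction},
        seed=config.seed,
    )
    logger.info("split: %d train / %d test proteins", len(parts["train"]), len(parts["test"]))

    model = _build_model(config, parts["train"])
    results = model.fit()
    _apply_threshold(config, results)
    report = results.evaluate(parts["test"])
    logger.info("held-out AUROC %.4f AUPRC %.4f recall %.4f",
                report.auroc, report.auprc, report.recall)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "model.json").write_text(results.booster.to_json())
    encoder_net.save_encoder(results.encoder, outdir / "encoder.json")
    (outdir / "report.json").write_text(_report_json(report))
    scores = results.predict(parts["test"])
    scores.to_csv(outdir / "scores.tsv", sep="\t", index=False)
    config.to_yaml(outdir / "config.yaml")
    (outdir / "threshold.json").write_text(json.dumps({"threshold": results.threshold}))
    return TrainArtifacts(results=results, report=report, outdir=outdir)


def run_predict(artifact_dir: str | Path, records: list[ProteinRecord]):
    """Score proteins with saved artifacts; returns (DataFrame, failed ids).

    Proteins missing a PSSM or secondary structure are skipped with an
    error log entry; the rest are scored.
    """
    import pandas as pd

    artifact_dir = Path(artifact_dir)
    encoder = encoder_net.load_encoder(artifact_dir / "encoder.json")
    booster = gbtree.BoostedTreeModel.from_json((artifact_dir / "model.json").read_text())
    thr = json.loads((artifact_dir / "threshold.json").read_text())["threshold"]
    rows, failed = [], []
    for rec in records:
        if rec.pssm is None or rec.ss9 is None:
            logger.error("%s: missing %s; skipped", rec.id,
                         "PSSM" if rec.pssm is None else "secondary structure")
            failed.append(rec.id)
            continue
        reps = encoder.extract_all(rec)
        scores = booster.predict_proba(reps)
        rows.extend((rec.id, i, float(s), int(s >= thr)) for i, s in enumerate(scores))
    return pd.DataFrame(rows, columns=["id", "pos", "score", "call"]), failed


@dataclass
class CrossvalResult:
    fold_reports: list[metrics.EvaluationReport]
    mean: dict[str, float]
    sd: dict[str, float]
    excluded: list[int] = field(default_factory=list)


_AGG_METRICS = ("acc", "precision", "recall", "f1", "mcc", "auroc", "auprc")


def run_crossval(config: RunConfig, k: int) -> CrossvalResult:
    """Protein-level k-fold cross-validation of the full pipeline."""
    records = _load_records(config)
    folds = metrics.kfold(records, k, seed=config.seed)
    reports: list[metrics.EvaluationReport] = []
    excluded: list[int] = []
    for fi, (train, held) in enumerate(folds):
        model = _build_model(config, train)
        results = model.fit()
        _apply_threshold(config, results)
        try:
            rep = results.evaluate(held)
        except ValueError as exc:
            logger.warning("fold %d excluded from aggregation: %s", fi, exc)
            excluded.append(fi)
            continue
        reports.append(rep)
        logger.info("fold %d: AUROC %.4f", fi, rep.auroc)
    if not reports:
        raise ValueError("every fold failed evaluation")
    mean = {m: float(np.mean([getattr(r, m) for r in reports])) for m in _AGG_METRICS}
    sd = {m: float(np.std([getattr(r, m) for r in reports])) for m in _AGG_METRICS}
    return CrossvalResult(fold_reports=reports, mean=mean, sd=sd, excluded=excluded)
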