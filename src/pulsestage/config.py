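"""Pipeline configuration, validation, and the stage runner.

Every fixed constant of the analysis lives in one auditable place: the
33-sample beat grid, the 20-beat smoothing window, the 10-fold 10% bootstrap,
the C grid, the presyncope thresholds (80 mmHg floor; 25/15/15 per-minute
drops), the 200 Hz sampling rate and the 30-min LBNP tolerance limit. A
single global seed deterministically derives the generator stream (seed) and
the evaluation stream (seed + 1), so partial re-runs reproduce exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .beats import BeatConfig, BeatMatrix, build_beat_matrix
from .evaluation import EvalConfig, loso_bootstrap_evaluate, severity_trend
from .features import fit_pca, project
from .io import read_recording, write_recording
from .labeling import ClassScheme, PresyncopeCriteria
from .svm import train_svm
from .synth import SyntheticConfig, generate_cohort

__all__ = [
    "PipelineConfig",
    "load_config",
    "validate_config",
    "config_hash",
    "run_pipeline",
    "STAGES",
]

logger = logging.getLogger("pulsestage")

STAGES = ("simulate", "extract", "features", "train", "evaluate")

_SECTION_TYPES = {
    "synthetic": SyntheticConfig,
    "beats": BeatConfig,
    "criteria": PresyncopeCriteria,
    "evaluation": EvalConfig,
}


@dataclass
class PipelineConfig:
    """Nested configuration of the whole pipeline."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    beats: BeatConfig = field(default_factory=BeatConfig)
    criteria: PresyncopeCriteria = field(default_factory=PresyncopeCriteria)
    evaluation: EvalConfig = field(default_factory=EvalConfig)
    out_dir: str = "pulsestage_out"
    log_level: str = "INFO"
    seed: int = 0

    def reseeded(self, seed: int) -> "PipelineConfig":
        """Derive all stream seeds from one global seed."""
        return dataclasses.replace(
            self,
            seed=seed,
            synthetic=dataclasses.replace(self.synthetic, seed=seed),
            evaluation=dataclasses.replace(self.evaluation, seed=seed + 1),
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Build a PipelineConfig from a YAML document (None: all defaults)."""
    doc = {}
    if path is not None:
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ValueError(f"{path}: expected a mapping document")
    kwargs: dict = {}
    for section, cls in _SECTION_TYPES.items():
        block = doc.get(section, {}) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(block) - known
        if unknown:
            raise ValueError(f"{section}: unknown fields {sorted(unknown)}")
        block = {
            k: tuple(v) if isinstance(v, list) else v for k, v in block.items()
        }
        kwargs[section] = cls(**block)
    for key in ("out_dir", "log_level", "seed"):
        if key in doc:
            kwargs[key] = doc[key]
    cfg = PipelineConfig(**kwargs)
    return cfg.reseeded(int(doc.get("seed", cfg.seed)))


def validate_config(path: str | Path | None) -> list[str]:
    """Field-level invariant violations of a config document (empty = valid)."""
    violations: list[str] = []
    doc = {}
    if path is not None:
        try:
            with open(path) as fh:
                doc = yaml.safe_load(fh) or {}
        except OSError as exc:
            return [f"unreadable config: {exc}"]
        if not isinstance(doc, dict):
            return ["config must be a mapping document"]
    for section, cls in _SECTION_TYPES.items():
        block = doc.get(section, {}) or {}
        block = {k: tuple(v) if isinstance(v, list) else v for k, v in block.items()}
        known = {f.name for f in dataclasses.fields(cls)}
        for k in sorted(set(block) - known):
            violations.append(f"{section}.{k}: unknown field")
        try:
            cls(**{k: v for k, v in block.items() if k in known})
        except (ValueError, TypeError) as exc:
            violations.append(f"{section}: {exc}")
    return violations


def config_hash(cfg: PipelineConfig) -> str:
    """Stable digest of every semantic field of the configuration."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=float)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _setup_logging(cfg: PipelineConfig, out: Path) -> None:
    logger.setLevel(cfg.log_level.upper())
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for h in (logging.StreamHandler(sys.stderr), logging.FileHandler(out / "run.log")):
        h.setFormatter(fmt)
        logger.addHandler(h)


def _stamp(cfg: PipelineConfig, out: Path) -> None:
    meta = {"config_hash": config_hash(cfg), "seed": cfg.seed}
    (out / "run_meta.json").write_text(json.dumps(meta, indent=2))


def run_pipeline(
    config_path: str | Path | None = None,
    stages: tuple[str, ...] = STAGES,
    seed: int | None = None,
    out_dir: str | Path | None = None,
) -> Path:
    """Execute the requested pipeline stages in order; returns the out dir.

    Stages: simulate (synthetic cohort to per-subject signal/marks files),
    extract (beat matrix CSV), features (PCA basis artifacts), train (one
    staging model on all presyncope data), evaluate (the full LOSO bootstrap
    protocol with metrics and trace artifacts).
    """
    problems = validate_config(config_path)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    cfg = load_config(config_path)
    if seed is not None:
        cfg = cfg.reseeded(int(seed))
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(cfg, out)
    _stamp(cfg, out)
    logger.info("config %s seed %d stages %s", config_hash(cfg), cfg.seed, stages)

    data_dir = out / "data"
    matrix: BeatMatrix | None = None

    if "simulate" in stages:
        data_dir.mkdir(exist_ok=True)
        cohort = generate_cohort(cfg.synthetic, cfg.criteria)
        gt_rows = []
        for rec, gt in cohort:
            write_recording(
                rec, data_dir / f"{rec.subject_id}_signal.csv",
                data_dir / f"{rec.subject_id}_marks.yaml",
            )
            gt_rows.append(
                {
                    "subject_id": gt.subject_id,
                    "end_reason": gt.end_reason,
                    "presyncope_time_s": gt.presyncope_time_s,
                }
            )
        pd.DataFrame(gt_rows).to_csv(out / "ground_truth.csv", index=False)
        logger.info("simulated %d subjects into %s", len(cohort), data_dir)

    if "extract" in stages:
        recs = [
            read_recording(p, p.with_name(p.name.replace("_signal.csv", "_marks.yaml")))
            for p in sorted(data_dir.glob("*_signal.csv"))
        ]
        matrix = build_beat_matrix(recs, cfg.beats, ClassScheme())
        matrix.to_csv(out / "beats.csv")
        excluded = {r.subject_id for r in recs} - set(matrix.subjects)
        for sid in sorted(excluded):
            logger.warning("subject %s excluded (no usable beats)", sid)
        logger.info("extracted %d beats from %d subjects",
                    len(matrix), len(matrix.subjects))

    def _load_matrix() -> BeatMatrix:
        reasons = {}
        gt_path = out / "ground_truth.csv"
        if gt_path.exists():
            df = pd.read_csv(gt_path)
            reasons = dict(zip(df.subject_id, df.end_reason))
        return BeatMatrix.from_csv(out / "beats.csv", end_reasons=reasons)

    if "features" in stages:
        matrix = matrix if matrix is not None else _load_matrix()
        basis = fit_pca(matrix, fitted_on="global")
        np.savetxt(out / "pca_mean.csv", basis.mean_vector[None], delimiter=",")
        np.savetxt(out / "pca_components.csv", basis.components, delimiter=",")
        np.savetxt(out / "pca_variance.csv", basis.explained_variance[None],
                   delimiter=",")
        logger.info("PCA basis written (%d components)", basis.n_components)

    if "train" in stages:
        matrix = matrix if matrix is not None else _load_matrix()
        pre = matrix.subset(
            np.isin(
                matrix.subject_ids,
                [s for s in matrix.subjects
                 if matrix.end_reasons.get(s) == "presyncope"],
            )
        )
        basis = fit_pca(pre, fitted_on="train")
        feats = project(basis, pre, cfg.evaluation.k_components, "train")
        model = train_svm(feats, cfg.evaluation.C, tol=cfg.evaluation.svm_tol)
        doc = {
            "C": model.C, "k": model.k,
            "classes_present": model.classes_present.tolist(),
            "pairs": [list(p) for p in model.pairs],
            "weights": model.weights.tolist(),
            "biases": model.biases.tolist(),
        }
        (out / "model.json").write_text(json.dumps(doc, indent=2))
        logger.info("trained staging model at C=%g on %d beats",
                    model.C, len(feats))

    if "evaluate" in stages:
        matrix = matrix if matrix is not None else _load_matrix()
        traces, report = loso_bootstrap_evaluate(matrix, cfg.evaluation)
        trends = {s: severity_trend(t, cfg.evaluation) for s, t in traces.items()}
        metrics = {
            "config_hash": config_hash(cfg),
            "seed": cfg.seed,
            "pooled_kappa": report.pooled_kappa,
            "overall_accuracy_pct": report.overall_accuracy,
            "overall_mse": report.overall_mse,
            "severity_trend": trends,
            "per_subject": {
                s: {
                    "accuracy_pct": m["accuracy"].tolist(),
                    "mse": m["mse"].tolist(),
                    "overall_accuracy_pct": m["overall_accuracy"],
                    "overall_mse": m["overall_mse"],
                    "kappa": m["kappa"],
                }
                for s, m in report.per_subject.items()
            },
        }
        (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
        report.table.to_csv(out / "table_metrics.csv")
        np.savetxt(out / "pooled_confusion.csv", report.pooled_confusion,
                   fmt="%d", delimiter=",")
        trace_dir = out / "traces"
        trace_dir.mkdir(exist_ok=True)
        for s, t in traces.items():
            df = pd.DataFrame(
                {"time_s": t.times_s, "true_class": t.true_labels,
                 **{f"model_{b + 1:02d}": t.raw[:, b]
                    for b in range(t.raw.shape[1])},
                 "averaged": t.averaged}
            )
            df.to_csv(trace_dir / f"{s}_trace.csv", index=False)
        logger.info("evaluation done: kappa=%.3f accuracy=%.1f%%",
                    report.pooled_kappa, report.overall_accuracy)
    return out
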