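"""Leave-one-subject-out bootstrap evaluation of the staging pipeline.

Protocol: every subject is held out in turn; from the pooled beats of the
remaining presyncope subjects (tolerant subjects never enter training) ten
random 10% subsamples are drawn, one linear SVM is trained per subsample, and
all ten models predict every held-out beat. Each model's discrete class trace
is smoothed with a trailing 20-beat moving average and the ten smoothed
traces are averaged into one continuous trace in [0, 3] — the subject's
modeled hypovolemia progression. Smoothing and averaging commute (both are
linear), so the order is immaterial.

Metrics: per-class accuracy (rounded trace, ties rounding toward the less
severe class) and per-class MSE of the continuous trace; cohort tables report
the median [IQR] across presyncope subjects, plus a single Cohen's kappa from
the pooled confusion matrix. Tolerant subjects are evaluated as a
false-positive check through the severity-trend call (increase vs
stagnation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .beats import BeatMatrix
from .features import PCABasis, fit_pca, project
from .svm import C_GRID, predict_classes, train_svm

__all__ = [
    "EvalConfig",
    "PredictionTrace",
    "MetricsReport",
    "moving_average",
    "round_classes",
    "confusion_matrix",
    "cohen_kappa",
    "per_class_metrics",
    "aggregate_cohort",
    "severity_trend",
    "loso_bootstrap_evaluate",
    "c_grid_sweep",
    "component_addition_curve",
]

N_CLASSES = 4


@dataclass(frozen=True)
class EvalConfig:
    """Evaluation-protocol parameters (defaults are the study values)."""

    n_bootstrap: int = 10
    subsample_fraction: float = 0.10
    smooth_window_beats: int = 20
    C: float = 0.01
    C_grid: tuple[float, ...] = C_GRID
    k_components: int = 5
    pca_scope: str = "fold"            # "fold" (no leakage) or "global"
    seed: int = 0
    trend_delta: float = 0.5           # classes
    trend_tail_fraction: float = 0.10  # tail of the LBNP segment
    trend_mid_window: tuple[float, float] = (0.4, 0.6)
    with_replacement: bool = False
    max_redraws: int = 100
    svm_tol: float = 1e-4

    def __post_init__(self) -> None:
        if not 0.0 < self.subsample_fraction <= 1.0:
            raise ValueError("subsample_fraction must lie in (0, 1]")
        if self.smooth_window_beats < 1:
            raise ValueError("smooth_window_beats must be >= 1")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if not all(c > 0 for c in self.C_grid) or not self.C > 0:
            raise ValueError("all C values must be positive")
        if self.pca_scope not in ("fold", "global"):
            raise ValueError("pca_scope must be 'fold' or 'global'")
        if self.k_components < 1:
            raise ValueError("k_components must be >= 1")


@dataclass
class PredictionTrace:
    """All model outputs for one held-out subject."""

    subject_id: str
    end_reason: str
    times_s: np.ndarray       # beat onsets
    true_labels: np.ndarray
    raw: np.ndarray           # (n_beats, n_models) integer classes
    smoothed: np.ndarray      # (n_beats, n_models) continuous
    averaged: np.ndarray      # (n_beats,) continuous in [0, 3]
    baseline_start_s: float
    lbnp_onset_s: float
    protocol_end_s: float


@dataclass
class MetricsReport:
    """Per-subject and pooled performance of one evaluation run."""

    per_subject: dict[str, dict] = field(default_factory=dict)
    pooled_confusion: np.ndarray = field(
        default_factory=lambda: np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    )
    pooled_kappa: float = float("nan")
    overall_accuracy: float = float("nan")
    overall_mse: float = float("nan")
    table: pd.DataFrame | None = None


def moving_average(trace: np.ndarray, window: int = 20) -> np.ndarray:
    """Trailing moving average; early positions average available history.

    Output length equals input length; a window of 1 is the identity.
    """
    x = np.asarray(trace, dtype=float)
    if x.size == 0:
        raise ValueError("empty trace")
    if window < 1:
        raise ValueError("window must be >= 1")
    c = np.concatenate(([0.0], np.cumsum(x)))
    i = np.arange(1, x.size + 1)
    lo = np.maximum(i - window, 0)
    return (c[i] - c[lo]) / (i - lo)


def round_classes(trace: np.ndarray) -> np.ndarray:
    """Round a continuous trace to classes; x.5 rounds toward lower severity."""
    return np.clip(np.ceil(np.asarray(trace, dtype=float) - 0.5), 0, N_CLASSES - 1).astype(int)


def confusion_matrix(true_labels: np.ndarray, pred_classes: np.ndarray) -> np.ndarray:
    """4x4 count matrix, rows = true class, columns = predicted class."""
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(pred_classes, dtype=int)
    if t.size != p.size:
        raise ValueError("label vectors must be aligned")
    if t.size and (t.min() < 0 or t.max() >= N_CLASSES or p.min() < 0 or p.max() >= N_CLASSES):
        raise ValueError(f"labels must lie in 0..{N_CLASSES - 1}")
    conf = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    np.add.at(conf, (t, p), 1)
    return conf


def cohen_kappa(confusion: np.ndarray) -> float:
    """Chance-corrected agreement from a confusion matrix.

    kappa = (p_o - p_e) / (1 - p_e) with observed agreement p_o = trace/N and
    chance agreement p_e = sum_c row_c * col_c / N^2. The degenerate case
    p_e = 1 (all mass in one cell) returns 0 by convention.
    """
    conf = np.asarray(confusion, dtype=float)
    n = conf.sum()
    if n <= 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(conf) / n
    p_e = float(conf.sum(axis=1) @ conf.sum(axis=0)) / n**2
    if np.isclose(p_e, 1.0):
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def per_class_metrics(trace: PredictionTrace) -> dict:
    """Accuracy (%) and MSE per true class from the averaged trace.

    Accuracy uses the rounded trace; MSE uses the continuous trace, which is
    what makes sub-unit per-class errors possible. Classes absent from the
    subject are reported as NaN and excluded from cohort medians.
    """
    rounded = round_classes(trace.averaged)
    acc = np.full(N_CLASSES, np.nan)
    mse = np.full(N_CLASSES, np.nan)
    for c in range(N_CLASSES):
        m = trace.true_labels == c
        if not m.any():
            continue
        acc[c] = 100.0 * np.mean(rounded[m] == c)
        mse[c] = float(np.mean((trace.averaged[m] - c) ** 2))
    overall_acc = 100.0 * np.mean(rounded == trace.true_labels)
    overall_mse = float(np.mean((trace.averaged - trace.true_labels) ** 2))
    return {
        "accuracy": acc,
        "mse": mse,
        "overall_accuracy": float(overall_acc),
        "overall_mse": overall_mse,
        "confusion": confusion_matrix(trace.true_labels, rounded),
    }


def severity_trend(trace: PredictionTrace, cfg: EvalConfig | None = None) -> str:
    """Classify a subject's modeled progression: ``increase`` or ``stagnation``.

    ``increase`` requires the averaged trace over the final tail of the LBNP
    segment to exceed BOTH the baseline mean and the mid-LBNP mean by at
    least ``trend_delta`` classes: a subject whose trace rose early but then
    plateaued (the tolerant phenotype) therefore counts as stagnation even
    though it sits above baseline.
    """
    cfg = cfg or EvalConfig()
    t = trace.times_s
    base = (t >= trace.baseline_start_s) & (t < trace.lbnp_onset_s)
    if not base.any():
        raise ValueError(f"{trace.subject_id}: no baseline beats in trace")
    dur = trace.protocol_end_s - trace.lbnp_onset_s
    tail = t >= trace.protocol_end_s - cfg.trend_tail_fraction * dur
    m0, m1 = cfg.trend_mid_window
    mid = (t >= trace.lbnp_onset_s + m0 * dur) & (t <= trace.lbnp_onset_s + m1 * dur)
    if not tail.any():
        return "stagnation"
    tail_mean = float(trace.averaged[tail].mean())
    base_mean = float(trace.averaged[base].mean())
    rising = tail_mean - base_mean >= cfg.trend_delta
    if mid.any():
        rising = rising and (tail_mean - float(trace.averaged[mid].mean()) >= cfg.trend_delta)
    return "increase" if rising else "stagnation"


def _draw_subsample(
    rng: np.random.Generator,
    labels: np.ndarray,
    size: int,
    with_replacement: bool,
    max_redraws: int,
) -> np.ndarray:
    """Index subsample of the training pool containing at least two classes."""
    n = labels.size
    for _ in range(max_redraws + 1):
        idx = rng.choice(n, size=size, replace=with_replacement)
        if np.unique(labels[idx]).size >= 2:
            return idx
    raise RuntimeError(f"no subsample with >= 2 classes after {max_redraws} redraws")


def loso_bootstrap_evaluate(
    matrix: BeatMatrix,
    cfg: EvalConfig | None = None,
    C: float | None = None,
    k: int | None = None,
) -> tuple[dict[str, PredictionTrace], MetricsReport]:
    """Run the full leave-one-subject-out bootstrap protocol.

    Every subject is evaluated; only presyncope subjects contribute training
    beats and pooled metrics. Subsample draws are derived from ``cfg.seed``
    and the held-out subject alone, so sweeps over C or k reuse identical
    draws. Returns the per-subject traces and the cohort metrics report.
    """
    cfg = cfg or EvalConfig()
    C = cfg.C if C is None else C
    k = cfg.k_components if k is None else k
    subjects = matrix.subjects
    train_subjects = [s for s in subjects if matrix.end_reasons.get(s) == "presyncope"]
    if len(train_subjects) < 3:
        raise ValueError("need at least 3 presyncope subjects to train")

    global_basis: PCABasis | None = None
    if cfg.pca_scope == "global":
        global_basis = fit_pca(matrix, fitted_on="global")

    traces: dict[str, PredictionTrace] = {}
    report = MetricsReport()
    for si, sid in enumerate(subjects):
        pool = matrix.subset(
            np.isin(matrix.subject_ids, [s for s in train_subjects if s != sid])
        )
        assert sid not in set(pool.subject_ids.tolist())  # leakage guard
        fold_tag = "global" if global_basis is not None else f"excl:{sid}"
        basis = global_basis or fit_pca(pool, fitted_on=fold_tag)
        pool_feats = project(basis, pool, k, expect_fitted_on=fold_tag)
        held = matrix.for_subject(sid)
        held_feats = project(basis, held, k, expect_fitted_on=fold_tag)

        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(si,)))
        size = int(np.ceil(cfg.subsample_fraction * len(pool)))
        raw = np.empty((len(held), cfg.n_bootstrap), dtype=int)
        smoothed = np.empty((len(held), cfg.n_bootstrap))
        drawn_subjects: set[str] = set()
        for b in range(cfg.n_bootstrap):
            idx = _draw_subsample(
                rng, pool_feats.labels, size, cfg.with_replacement, cfg.max_redraws
            )
            drawn_subjects.update(pool_feats.subject_ids[idx].tolist())
            sub = subset_features(pool_feats, idx)
            model = train_svm(sub, C, tol=cfg.svm_tol)
            raw[:, b] = predict_classes(model, held_feats)
            smoothed[:, b] = moving_average(raw[:, b], cfg.smooth_window_beats)
        averaged = smoothed.mean(axis=1)

        rec_marks = _marks_for(matrix, sid)
        trace = PredictionTrace(
            subject_id=sid,
            end_reason=matrix.end_reasons.get(sid, "presyncope"),
            times_s=held.onsets_s.copy(),
            true_labels=held.labels.copy(),
            raw=raw,
            smoothed=smoothed,
            averaged=averaged,
            **rec_marks,
        )
        traces[sid] = trace
        metrics = per_class_metrics(trace)
        metrics["kappa"] = cohen_kappa(metrics["confusion"])
        # protocol diagnostics: which subjects actually trained this fold's
        # models, and which basis scored its beats
        metrics["train_subject_ids"] = sorted(drawn_subjects)
        metrics["pca_fitted_on"] = fold_tag
        report.per_subject[sid] = metrics
        if trace.end_reason == "presyncope":
            report.pooled_confusion += metrics["confusion"]

    report.pooled_kappa = cohen_kappa(report.pooled_confusion)
    n_pooled = report.pooled_confusion.sum()
    report.overall_accuracy = 100.0 * np.trace(report.pooled_confusion) / n_pooled
    pre = [s for s in subjects if traces[s].end_reason == "presyncope"]
    report.overall_mse = float(
        np.mean(
            np.concatenate(
                [(traces[s].averaged - traces[s].true_labels) ** 2 for s in pre]
            )
        )
    )
    report.table = aggregate_cohort(
        {s: report.per_subject[s] for s in pre}, report.pooled_kappa
    )
    return traces, report


def subset_features(feats, idx):
    """Row-subset of a FeatureMatrix (helper for subsample training)."""
    from .features import FeatureMatrix

    return FeatureMatrix(
        scores=feats.scores[idx],
        labels=feats.labels[idx],
        subject_ids=feats.subject_ids[idx],
        onsets_s=feats.onsets_s[idx],
        fitted_on=feats.fitted_on,
    )


def _marks_for(matrix: BeatMatrix, sid: str) -> dict:
    """Protocol anchors for a subject, reconstructed from its labeled beats."""
    sub = matrix.for_subject(sid)
    t, lab = sub.onsets_s, sub.labels
    lbnp = t[lab > 0]
    base = t[lab == 0]
    onset = float(lbnp.min()) if lbnp.size else float(t.max())
    return {
        "baseline_start_s": float(base.min()) if base.size else float(t.min()),
        "lbnp_onset_s": onset,
        "protocol_end_s": float(t.max()),
    }


def aggregate_cohort(per_subject: dict[str, dict], pooled_kappa: float) -> pd.DataFrame:
    """Median [IQR] table across subjects: MSE and accuracy per class plus
    overall, and the single pooled kappa."""
    if not per_subject:
        raise ValueError("no subjects to aggregate")

    def med_iqr(values: list[float]) -> tuple[float, float]:
        v = np.asarray([x for x in values if np.isfinite(x)], dtype=float)
        if v.size == 0:
            return float("nan"), float("nan")
        q25, q50, q75 = np.percentile(v, [25, 50, 75])
        return float(q50), float(q75 - q25)

    rows = []
    for metric in ("mse", "accuracy"):
        row_m: dict = {"metric": metric}
        for c in range(N_CLASSES):
            m, i = med_iqr([s[metric][c] for s in per_subject.values()])
            row_m[f"class_{c}_median"] = m
            row_m[f"class_{c}_iqr"] = i
        key = f"overall_{metric}"
        m, i = med_iqr([s[key] for s in per_subject.values()])
        row_m["overall_median"] = m
        row_m["overall_iqr"] = i
        rows.append(row_m)
    df = pd.DataFrame(rows).set_index("metric")
    df.attrs["kappa"] = float(pooled_kappa)
    return df


def c_grid_sweep(
    matrix: BeatMatrix, cfg: EvalConfig | None = None
) -> dict[float, tuple[dict[str, PredictionTrace], MetricsReport]]:
    """Full evaluation at every C of the grid, identical draws across C."""
    cfg = cfg or EvalConfig()
    if not cfg.C_grid:
        raise ValueError("empty C grid")
    return {C: loso_bootstrap_evaluate(matrix, cfg, C=C) for C in cfg.C_grid}


def component_addition_curve(
    matrix: BeatMatrix,
    k_values: list[int],
    cfg: EvalConfig | None = None,
    C: float | None = None,
) -> pd.DataFrame:
    """Stepwise component addition: metrics of the full protocol per k.

    One row per requested k with pooled kappa, overall accuracy (%) and
    overall MSE; used to locate the point where added shape modes stop
    improving the staging.
    """
    cfg = cfg or EvalConfig()
    if not k_values or any(k < 1 for k in k_values):
        raise ValueError("k_values must be positive")
    if list(k_values) != sorted(k_values):
        raise ValueError("k_values must be increasing")
    rows = []
    for k in k_values:
        _, rep = loso_bootstrap_evaluate(matrix, cfg, C=C, k=k)
        rows.append(
            {
                "k": k,
                "kappa": rep.pooled_kappa,
                "overall_accuracy": rep.overall_accuracy,
                "overall_mse": rep.overall_mse,
            }
        )
    return pd.DataFrame(rows).set_index("k")
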