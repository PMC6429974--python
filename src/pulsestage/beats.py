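"""Beat segmentation, calibration-beat removal, and fixed-length resampling.

The continuous pressure tracing is cut into foot-to-foot beats (diastolic
minimum to the next diastolic minimum). Each foot is located as the local
pressure minimum preceding the steepest upstroke, where upstrokes are maxima
of the low-pass-filtered first difference with a 0.25-s refractory period.
Beats contaminated by calibration intervals are dropped, survivors are
resampled with a monotone cubic Hermite interpolant (Fritsch-Carlson / PCHIP,
which cannot overshoot the raw range) onto exactly 33 points spanning the
beat in normalized time, endpoints included. Amplitude is deliberately kept
in absolute mmHg: the pressure level itself is informative for staging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.signal import butter, filtfilt, find_peaks

from .io import PressureRecording
from .labeling import ClassScheme, assign_classes

__all__ = [
    "BeatConfig",
    "Beat",
    "NormalizedBeat",
    "BeatMatrix",
    "detect_beats",
    "remove_calibration_beats",
    "resample_beat",
    "build_beat_matrix",
]

#: Number of samples per normalized beat; the fixed feature-vector length.
N_SAMPLES = 33


@dataclass(frozen=True)
class BeatConfig:
    """Tunable beat-segmentation parameters (defaults are the study values)."""

    n_samples: int = N_SAMPLES
    min_duration_s: float = 0.25   # physiologic validity band (240 bpm)
    max_duration_s: float = 2.5    # (24 bpm)
    min_pulse_pressure_mmHg: float = 10.0
    refractory_s: float = 0.25
    lowpass_hz: float = 10.0
    flat_range_mmHg: float = 1.0   # below this total range: no beats

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        if not 0 < self.min_duration_s < self.max_duration_s:
            raise ValueError("invalid duration band")


@dataclass
class Beat:
    """One foot-to-foot cardiac cycle of the pressure wave."""

    subject_id: str
    onset_s: float
    duration_s: float
    raw: np.ndarray
    sap_mmHg: float
    dap_mmHg: float
    map_mmHg: float
    hr_bpm: float


@dataclass
class NormalizedBeat:
    """A beat resampled to exactly 33 points on [0,1] normalized time."""

    subject_id: str
    onset_s: float
    values: np.ndarray
    label: int = -1


@dataclass
class BeatMatrix:
    """Stacked normalized beats with aligned labels and bookkeeping."""

    values: np.ndarray                 # (n_beats, 33) in mmHg
    labels: np.ndarray                 # (n_beats,) in {0..3}, -1 if unlabeled
    subject_ids: np.ndarray            # (n_beats,) str
    onsets_s: np.ndarray               # (n_beats,)
    end_reasons: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != N_SAMPLES:
            raise ValueError(f"values must be (n, {N_SAMPLES})")
        n = self.values.shape[0]
        if not (self.labels.size == self.subject_ids.size == self.onsets_s.size == n):
            raise ValueError("misaligned bookkeeping vectors")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def subjects(self) -> list[str]:
        """Distinct subject ids in first-appearance order."""
        return list(dict.fromkeys(self.subject_ids.tolist()))

    def subset(self, mask: np.ndarray) -> "BeatMatrix":
        return BeatMatrix(
            values=self.values[mask],
            labels=self.labels[mask],
            subject_ids=self.subject_ids[mask],
            onsets_s=self.onsets_s[mask],
            end_reasons=self.end_reasons,
        )

    def for_subject(self, subject_id: str) -> "BeatMatrix":
        return self.subset(self.subject_ids == subject_id)

    def to_frame(self) -> pd.DataFrame:
        cols = {f"v{i + 1:02d}": self.values[:, i] for i in range(N_SAMPLES)}
        return pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "onset_s": self.onsets_s,
                "label": self.labels,
                **cols,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, end_reasons: dict[str, str] | None = None) -> "BeatMatrix":
        df = pd.read_csv(path)
        vals = df[[f"v{i + 1:02d}" for i in range(N_SAMPLES)]].to_numpy(float)
        return cls(
            values=vals,
            labels=df["label"].to_numpy(int),
            subject_ids=df["subject_id"].to_numpy(str),
            onsets_s=df["onset_s"].to_numpy(float),
            end_reasons=end_reasons or {},
        )


def detect_beats(rec: PressureRecording, cfg: BeatConfig | None = None) -> list[Beat]:
    """Segment a recording into validated foot-to-foot beats.

    Upstrokes are maxima of the 10-Hz low-passed first difference separated by
    at least the refractory period; each foot is the pressure minimum in the
    0.3 s preceding its upstroke (located on the smoothed signal, refined on
    the raw signal). Beats outside the physiologic duration band or with
    pulse pressure below 10 mmHg are discarded.
    """
    cfg = cfg or BeatConfig()
    x = rec.pressure
    if x.size < int(2 * rec.fs):
        raise ValueError("recording must be at least 2 s long")
    if np.ptp(x) < cfg.flat_range_mmHg:
        warnings.warn(f"{rec.subject_id}: flat signal, no beats detected")
        return []
    nyq = rec.fs / 2.0
    b, a = butter(4, min(cfg.lowpass_hz / nyq, 0.99))
    smooth = filtfilt(b, a, x)
    deriv = np.diff(smooth) * rec.fs
    height = 0.2 * np.percentile(deriv[deriv > 0], 99) if np.any(deriv > 0) else None
    peaks, _ = find_peaks(deriv, height=height,
                          distance=max(int(cfg.refractory_s * rec.fs), 1))
    look = int(0.3 * rec.fs)
    feet = []
    for p in peaks:
        lo = max(p - look, 0)
        f = lo + int(np.argmin(smooth[lo: p + 1]))
        r0, r1 = max(f - 3, 0), min(f + 4, x.size)
        f = r0 + int(np.argmin(x[r0:r1]))  # refine on the raw samples
        if not feet or f > feet[-1]:
            feet.append(f)
    beats: list[Beat] = []
    for i0, i1 in zip(feet[:-1], feet[1:]):
        dur = (i1 - i0) / rec.fs
        seg = x[i0:i1]
        if not cfg.min_duration_s <= dur <= cfg.max_duration_s:
            continue
        sap = float(seg.max())
        foot_region = seg[: max(int(0.1 * seg.size), 1)]
        dap = float(foot_region.min())
        if sap - float(seg.min()) < cfg.min_pulse_pressure_mmHg:
            continue
        beats.append(
            Beat(
                subject_id=rec.subject_id,
                onset_s=rec.t0 + i0 / rec.fs,
                duration_s=dur,
                raw=seg,
                sap_mmHg=sap,
                dap_mmHg=dap,
                map_mmHg=float(seg.mean()),
                hr_bpm=60.0 / dur,
            )
        )
    return beats


def remove_calibration_beats(
    beats: list[Beat], intervals: list[tuple[float, float]]
) -> list[Beat]:
    """Drop every beat whose half-open span overlaps an artifact interval."""
    if not intervals:
        return list(beats)

    def clean(beat: Beat) -> bool:
        s, e = beat.onset_s, beat.onset_s + beat.duration_s
        return not any(s < b and e > a for a, b in intervals)

    return [bt for bt in beats if clean(bt)]


def resample_beat(beat: Beat, n_samples: int = N_SAMPLES) -> NormalizedBeat:
    """Resample one beat to exactly ``n_samples`` points, endpoints included.

    Uses shape-preserving monotone cubic Hermite interpolation, so the output
    never leaves the raw sample range and reproduces linear data exactly.
    Amplitudes stay in mmHg.
    """
    raw = np.asarray(beat.raw, dtype=float)
    if raw.size < 4:
        raise ValueError("beat must contain at least 4 raw samples")
    interp = PchipInterpolator(np.arange(raw.size), raw)
    values = interp(np.linspace(0.0, raw.size - 1.0, n_samples))
    return NormalizedBeat(
        subject_id=beat.subject_id, onset_s=beat.onset_s, values=values
    )


def build_beat_matrix(
    recordings: list[PressureRecording],
    beat_cfg: BeatConfig | None = None,
    scheme: ClassScheme | None = None,
) -> BeatMatrix:
    """Full per-subject extraction: detect, de-artifact, resample, label.

    Subjects yielding zero usable beats are excluded with a warning (the
    analysis requires at least some clean LBNP data per subject).
    """
    beat_cfg = beat_cfg or BeatConfig()
    if not recordings:
        raise ValueError("need at least one recording")
    rows, labels, sids, onsets = [], [], [], []
    end_reasons: dict[str, str] = {}
    for rec in recordings:
        beats = remove_calibration_beats(
            detect_beats(rec, beat_cfg), rec.artifact_intervals
        )
        if not beats:
            warnings.warn(f"{rec.subject_id}: no usable beats, subject excluded")
            continue
        t = np.array([b.onset_s for b in beats])
        lab, keep = assign_classes(t, rec.marks, scheme)
        beats = [b for b, k in zip(beats, keep) if k]
        if not beats:
            warnings.warn(f"{rec.subject_id}: no in-protocol beats, excluded")
            continue
        for b in beats:
            rows.append(resample_beat(b, beat_cfg.n_samples).values)
        labels.extend(lab.tolist())
        sids.extend([rec.subject_id] * len(beats))
        onsets.extend(b.onset_s for b in beats)
        end_reasons[rec.subject_id] = rec.marks.end_reason
    if not rows:
        raise ValueError("no recording yielded any usable beats")
    return BeatMatrix(
        values=np.vstack(rows),
        labels=np.asarray(labels, dtype=int),
        subject_ids=np.asarray(sids, dtype=object),
        onsets_s=np.asarray(onsets, dtype=float),
        end_reasons=end_reasons,
    )
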