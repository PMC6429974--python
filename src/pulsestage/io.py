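"""Reading and writing continuous arterial-pressure recordings.

A recording is a uniformly sampled finger-arterial-pressure signal (mmHg)
together with the protocol event marks that anchor the ordinal class labels
(baseline start, LBNP onset, protocol end) and any intervals contaminated by
the finger-cuff's periodic self-calibration ("Physiocal"), during which the
waveform is not physiological.

On-disk dialect: the signal is a two-column CSV ``time_s,pressure_mmHg``
(header required, '.' decimal point); marks and artifact intervals live in a
separate YAML document so the same signal can be re-labeled. All times are
seconds; all intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "ProtocolMarks",
    "PressureRecording",
    "FormatError",
    "DataError",
    "read_recording",
    "write_recording",
]

#: Maximum relative deviation from uniform sample spacing tolerated on read.
UNIFORMITY_RTOL = 1e-6

#: LBNP tolerance limit (s): a subject who withstands this long without
#: presyncope ends the protocol with ``end_reason='tolerated'``.
TOLERANCE_DURATION_S = 1800.0


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class DataError(ValueError):
    """A file parses but its contents violate a recording invariant."""


@dataclass(frozen=True)
class ProtocolMarks:
    """Event marks of one LBNP protocol run.

    Parameters
    ----------
    baseline_start_s, lbnp_onset_s, protocol_end_s
        Protocol phase boundaries in seconds. The supine-rest baseline spans
        ``[baseline_start_s, lbnp_onset_s)``; the LBNP segment spans
        ``[lbnp_onset_s, protocol_end_s]``.
    end_reason
        ``'presyncope'`` if the run was terminated by the presyncope safety
        criteria, ``'tolerated'`` if the subject withstood the full LBNP
        duration.
    tolerance_duration_s
        Configured tolerance limit used to validate tolerated runs.
    """

    baseline_start_s: float
    lbnp_onset_s: float
    protocol_end_s: float
    end_reason: str
    tolerance_duration_s: float = TOLERANCE_DURATION_S

    def __post_init__(self) -> None:
        if self.end_reason not in ("presyncope", "tolerated"):
            raise DataError(f"unknown end_reason {self.end_reason!r}")
        if not self.lbnp_onset_s > self.baseline_start_s:
            raise DataError("lbnp_onset_s must exceed baseline_start_s")
        if not self.protocol_end_s > self.lbnp_onset_s:
            raise DataError("protocol_end_s must exceed lbnp_onset_s")
        if self.end_reason == "tolerated":
            lbnp = self.protocol_end_s - self.lbnp_onset_s
            if lbnp < self.tolerance_duration_s - 1e-9:
                raise DataError(
                    f"tolerated run but LBNP lasted only {lbnp:.1f} s "
                    f"(< {self.tolerance_duration_s:.0f} s limit)"
                )

    @property
    def lbnp_duration_s(self) -> float:
        return self.protocol_end_s - self.lbnp_onset_s


@dataclass
class PressureRecording:
    """One subject's continuous pressure signal plus protocol bookkeeping."""

    subject_id: str
    fs: float
    pressure: np.ndarray
    marks: ProtocolMarks
    t0: float = 0.0
    artifact_intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pressure = np.asarray(self.pressure, dtype=float)
        if not self.fs > 0:
            raise DataError("fs must be positive")
        if self.pressure.ndim != 1 or self.pressure.size < 1:
            raise DataError("pressure must be a non-empty 1-D sequence")
        end = self.t0 + self.pressure.size / self.fs
        for a, b in self.artifact_intervals:
            if not (self.t0 - 1e-9 <= a < b <= end + 1e-9):
                raise DataError(
                    f"artifact interval [{a}, {b}) outside recording "
                    f"[{self.t0}, {end})"
                )

    @property
    def duration_s(self) -> float:
        return self.pressure.size / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.pressure.size) / self.fs


def _infer_fs(time_s: np.ndarray) -> float:
    dt = np.diff(time_s)
    if np.any(dt <= 0):
        raise DataError("time column must be strictly increasing")
    mean_dt = dt.mean()
    if np.max(np.abs(dt - mean_dt)) > UNIFORMITY_RTOL * mean_dt:
        raise DataError(
            "non-uniform sampling beyond 1 ppm; resample before loading"
        )
    return 1.0 / mean_dt


def read_recording(signal_path: str | Path, marks_path: str | Path) -> PressureRecording:
    """Load a recording from a signal CSV and a marks YAML document.

    The sampling rate is inferred from the time column; if the marks document
    also declares ``fs`` the two must agree to within 1 ppm.
    """
    signal_path, marks_path = Path(signal_path), Path(marks_path)
    try:
        arr = np.genfromtxt(signal_path, delimiter=",", names=True)
    except Exception as exc:  # pragma: no cover - numpy message passthrough
        raise FormatError(f"cannot parse {signal_path}: {exc}") from exc
    names = arr.dtype.names
    if names is None or "time_s" not in names or "pressure_mmHg" not in names:
        raise FormatError(
            f"{signal_path}: expected header columns time_s,pressure_mmHg"
        )
    time_s = np.atleast_1d(arr["time_s"]).astype(float)
    pressure = np.atleast_1d(arr["pressure_mmHg"]).astype(float)
    if time_s.size >= 2:
        fs = _infer_fs(time_s)
    else:
        fs = None

    with open(marks_path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise FormatError(f"{marks_path}: expected a mapping document")
    required = ("baseline_start_s", "lbnp_onset_s", "protocol_end_s", "end_reason")
    missing = [k for k in required if k not in doc]
    if missing:
        raise FormatError(f"{marks_path}: missing marks fields {missing}")
    marks = ProtocolMarks(
        baseline_start_s=float(doc["baseline_start_s"]),
        lbnp_onset_s=float(doc["lbnp_onset_s"]),
        protocol_end_s=float(doc["protocol_end_s"]),
        end_reason=str(doc["end_reason"]),
        tolerance_duration_s=float(
            doc.get("tolerance_duration_s", TOLERANCE_DURATION_S)
        ),
    )
    declared_fs = doc.get("fs")
    if declared_fs is not None:
        declared_fs = float(declared_fs)
        if fs is not None and abs(fs - declared_fs) > UNIFORMITY_RTOL * declared_fs:
            raise DataError(
                f"declared fs {declared_fs} Hz disagrees with inferred {fs} Hz"
            )
        fs = declared_fs
    if fs is None:
        raise FormatError("cannot determine fs: <2 samples and no declared fs")
    intervals = [
        (float(a), float(b)) for a, b in doc.get("artifact_intervals", []) or []
    ]
    return PressureRecording(
        subject_id=str(doc.get("subject_id", signal_path.stem)),
        fs=fs,
        pressure=pressure,
        marks=marks,
        t0=float(time_s[0]),
        artifact_intervals=intervals,
    )


def write_recording(
    rec: PressureRecording, signal_path: str | Path, marks_path: str | Path
) -> None:
    """Write a recording in the dialect :func:`read_recording` expects.

    Round-trip preserves every field; pressures survive to better than
    1e-9 mmHg (12 significant digits).
    """
    signal_path, marks_path = Path(signal_path), Path(marks_path)
    t = rec.times()
    with open(signal_path, "w") as fh:
        fh.write("time_s,pressure_mmHg\n")
        for ti, pi in zip(t, rec.pressure):
            fh.write(f"{ti:.12g},{pi:.12g}\n")
    doc: dict = {
        "subject_id": rec.subject_id,
        "fs": float(rec.fs),
        "baseline_start_s": float(rec.marks.baseline_start_s),
        "lbnp_onset_s": float(rec.marks.lbnp_onset_s),
        "protocol_end_s": float(rec.marks.protocol_end_s),
        "end_reason": rec.marks.end_reason,
        "tolerance_duration_s": float(rec.marks.tolerance_duration_s),
    }
    if rec.artifact_intervals:
        doc["artifact_intervals"] = [
            [float(a), float(b)] for a, b in rec.artifact_intervals
        ]
    with open(marks_path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
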