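"""Synthetic hemodynamic cohort generator.

Emulates the statistical structure of a single-step LBNP (lower body negative
pressure) protocol recorded with a finger-cuff pressure monitor: a supine
baseline at constant morphology, then an LBNP phase in which a latent
hypovolemia severity s(t) in [0,1] rises as a power law of elapsed time and
drives the beat morphology — pulse pressure falls, the dicrotic notch
attenuates, heart rate rises. Presyncope subjects end with an abrupt
vasodepressor collapse (SAP and DAP falling linearly) that fires the
protocol's termination criteria; tolerant subjects plateau at a sub-critical
severity and complete the full LBNP duration. Periodic finger-cuff
self-calibration artifacts are rendered as flat-line segments and listed in
the recording's artifact intervals.

Each beat is a three-component template: a raised-cosine-squared systolic
upstroke, an exponential diastolic run-off pinned to zero at both beat ends
(so consecutive beats join continuously at the diastolic foot), and a
Gaussian dicrotic secondary wave whose amplitude shrinks with severity. The
generator is deliberately phenomenological: it produces the morphology drift
the staging pipeline assumes, not baroreflex mechanics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import PressureRecording, ProtocolMarks
from .labeling import PresyncopeCriteria, assign_classes, detect_presyncope

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "beat_template",
    "generate_subject",
    "generate_cohort",
]

# Beat-template shape constants. Systolic peak and dicrotic notch are placed
# at fixed times proportional to the square root of the cycle length (the
# classical ejection-time relation), so faster beats carry relatively longer
# systole in normalized time; constants below are seconds at a 0.92-s cycle.
_T_SYS = 0.15       # time to systolic peak (s at 65 bpm)
_T_NOTCH = 0.35     # dicrotic notch time (s at 65 bpm)
_REF_PERIOD = 0.92  # reference cycle length (s)
_TAU_RUNOFF = 0.22  # diastolic decay constant, fraction of the beat
_SIGMA_NOTCH = 0.05
_A_NOTCH = 0.20     # dicrotic amplitude relative to pulse pressure, severity 0


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults describe a screened, homogeneous cohort of 15 young healthy
    adults, 12 of whom reach presyncope under single-step LBNP and 3 of whom
    tolerate the full 30-min phase; 5 min of supine baseline precedes LBNP
    onset. Between-subject SDs are deliberately those of a screened cohort
    (a few mmHg / bpm), so that severity-driven morphology drift dominates
    between-subject morphology differences — the low-noise regime the
    staging protocol presumes. Severity-1 effect sizes (pulse pressure
    nearly halved, dicrotic notch almost completely lost, HR up 30 bpm)
    reflect the textbook response to progressive central hypovolemia near
    collapse.
    """

    n_subjects: int = 15
    presyncope_fraction: float = 0.8
    fs: float = 200.0
    baseline_duration_s: float = 300.0
    max_lbnp_duration_s: float = 1800.0
    hr_baseline_bpm: tuple[float, float] = (65.0, 5.0)
    sap_baseline_mmHg: tuple[float, float] = (120.0, 4.0)
    dap_baseline_mmHg: tuple[float, float] = (70.0, 3.0)
    severity_shape: float = 2.0        # power-law exponent of the ramp
    ramp_duration_s: tuple[float, float] = (900.0, 180.0)
    pulse_pressure_drop_frac: float = 0.45
    notch_attenuation_frac: float = 0.9
    hr_rise_bpm: float = 30.0
    onset_response_frac: float = 0.2   # immediate severity step at LBNP onset
    onset_response_time_s: float = 20.0
    tolerated_plateau: float = 0.5     # severity plateau of tolerant subjects
    collapse_rate_mmHg_per_min: float = 30.0
    hr_jitter_frac: float = 0.02       # SD of beat-to-beat period jitter
    noise_sd_mmHg: float = 2.0
    physiocal_period_s: float = 70.0
    physiocal_duration_s: float = 2.0
    list_artifacts: bool = True        # record Physiocal intervals in metadata
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("presyncope_fraction", "pulse_pressure_drop_frac",
                     "notch_attenuation_frac", "tolerated_plateau",
                     "onset_response_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0,1]")
        for name in ("fs", "baseline_duration_s", "max_lbnp_duration_s",
                     "severity_shape", "collapse_rate_mmHg_per_min",
                     "physiocal_period_s", "physiocal_duration_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.hr_baseline_bpm[0] + self.hr_rise_bpm >= 220.0:
            raise ValueError("mean HR plus HR rise must stay below 220 bpm")
        if self.noise_sd_mmHg < 0:
            raise ValueError("noise_sd_mmHg must be nonnegative")


@dataclass
class GroundTruth:
    """Latent state of one generated subject, for oracle-style tests."""

    subject_id: str
    end_reason: str
    presyncope_time_s: float | None
    beat_onsets_s: np.ndarray      # true foot time of every rendered beat
    beat_severity: np.ndarray      # latent severity at each beat onset
    beat_sap_mmHg: np.ndarray      # programmed (noise-free) per-beat values
    beat_dap_mmHg: np.ndarray
    beat_hr_bpm: np.ndarray
    beat_labels: np.ndarray        # ordinal class of each beat per the marks
    ramp_duration_s: float = field(default=float("nan"))


def beat_template(
    sap: float,
    dap: float,
    period_s: float,
    severity: float,
    cfg: SyntheticConfig,
) -> np.ndarray:
    """Render one beat of ``round(period_s * cfg.fs)`` samples.

    The waveform starts and ends at the diastolic level ``dap`` (the foot),
    peaks at ``sap``, and carries a dicrotic secondary wave whose relative
    amplitude is scaled by ``1 - severity * cfg.notch_attenuation_frac``.
    Deterministic: no randomness enters the template itself.
    """
    if not sap > dap:
        raise ValueError(f"sap ({sap}) must exceed dap ({dap})")
    n = int(round(period_s * cfg.fs))
    if n < 4:
        raise ValueError("beat period too short for the sampling rate")
    scale = np.sqrt(period_s / _REF_PERIOD)
    u_sys = float(np.clip(_T_SYS * scale / period_s, 0.08, 0.25))
    u_notch = float(np.clip(_T_NOTCH * scale / period_s, 0.25, 0.55))
    u = np.arange(n) / n
    e1 = np.empty(n)
    rising = u < u_sys
    e1[rising] = np.sin(np.pi * u[rising] / (2.0 * u_sys)) ** 2
    tail = np.exp(-(1.0 - u_sys) / _TAU_RUNOFF)
    e1[~rising] = (np.exp(-(u[~rising] - u_sys) / _TAU_RUNOFF) - tail) / (1.0 - tail)
    a_d = _A_NOTCH * (1.0 - severity * cfg.notch_attenuation_frac)
    e2 = np.exp(-0.5 * ((u - u_notch) / _SIGMA_NOTCH) ** 2)
    w = e1 + a_d * e2
    return dap + (sap - dap) * w


def _severity(t: np.ndarray | float, onset: float, ramp: float,
              gamma: float, plateau: float, step_frac: float,
              step_time: float) -> np.ndarray | float:
    """Latent severity during the protocol.

    Zero during baseline; at LBNP onset an immediate component rises to
    ``step_frac`` over ``step_time`` seconds (the chamber pressure is
    established within tens of seconds and translocates blood at once), and
    the remaining ``1 - step_frac`` ramps as a power law of elapsed time with
    exponent ``gamma``. ``plateau`` caps the total (1 for presyncope
    subjects, sub-critical for tolerant ones)."""
    dt = np.asarray(t, dtype=float) - onset
    step = step_frac * np.clip(dt / step_time, 0.0, 1.0)
    rel = np.clip(dt / ramp, 0.0, 1.0)
    return np.minimum(plateau, step + (1.0 - step_frac) * rel**gamma)


def generate_subject(
    cfg: SyntheticConfig,
    subject_index: int,
    rng: np.random.Generator,
    presyncope: bool = True,
    criteria: PresyncopeCriteria | None = None,
) -> tuple[PressureRecording, GroundTruth]:
    """Generate one subject's recording plus its latent ground truth.

    For presyncope subjects the recording is truncated at the first beat on
    which :func:`pulsestage.labeling.detect_presyncope` fires on the
    programmed (noise-free) per-beat SAP/DAP/HR series, so the generator and
    the detector agree by construction. Tolerant subjects plateau at
    ``cfg.tolerated_plateau`` severity and run the full LBNP duration.
    """
    criteria = criteria or PresyncopeCriteria()
    subject_id = f"S{subject_index:02d}"
    onset = cfg.baseline_duration_s
    hr0 = rng.normal(*cfg.hr_baseline_bpm)
    sap0 = rng.normal(*cfg.sap_baseline_mmHg)
    dap0 = rng.normal(*cfg.dap_baseline_mmHg)
    dap0 = min(dap0, sap0 - 20.0)  # keep a physiologic pulse pressure
    pp0 = sap0 - dap0
    ramp_lo = min(120.0, 0.5 * cfg.max_lbnp_duration_s)
    ramp_hi = max(ramp_lo + 1.0, cfg.max_lbnp_duration_s - 120.0)
    ramp = float(np.clip(rng.normal(*cfg.ramp_duration_s), ramp_lo, ramp_hi))
    plateau = 1.0 if presyncope else cfg.tolerated_plateau
    collapse_per_s = cfg.collapse_rate_mmHg_per_min / 60.0

    if presyncope:
        # generous horizon: collapse must fire well before SAP reaches zero
        sap_at_ramp_end = dap0 + pp0 * (1.0 - cfg.pulse_pressure_drop_frac)
        extra = (sap_at_ramp_end - criteria.sap_floor_mmHg) / collapse_per_s
        horizon = onset + ramp + max(extra, 0.0) + criteria.window_s + 30.0
    else:
        horizon = onset + cfg.max_lbnp_duration_s

    chunks: list[np.ndarray] = []
    onsets, sevs, saps, daps, hrs = [], [], [], [], []
    n_samples = 0
    while n_samples / cfg.fs < horizon:
        t = n_samples / cfg.fs
        sev = float(_severity(t, onset, ramp, cfg.severity_shape, plateau,
                              cfg.onset_response_frac, cfg.onset_response_time_s))
        drop = collapse_per_s * max(0.0, t - (onset + ramp)) if presyncope else 0.0
        hr = hr0 + cfg.hr_rise_bpm * sev
        period = (60.0 / hr) * (1.0 + cfg.hr_jitter_frac * rng.standard_normal())
        period = float(np.clip(period, 0.3, 2.0))
        sap_t = dap0 + pp0 * (1.0 - cfg.pulse_pressure_drop_frac * sev) - drop
        dap_t = dap0 - drop
        beat = beat_template(sap_t, dap_t, period, sev, cfg)
        chunks.append(beat)
        onsets.append(t)
        sevs.append(sev)
        saps.append(sap_t)
        daps.append(dap_t)
        hrs.append(60.0 / period)
        n_samples += beat.size

    onsets = np.asarray(onsets)
    saps, daps, hrs = np.asarray(saps), np.asarray(daps), np.asarray(hrs)
    sevs = np.asarray(sevs)

    if presyncope:
        trigger = detect_presyncope(onsets, saps, daps, hrs, criteria)
        if trigger is None:
            raise RuntimeError(
                f"{subject_id}: presyncope criteria never fired within the "
                "generation horizon; check collapse settings"
            )
        last = int(np.searchsorted(onsets, trigger, side="left"))
        end_reason, protocol_end = "presyncope", float(onsets[last])
        keep = last + 1
    else:
        protocol_end = onset + cfg.max_lbnp_duration_s
        end_reason = "tolerated"
        keep = int(np.searchsorted(onsets, protocol_end, side="left"))
    chunks = chunks[:keep]
    onsets, sevs = onsets[:keep], sevs[:keep]
    saps, daps, hrs = saps[:keep], daps[:keep], hrs[:keep]

    signal = np.concatenate(chunks)
    if not presyncope:
        # the protocol ends exactly at the tolerance limit, mid-beat if need be
        signal = signal[: int(round(protocol_end * cfg.fs))]
    if cfg.noise_sd_mmHg > 0:
        signal = signal + rng.normal(0.0, cfg.noise_sd_mmHg, signal.size)

    # Physiocal-like self-calibration artifacts: flat at the diastolic level.
    duration = signal.size / cfg.fs
    intervals: list[tuple[float, float]] = []
    k = 1
    while k * cfg.physiocal_period_s + cfg.physiocal_duration_s < duration:
        a = k * cfg.physiocal_period_s
        b = a + cfg.physiocal_duration_s
        i_beat = int(np.searchsorted(onsets, a, side="right")) - 1
        level = daps[max(i_beat, 0)]
        signal[int(a * cfg.fs): int(b * cfg.fs)] = level
        intervals.append((a, b))
        k += 1

    marks = ProtocolMarks(
        baseline_start_s=0.0,
        lbnp_onset_s=onset,
        protocol_end_s=protocol_end,
        end_reason=end_reason,
        tolerance_duration_s=cfg.max_lbnp_duration_s,
    )
    rec = PressureRecording(
        subject_id=subject_id,
        fs=cfg.fs,
        pressure=signal,
        marks=marks,
        artifact_intervals=intervals if cfg.list_artifacts else [],
    )
    labels, keep_mask = assign_classes(onsets, marks)
    full_labels = np.full(onsets.size, -1, dtype=int)
    full_labels[keep_mask] = labels
    gt = GroundTruth(
        subject_id=subject_id,
        end_reason=end_reason,
        presyncope_time_s=protocol_end if presyncope else None,
        beat_onsets_s=onsets,
        beat_severity=sevs,
        beat_sap_mmHg=saps,
        beat_dap_mmHg=daps,
        beat_hr_bpm=hrs,
        beat_labels=full_labels,
        ramp_duration_s=ramp,
    )
    return rec, gt


def generate_cohort(
    cfg: SyntheticConfig,
    criteria: PresyncopeCriteria | None = None,
) -> list[tuple[PressureRecording, GroundTruth]]:
    """Generate the full cohort with independent per-subject RNG streams.

    Exactly ``round(n_subjects * presyncope_fraction)`` subjects end in
    presyncope (the first ones by index); the rest tolerate the full LBNP
    phase. Streams are spawned from ``cfg.seed`` so the cohort is bit
    reproducible and subjects are statistically independent.
    """
    n_pre = int(round(cfg.n_subjects * cfg.presyncope_fraction))
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_subjects)
    cohort = []
    for i, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        cohort.append(
            generate_subject(cfg, i + 1, rng, presyncope=i < n_pre,
                             criteria=criteria)
        )
    return cohort
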