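"""Ordinal class assignment and the presyncope safety-criteria detector.

Four classes describe the progression of central hypovolemia: class 0 is
supine baseline rest (normovolemia); classes 1-3 are the first, second and
third tertile of the LBNP segment in elapsed time, so later beats carry a
higher (more severe) class. The presyncope detector implements the standard
laboratory termination criteria on beat-wise SAP/DAP/HR series: an absolute
systolic floor, plus rapid-decline criteria evaluated over a trailing
one-minute window. The criteria are combined disjunctively (ANY criterion
terminates the run), the conventional reading of safety-abort rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ProtocolMarks

__all__ = ["ClassScheme", "PresyncopeCriteria", "assign_classes", "detect_presyncope"]

#: Class label given to every beat during supine baseline.
BASELINE_CLASS = 0


@dataclass(frozen=True)
class ClassScheme:
    """Tertile split of the LBNP segment into ordinal classes 1-3.

    Boundaries are fractions of elapsed LBNP time; tertiles are right-closed,
    ``(0, 1/3] -> 1, (1/3, 2/3] -> 2, (2/3, 1] -> 3``, with the beat at
    fraction 0 assigned class 1 so every LBNP beat has an LBNP class.
    """

    boundaries: tuple[float, ...] = (1.0 / 3.0, 2.0 / 3.0)

    def __post_init__(self) -> None:
        b = self.boundaries
        if not all(0.0 < x < 1.0 for x in b) or list(b) != sorted(set(b)):
            raise ValueError("boundaries must be strictly increasing in (0,1)")

    @property
    def n_classes(self) -> int:
        return len(self.boundaries) + 2  # baseline + tertiles


@dataclass(frozen=True)
class PresyncopeCriteria:
    """Thresholds of the protocol termination criteria.

    ``sap_floor_mmHg`` is absolute; the three rate criteria are total declines
    over the trailing ``window_s`` (max value in window minus current value),
    a robust reading of "per minute" rates at beat-level noise.
    """

    sap_floor_mmHg: float = 80.0
    sap_drop_mmHg_per_min: float = 25.0
    dap_drop_mmHg_per_min: float = 15.0
    hr_drop_bpm_per_min: float = 15.0
    window_s: float = 60.0

    def __post_init__(self) -> None:
        for name in (
            "sap_floor_mmHg",
            "sap_drop_mmHg_per_min",
            "dap_drop_mmHg_per_min",
            "hr_drop_bpm_per_min",
            "window_s",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


def assign_classes(
    onsets_s: np.ndarray,
    marks: ProtocolMarks,
    scheme: ClassScheme | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Label beat onsets with ordinal classes from the protocol marks.

    Parameters
    ----------
    onsets_s
        Beat onset (foot) times in seconds, nondecreasing.
    marks
        Protocol marks; the LBNP segment is ``[lbnp_onset_s, protocol_end_s]``.
    scheme
        Tertile scheme; default thirds.

    Returns
    -------
    labels : int array
        Class per kept beat (0 baseline, 1-3 LBNP tertiles).
    keep : bool array
        Mask over the input marking beats inside the protocol (onset in
        ``[baseline_start_s, protocol_end_s]``); beats outside are dropped.
    """
    scheme = scheme or ClassScheme()
    onsets_s = np.asarray(onsets_s, dtype=float)
    if not marks.protocol_end_s > marks.lbnp_onset_s:
        raise ValueError("protocol_end_s must exceed lbnp_onset_s")
    keep = (onsets_s >= marks.baseline_start_s) & (onsets_s <= marks.protocol_end_s)
    t = onsets_s[keep]
    labels = np.full(t.size, BASELINE_CLASS, dtype=int)
    lbnp = t >= marks.lbnp_onset_s
    f = (t[lbnp] - marks.lbnp_onset_s) / marks.lbnp_duration_s
    edges = np.asarray(scheme.boundaries)
    # right-closed tertiles; f = 0 still gets class 1
    labels[lbnp] = 1 + np.searchsorted(edges, f, side="left") - (f == 0.0)
    labels[lbnp] = np.clip(labels[lbnp], 1, scheme.n_classes - 1)
    return labels, keep


def detect_presyncope(
    times_s: np.ndarray,
    sap_mmHg: np.ndarray,
    dap_mmHg: np.ndarray,
    hr_bpm: np.ndarray,
    criteria: PresyncopeCriteria | None = None,
) -> float | None:
    """Earliest beat time at which any presyncope criterion holds, else None.

    Criteria (disjunctive): (a) SAP below the floor; (b) SAP decline over the
    trailing window >= 25 mmHg; (c) DAP decline >= 15 mmHg; (d) HR decline
    >= 15 bpm. While the elapsed record is shorter than the window only the
    absolute floor (a) is evaluated. Rate criteria compare the current value
    with the maximum over the trailing window, so they are invariant under
    time translation and under adding a constant to the series; the SAP floor
    is not offset-invariant by design.
    """
    criteria = criteria or PresyncopeCriteria()
    t = np.asarray(times_s, dtype=float)
    sap = np.asarray(sap_mmHg, dtype=float)
    dap = np.asarray(dap_mmHg, dtype=float)
    hr = np.asarray(hr_bpm, dtype=float)
    if t.size == 0:
        raise ValueError("empty series")
    if not (t.size == sap.size == dap.size == hr.size):
        raise ValueError("series must be aligned")
    w = criteria.window_s
    for i in range(t.size):
        if sap[i] < criteria.sap_floor_mmHg:
            return float(t[i])
        if t[i] - t[0] < w:
            continue
        j = np.searchsorted(t, t[i] - w, side="left")
        win = slice(j, i + 1)
        if sap[win].max() - sap[i] >= criteria.sap_drop_mmHg_per_min * (w / 60.0):
            return float(t[i])
        if dap[win].max() - dap[i] >= criteria.dap_drop_mmHg_per_min * (w / 60.0):
            return float(t[i])
        if hr[win].max() - hr[i] >= criteria.hr_drop_bpm_per_min * (w / 60.0):
            return float(t[i])
    return None
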