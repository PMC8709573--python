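"""Per-trace quantification: dF/F0 normalization, amplitude, class, and QC.

Each recording is 60 frames at 2 s/frame: a 60 s pre-wash, a 30 s stimulus
(frames 30-44) and a 30 s wash.  F0 is the mean raw fluorescence over the 10
frames immediately preceding stimulus onset; traces are expressed as
(Ft - F0)/F0.  The response amplitude is the mean of a 5-frame window placed
on the post-onset maximum, and a response counts only above a 20% dF/F0
threshold.  Response classes:

``on``
    first threshold crossing inside the stimulus window;
``off_late``
    first crossing at or after stimulus offset (late activation and OFF
    responses are one class -- no principled boundary separates them);
``deactivation``
    no positive crossing but a dip below -threshold during the stimulus;
``none``
    everything else.

Quality control excludes traces whose baseline peak-to-peak range reaches the
response amplitude, or whose baseline drifts linearly by at least half the
response threshold over the baseline window.  Baseline "variance" is
operationalized as peak-to-peak range so that it is commensurable with the
amplitude (both in dF/F units).  Artifact-style exclusions that require a
human eye are covered by a manual-override flag instead of a rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "StimulusSchedule",
    "DffTrace",
    "ResponseRecord",
    "QCResult",
    "compute_dff",
    "compute_amplitude",
    "classify_response",
    "qc_validate",
    "response_amplitude",
    "analyze_trace",
    "records_to_frame",
    "frame_to_records",
]

RESPONSE_CLASSES = ("none", "on", "off_late", "deactivation")
DEFAULT_THRESHOLD = 0.20


@dataclass(frozen=True)
class StimulusSchedule:
    """Frame layout of one taste stimulation recording."""

    onset_frame: int = 30
    offset_frame: int = 45  # exclusive
    n_frames: int = 60
    baseline_len: int = 10
    peak_window: int = 5
    frame_interval: float = 2.0  # seconds

    def __post_init__(self):
        if not (0 < self.onset_frame < self.offset_frame <= self.n_frames):
            raise ConfigurationError(
                f"need 0 < onset ({self.onset_frame}) < offset ({self.offset_frame})"
                f" <= n_frames ({self.n_frames})")
        if self.baseline_len < 1 or self.baseline_len > self.onset_frame:
            raise ConfigurationError("baseline_len must be in [1, onset_frame]")
        if self.peak_window < 1 or self.peak_window % 2 == 0:
            raise ConfigurationError("peak_window must be odd and >= 1")
        if self.frame_interval <= 0:
            raise ConfigurationError("frame_interval must be positive")

    @property
    def baseline_slice(self) -> slice:
        return slice(self.onset_frame - self.baseline_len, self.onset_frame)

    @property
    def stimulus_slice(self) -> slice:
        return slice(self.onset_frame, self.offset_frame)


@dataclass(frozen=True)
class DffTrace:
    """A normalized (Ft - F0)/F0 trace for one (cell, tastant)."""

    values: np.ndarray
    f0: float
    cell_id: str = ""
    tastant: str = ""

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


def compute_dff(raw: Sequence[float], schedule: StimulusSchedule,
                cell_id: str = "", tastant: str = "") -> DffTrace:
    """Normalize a raw fluorescence trace to dF/F0.

    F0 is the mean over the ``baseline_len`` frames before stimulus onset.
    Raises :class:`ValueError` when F0 <= 0 (the trace is unusable).
    """
    values = np.asarray(getattr(raw, "values", raw), dtype=float)
    cell_id = cell_id or getattr(raw, "cell_id", "") or ""
    tastant = tastant or getattr(raw, "tastant", "") or ""
    if values.shape != (schedule.n_frames,):
        raise ValueError(
            f"trace length {values.shape} does not match schedule n_frames="
            f"{schedule.n_frames}")
    f0 = float(values[schedule.baseline_slice].mean())
    if f0 <= 0:
        raise ValueError(f"non-positive baseline F0={f0} for cell {cell_id!r}")
    return DffTrace(values=(values - f0) / f0, f0=f0, cell_id=cell_id, tastant=tastant)


def compute_amplitude(dff: DffTrace, schedule: StimulusSchedule) -> float:
    """Peak response amplitude in dF/F units.

    The post-onset maximum is located over frames [onset, n_frames) (earliest
    frame wins ties); the amplitude is the mean of a ``peak_window``-frame
    window centered on it -- "5 frames near the maximal value".  The window
    is shifted where needed to stay inside the response epoch holding the
    peak: [onset, n_frames) for stimulus-window peaks, [offset, n_frames)
    for later peaks.  A step response at onset or an OFF/late response at
    offset is thus read off its own plateau instead of being diluted with
    pre-response baseline frames.
    """
    v = dff.values
    lo, hi = schedule.onset_frame, schedule.n_frames
    peak = lo + int(np.argmax(v[lo:hi]))  # argmax returns the earliest maximum
    dom_lo = schedule.offset_frame if peak >= schedule.offset_frame else lo
    w = min(schedule.peak_window, hi - dom_lo)
    start = min(max(peak - w // 2, dom_lo), hi - w)
    return float(v[start:start + w].mean())


def classify_response(dff: DffTrace, schedule: StimulusSchedule,
                      threshold: float = DEFAULT_THRESHOLD) -> str:
    """Assign one of ``on``, ``off_late``, ``deactivation``, ``none``.

    Positive classes take precedence over deactivation.
    """
    v = dff.values
    amplitude = compute_amplitude(dff, schedule)
    post = np.nonzero(v[schedule.onset_frame:] >= threshold)[0]
    if post.size and amplitude >= threshold:
        first = schedule.onset_frame + int(post[0])
        return "on" if first < schedule.offset_frame else "off_late"
    if not post.size and v[schedule.stimulus_slice].min() <= -threshold:
        return "deactivation"
    return "none"


@dataclass(frozen=True)
class QCResult:
    passed: bool
    reason: str | None = None  # unstable_baseline | baseline_exceeds_amplitude | manual

    def __str__(self) -> str:
        return "pass" if self.passed else f"fail:{self.reason}"


def qc_validate(dff: DffTrace, schedule: StimulusSchedule, amplitude: float,
                threshold: float = DEFAULT_THRESHOLD,
                manual_exclude: bool = False) -> QCResult:
    """Baseline-stability quality control for one trace.

    Fails with ``baseline_exceeds_amplitude`` when the baseline peak-to-peak
    range reaches |amplitude|, and with ``unstable_baseline`` when the fitted
    linear baseline trend accumulates at least half the response threshold
    over the baseline window.  ``manual_exclude`` mirrors by-eye exclusions
    (artifacts, delocalized fluorescence) that no rule captures.
    """
    if manual_exclude:
        return QCResult(False, "manual")
    base = dff.values[schedule.baseline_slice]
    if float(np.ptp(base)) >= abs(amplitude):
        return QCResult(False, "baseline_exceeds_amplitude")
    slope = float(np.polyfit(np.arange(base.size), base, 1)[0])
    if abs(slope) * schedule.baseline_len >= 0.5 * threshold:
        return QCResult(False, "unstable_baseline")
    return QCResult(True)


def response_amplitude(dff: DffTrace, schedule: StimulusSchedule,
                       response_class: str) -> float:
    """Signed amplitude of a classified trace.

    Activation classes report the (positive) peak-window amplitude;
    deactivation reports the (negative) stimulus-window minimum.
    """
    if response_class == "deactivation":
        return float(dff.values[schedule.stimulus_slice].min())
    return compute_amplitude(dff, schedule)


@dataclass(frozen=True)
class ResponseRecord:
    """One quantified (organ, cell, tastant) response -- the pooling unit."""

    organ_id: str
    cell_name_in_prep: str
    tastant: str
    amplitude: float
    response_class: str
    qc: str = "pass"  # "pass" or "fail:<reason>"
    series_id: str | None = None
    map_cell_name: str | None = None

    def __post_init__(self):
        if self.response_class not in RESPONSE_CLASSES:
            raise ValueError(f"unknown response class {self.response_class!r}")

    @property
    def qc_pass(self) -> bool:
        return self.qc == "pass"


def analyze_trace(raw: Sequence[float], schedule: StimulusSchedule,
                  threshold: float = DEFAULT_THRESHOLD, *,
                  organ_id: str = "", cell_id: str = "", tastant: str = "",
                  series_id: str | None = None,
                  manual_exclude: bool = False) -> tuple[DffTrace, ResponseRecord]:
    """Full single-trace analysis: normalize, classify, measure, QC."""
    dff = compute_dff(raw, schedule, cell_id=cell_id, tastant=tastant)
    cls = classify_response(dff, schedule, threshold)
    amp = response_amplitude(dff, schedule, cls)
    qc = qc_validate(dff, schedule, amp, threshold, manual_exclude=manual_exclude)
    record = ResponseRecord(
        organ_id=organ_id, cell_name_in_prep=dff.cell_id, tastant=dff.tastant,
        amplitude=amp, response_class=cls, qc=str(qc), series_id=series_id)
    return dff, record


_RECORD_COLUMNS = ["organ_id", "series_id", "cell_name_in_prep", "tastant",
                   "amplitude", "response_class", "qc", "map_cell_name"]


def records_to_frame(records: Iterable[ResponseRecord]) -> pd.DataFrame:
    rows = [{c: getattr(r, c) for c in _RECORD_COLUMNS} for r in records]
    return pd.DataFrame(rows, columns=_RECORD_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[ResponseRecord]:
    records = []
    for row in frame.to_dict("records"):
        records.append(ResponseRecord(
            organ_id=str(row["organ_id"]),
            cell_name_in_prep=str(row["cell_name_in_prep"]),
            tastant=str(row["tastant"]),
            amplitude=float(row["amplitude"]),
            response_class=str(row["response_class"]),
            qc=str(row.get("qc", "pass")),
            series_id=None if pd.isna(row.get("series_id")) else str(row["series_id"]),
            map_cell_name=(None if pd.isna(row.get("map_cell_name"))
                           else str(row["map_cell_name"])),
        ))
    return records
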