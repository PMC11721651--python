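"""Gesture-aligned EDA windowing, specific-response classification and
cross-participant resonance detection.

For every (gesture, participant) pair a response window covers the gesture
span plus a post-gesture pad (1.5 s by default, accommodating the typical
1-3 s skin-conductance response latency).  A window is a *specific* response
when its amplitude — the maximal trough-to-peak rise between any ordered
sample pair inside the window — strictly exceeds 0.05 microsiemens.  A
gesture *resonates* when two or more participants (the narrator counts)
show specific responses within its window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corpus import EDATrace, GestureAnnotation

__all__ = [
    "SPECIFIC_THRESHOLD",
    "LATENCY_PAD",
    "RESONANCE_MIN",
    "ResponseWindow",
    "ResonanceRecord",
    "CoverageError",
    "InsufficientDataError",
    "extract_window",
    "classify_specific",
    "detect_resonance",
    "append_eda_outcomes",
    "build_response_table",
]

#: Minimum EDA rise (microsiemens) for a response to count as specific.
SPECIFIC_THRESHOLD = 0.05

#: Post-gesture window extension (seconds) absorbing response latency.
LATENCY_PAD = 1.5

#: Minimum number of concurrent specific responses for resonance.
RESONANCE_MIN = 2


class CoverageError(ValueError):
    """The requested window lies entirely outside the trace span."""


class InsufficientDataError(ValueError):
    """Too few samples in the window to measure an amplitude."""


@dataclass
class ResponseWindow:
    gesture_id: str
    participant_id: str
    window_start: float
    window_end: float
    samples: np.ndarray = field(repr=False)
    truncated: bool = False
    amplitude: float | None = None
    specific: bool | None = None


@dataclass
class ResonanceRecord:
    gesture_id: str
    n_specific: int
    EDA_G_resonance: bool


def extract_window(
    g: GestureAnnotation,
    trace: EDATrace,
    latency_pad: float = LATENCY_PAD,
) -> ResponseWindow:
    """Collect the trace samples falling in ``[onset, offset + latency_pad)``.

    Windows that run past either end of the trace are truncated and flagged;
    a window with no overlap at all raises :class:`CoverageError`.
    """
    start = g.onset
    end = g.offset + latency_pad
    if end <= trace.t0 or start >= trace.t_end:
        raise CoverageError(
            f"gesture {g.id}: window [{start}, {end}) outside trace span "
            f"[{trace.t0}, {trace.t_end}) of participant "
            f"{trace.participant_id}"
        )
    rate = trace.sampling_rate
    # first sample index with t >= start; last index with t < end (half-open)
    k0 = max(0, int(np.ceil((start - trace.t0) * rate - 1e-9)))
    k1 = min(len(trace.values),
             int(np.ceil((end - trace.t0) * rate - 1e-9)))
    truncated = start < trace.t0 - 1e-9 or end > trace.t_end + 1e-9
    return ResponseWindow(
        gesture_id=g.id,
        participant_id=trace.participant_id,
        window_start=start,
        window_end=end,
        samples=np.asarray(trace.values[k0:k1], dtype=float),
        truncated=truncated,
    )


def classify_specific(
    w: ResponseWindow, threshold: float = SPECIFIC_THRESHOLD
) -> ResponseWindow:
    """Fill ``amplitude`` and ``specific`` on a window.

    Amplitude is the maximal rise ``samples[j] - samples[i]`` over ordered
    pairs ``i < j`` (trough-to-peak), floored at 0; the response is specific
    when the amplitude strictly exceeds the threshold.
    """
    x = np.asarray(w.samples, dtype=float)
    if x.size < 2:
        raise InsufficientDataError(
            f"gesture {w.gesture_id}/{w.participant_id}: "
            f"{x.size} sample(s) in window"
        )
    running_min = np.minimum.accumulate(x)
    amplitude = float(max(0.0, np.max(x - running_min)))
    w.amplitude = amplitude
    w.specific = amplitude > threshold
    return w


def detect_resonance(
    g: GestureAnnotation,
    windows: list[ResponseWindow],
    resonance_min: int = RESONANCE_MIN,
    require_narrator: bool = False,
    narrator_id: str | None = None,
) -> ResonanceRecord:
    """Tally specific responses across participants for one gesture.

    The narrator's own window counts toward the tally; with
    ``require_narrator=True`` resonance additionally requires the narrator's
    response to be specific (``narrator_id`` must then be given).
    """
    for w in windows:
        if w.gesture_id != g.id:
            raise ValueError(
                f"window for gesture {w.gesture_id} passed to "
                f"detect_resonance({g.id})"
            )
        if w.specific is None:
            raise ValueError(
                f"window {w.gesture_id}/{w.participant_id} not classified"
            )
    n_specific = sum(bool(w.specific) for w in windows)
    resonates = n_specific >= resonance_min
    if require_narrator:
        if narrator_id is None:
            raise ValueError("require_narrator=True needs narrator_id")
        narr = [w for w in windows if w.participant_id == narrator_id]
        resonates = resonates and any(w.specific for w in narr)
    return ResonanceRecord(
        gesture_id=g.id, n_specific=n_specific, EDA_G_resonance=resonates
    )


def _windows_for_gesture(
    g: GestureAnnotation,
    traces: dict[str, EDATrace],
    latency_pad: float,
    threshold: float,
) -> list[ResponseWindow]:
    out = []
    for pid in sorted(traces):
        w = extract_window(g, traces[pid], latency_pad)
        out.append(classify_specific(w, threshold))
    return out


def append_eda_outcomes(
    table: pd.DataFrame,
    gestures: list[GestureAnnotation],
    traces: dict[str, EDATrace],
    threshold: float = SPECIFIC_THRESHOLD,
    latency_pad: float = LATENCY_PAD,
    resonance_min: int = RESONANCE_MIN,
    require_narrator: bool = False,
) -> pd.DataFrame:
    """Append per-gesture EDA outcome columns to a feature table.

    Adds ``EDA_specific_narrator`` (the narrator's own response),
    ``n_specific`` and ``EDA_G_resonance``.  Gestures whose windows fall
    outside every trace raise :class:`CoverageError`.
    """
    by_id = {g.id: g for g in gestures}
    narr_spec, n_spec, reso = [], [], []
    for _, row in table.iterrows():
        g = by_id[row["gesture_id"]]
        windows = _windows_for_gesture(g, traces, latency_pad, threshold)
        rec = detect_resonance(
            g, windows, resonance_min, require_narrator,
            narrator_id=row["narrator_id"],
        )
        narr = [w for w in windows
                if w.participant_id == row["narrator_id"]]
        narr_spec.append(int(bool(narr and narr[0].specific)))
        n_spec.append(rec.n_specific)
        reso.append(int(rec.EDA_G_resonance))
    out = table.copy()
    out["EDA_specific_narrator"] = narr_spec
    out["n_specific"] = n_spec
    out["EDA_G_resonance"] = reso
    return out


def build_response_table(
    table: pd.DataFrame,
    gestures: list[GestureAnnotation],
    traces: dict[str, EDATrace],
    threshold: float = SPECIFIC_THRESHOLD,
    latency_pad: float = LATENCY_PAD,
) -> pd.DataFrame:
    """Long per-(gesture, participant) table of specific-response indicators.

    One row per gesture per participant wearing a sensor, carrying the
    gesture's expressivity and grouping identifiers — the input to the
    arousal (expressivity -> specific response) model.
    """
    by_id = {g.id: g for g in gestures}
    rows = []
    for _, row in table.iterrows():
        g = by_id[row["gesture_id"]]
        for w in _windows_for_gesture(g, traces, latency_pad, threshold):
            rows.append(
                dict(
                    gesture_id=g.id,
                    story_id=row["story_id"],
                    recording_id=row["recording_id"],
                    participant_id=w.participant_id,
                    is_narrator=int(w.participant_id == row["narrator_id"]),
                    G_expressivity=row["G_expressivity"],
                    EDA_specific=int(bool(w.specific)),
                    amplitude=w.amplitude,
                )
            )
    return pd.DataFrame(rows)
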