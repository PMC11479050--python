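"""Angle-guided windowing of the movement trial.

Each flexion--extension repetition is delimited by successive full-flexion
points of the elbow-angle trace: the angle is low-pass smoothed (2 Hz), its
prominent local maxima (including the trace end points) are taken as marks,
and window k spans ``[marks[k], marks[k+1])`` in half-open sample-index
coordinates, yielding one window per repetition and muscle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .synth import MUSCLES, RecordingSession, ToneClass

log = logging.getLogger(__name__)

#: Feature formulas with N-2 terms degenerate on tiny windows; reject below this.
MIN_WINDOW_SAMPLES = 64


class SegmentationError(ValueError):
    """Raised when fewer than two flexion marks can be found."""


@dataclass
class SignalWindow:
    """One repetition's preprocessed sEMG samples for one muscle."""

    samples: np.ndarray
    muscle: str
    repetition_index: int  # 1-based
    subject_id: str
    tone_class: ToneClass

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("window contains non-finite samples")

    @property
    def n(self) -> int:
        return self.samples.size


def detect_flexion_marks(
    angle: np.ndarray,
    sampling_rate: float,
    smooth_cutoff: float = 2.0,
    prominence_frac: float = 0.5,
) -> np.ndarray:
    """Sample indices of full-flexion points (prominent angle maxima).

    The trace is smoothed with a zero-phase 2 Hz low-pass, then local maxima
    with prominence above ``prominence_frac`` of the trace's range are kept.
    End points are eligible: a movement that starts or ends at full flexion
    contributes boundary marks.
    """
    x = np.asarray(angle, dtype=float)
    if x.size < 8:
        raise SegmentationError("angle trace too short to segment")
    if smooth_cutoff > 0 and smooth_cutoff < sampling_rate / 2:
        sos = sps.butter(2, smooth_cutoff, btype="lowpass", fs=sampling_rate, output="sos")
        x = sps.sosfiltfilt(sos, x)
    rng_ = float(x.max() - x.min())
    if rng_ <= 0:
        raise SegmentationError("flat angle trace; no flexion cycles")
    # pad below the minimum so boundary maxima are detectable with full prominence
    padded = np.concatenate(([x.min() - rng_], x, [x.min() - rng_]))
    peaks, _ = sps.find_peaks(padded, prominence=prominence_frac * rng_)
    marks = peaks - 1
    if marks.size < 2:
        raise SegmentationError(
            f"found {marks.size} flexion mark(s); need at least 2 to window"
        )
    return marks


def windows_from_marks(
    session: RecordingSession,
    preprocessed: np.ndarray,
    marks: np.ndarray,
    min_samples: int = MIN_WINDOW_SAMPLES,
) -> list[SignalWindow]:
    """Cut the preprocessed movement channels into per-repetition windows.

    ``preprocessed`` is the (n, 2) movement sEMG after preprocessing, channel
    order (biceps, triceps).  Windows shorter than ``min_samples`` are
    rejected with a logged warning; repetition indices count accepted
    windows, identically for both muscles.
    """
    marks = np.asarray(marks)
    if marks.size < 2:
        raise SegmentationError("need at least 2 marks to form a window")
    windows: list[SignalWindow] = []
    rep = 0
    for k in range(marks.size - 1):
        start, stop = int(marks[k]), int(marks[k + 1])
        if stop - start < min_samples:
            log.warning(
                "subject %s: window %d-%d shorter than %d samples; rejected",
                session.subject_id, start, stop, min_samples,
            )
            continue
        rep += 1
        for j, muscle in enumerate(MUSCLES):
            windows.append(
                SignalWindow(
                    samples=preprocessed[start:stop, j],
                    muscle=muscle,
                    repetition_index=rep,
                    subject_id=session.subject_id,
                    tone_class=session.tone_class,
                )
            )
    return windows


def segment_session(
    session: RecordingSession,
    preprocessed: np.ndarray,
    **detect_kwargs,
) -> list[SignalWindow]:
    """Detect flexion marks on the session's angle trace and window the
    preprocessed movement channels."""
    marks = detect_flexion_marks(
        session.movement_angle, session.sampling_rate, **detect_kwargs
    )
    return windows_from_marks(session, preprocessed, marks)
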