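"""Repetition segmentation and peak range-of-motion extraction.

A movement trial contains (nominally) five repetitions.  Repetitions are
found by automated peak detection on a smoothed reference trace - the
whole-trunk (T1-vs-L5) primary angle - replacing the visual inspection a
human rater would perform: zero-phase low-pass filter, peak picking with a
minimum prominence and separation, boundaries at the between-peak minima.

Per repetition, the signed peak of the primary angle is taken in the
*effective* direction of movement: some participants move a segment opposite
to the cued global direction (countermovement), so the direction with the
larger absolute excursion inside the repetition window wins, with ties
broken toward the cued direction.  Non-primary (coupled) motion is an
envelope over the whole trial, max minus min, not per repetition.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, find_peaks, sosfiltfilt

from .config import CUED_SIGN
from .errors import InvalidInputError, SegmentationFailureError, TooFewRepetitionsError
from .kinematics import AnglePath

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Repetition:
    index: int  # 1-based
    start: int  # frame index, inclusive
    end: int  # frame index, exclusive
    peak: float = float("nan")  # signed, deg
    direction: float = 0.0  # +1 / -1 effective direction


@dataclass(frozen=True)
class SegmentMovementSummary:
    """The unit of all downstream statistics: one segment movement."""

    participant: str
    trial: int
    system: str
    segment: str
    movement: str
    mean_peak_primary: float  # deg, mean of |rep peaks| in effective direction
    excursion_secondary: float  # deg, whole-trial max - min
    excursion_tertiary: float  # deg
    n_reps: int


def _smooth(x: np.ndarray, fs: float, cutoff_hz: float) -> np.ndarray:
    nyq = fs / 2.0
    if cutoff_hz >= nyq:
        return x
    sos = butter(4, cutoff_hz / nyq, output="sos")
    return sosfiltfilt(sos, x)


def segment_repetitions(
    reference_path: AnglePath,
    expected_n: int = 5,
    lowpass_hz: float = 2.0,
    min_prominence_deg: float = 5.0,
    min_separation_s: float = 1.5,
) -> list[Repetition]:
    """Find repetition windows on the reference primary-plane trace.

    Returns ``expected_n`` repetitions, or ``expected_n - 1`` with a warning
    (mirroring trials where a participant performed only four); fewer is a
    :class:`SegmentationFailureError`.
    """
    if expected_n < 2:
        raise InvalidInputError("expected_n must be >= 2")
    t = reference_path.t
    x = reference_path.primary
    if len(t) < 8:
        raise SegmentationFailureError("reference trace too short to segment")
    fs = 1.0 / float(np.median(np.diff(t)))
    xs = _smooth(x, fs, lowpass_hz)
    # dominant excursion sign decides which way 'up' is on the rectified trace
    dom = 1.0 if abs(xs.max()) >= abs(xs.min()) else -1.0
    r = xs * dom
    distance = max(1, int(round(min_separation_s * fs)))
    peaks, props = find_peaks(r, prominence=min_prominence_deg, distance=distance)
    if len(peaks) > expected_n:
        # keep the expected_n most prominent bumps, back in time order
        order = np.argsort(props["prominences"])[::-1][:expected_n]
        peaks = np.sort(peaks[order])
    if len(peaks) < expected_n - 1:
        raise SegmentationFailureError(
            f"found {len(peaks)} repetitions, expected {expected_n} "
            f"(prominence>={min_prominence_deg} deg)"
        )
    if len(peaks) == expected_n - 1:
        warnings.warn(
            f"only {len(peaks)} of {expected_n} repetitions detected",
            RuntimeWarning,
            stacklevel=2,
        )
    # boundaries at the between-peak minima of the rectified trace
    bounds = [int(np.argmin(r[: peaks[0] + 1]))]
    for a, b in zip(peaks[:-1], peaks[1:]):
        bounds.append(a + int(np.argmin(r[a:b + 1])))
    bounds.append(peaks[-1] + int(np.argmin(r[peaks[-1]:])))
    return [
        Repetition(index=i + 1, start=bounds[i], end=bounds[i + 1] + 1)
        for i in range(len(peaks))
    ]


def peak_primary(
    path: AnglePath, reps: list[Repetition], cued_sign: float | None = None
) -> list[float]:
    """Signed peak per repetition, in the effective direction of movement."""
    if cued_sign is None:
        cued_sign = CUED_SIGN[path.movement]
    x = path.primary
    peaks = []
    for rep in reps:
        if rep.end <= rep.start or rep.start < 0 or rep.end > len(x):
            raise InvalidInputError(f"repetition window {rep} outside path bounds")
        w = x[rep.start:rep.end]
        if w.size == 0:
            raise InvalidInputError("empty repetition window")
        mx, mn = float(w.max()), float(w.min())
        if abs(mx) > abs(mn):
            direction = 1.0
        elif abs(mn) > abs(mx):
            direction = -1.0
        else:
            direction = cued_sign  # tie-break toward the cued direction
        peaks.append(mx if direction > 0 else mn)
    return peaks


def nonprimary_excursion(path: AnglePath) -> tuple[float, float]:
    """Whole-trial (max - min) envelope of the two coupled planes, deg."""
    sec = float(path.angles[:, 1].max() - path.angles[:, 1].min())
    ter = float(path.angles[:, 2].max() - path.angles[:, 2].min())
    return sec, ter


def summarize(
    path: AnglePath,
    reps: list[Repetition],
    participant: str = "",
    trial: int = 0,
    min_reps: int = 4,
) -> SegmentMovementSummary:
    """Average the repetition peak magnitudes and attach coupled excursions."""
    if len(reps) < min_reps:
        raise TooFewRepetitionsError(
            f"{path.segment}/{path.movement}: only {len(reps)} repetitions "
            f"(minimum {min_reps})"
        )
    peaks = peak_primary(path, reps)
    sec, ter = nonprimary_excursion(path)
    return SegmentMovementSummary(
        participant=participant,
        trial=trial,
        system=path.system,
        segment=path.segment,
        movement=path.movement,
        mean_peak_primary=float(np.mean(np.abs(peaks))),
        excursion_secondary=sec,
        excursion_tertiary=ter,
        n_reps=len(reps),
    )
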