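"""Per-pixel 1-D trace processing and per-beat feature extraction.

A pixel's intensity trace is optionally smoothed (Savitzky-Golay) and
detrended (polynomial baseline fit with the original mean re-added, so the
overall offset — useful for photobleaching monitoring — is preserved),
then split at its diastoles into single cardiac activations.  From each
activation five features are extracted: baseline, amplitude, duration at a
configurable recovery level, recovery time and activation time (half-max
upstroke), all with linear interpolation at threshold crossings.

Voltage-style traces, where activation is a downward intensity deflection,
are rectified internally as ``2*median - trace`` so every feature is
defined once for upward deflections and amplitudes are always positive.

Activation and recovery times are later synchronized across pixels by a
global recording clock: the greatest clock boundary preceding the event is
subtracted from it, and each activation is assigned to the clock bin
containing its half-time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy.signal import savgol_filter

from .comb import Polarity

__all__ = [
    "TraceParams",
    "SegmentedObject",
    "ActivationFeatures",
    "smooth_trace",
    "subtract_baseline_drift",
    "preprocess_trace",
    "rectify",
    "segment_activations",
    "threshold_objects",
    "select_object",
    "extract_features",
    "normalize_to_clock",
]

BaselineMode = Literal["first", "firstlast"]
ObjectSelection = Literal["first", "largest", "augmented"]


@dataclass
class TraceParams:
    """Parameters controlling per-trace processing and feature extraction.

    Attributes
    ----------
    smoothing_window, smoothing_order
        Savitzky-Golay window (odd number of frames; 0 disables smoothing)
        and polynomial order.
    drift_poly_degree
        Degree of the polynomial baseline-drift fit; negative disables.
    recovery_level
        Fraction of recovery defining the duration measurement: 0.8 means
        duration at 80% recovery (APD80/CaTD80).
    baseline_mode
        ``"first"`` uses the segment's first sample as baseline,
        ``"firstlast"`` the average of first and last samples.
    object_selection
        How to pick the thresholded object when noise splits a beat into
        several: first in time, longest, or nearest the comb-detected
        upstroke ("augmented").
    polarity
        ``"peaks"`` for upward activation deflections (calcium dyes),
        ``"troughs"`` for downward ones (voltage dyes).
    refinement_width_ms
        Radius of the local search around each comb tooth.
    """

    smoothing_window: int = 11
    smoothing_order: int = 4
    drift_poly_degree: int = 4
    recovery_level: float = 0.8
    baseline_mode: BaselineMode = "first"
    object_selection: ObjectSelection = "largest"
    polarity: Polarity = "peaks"
    refinement_width_ms: float = 10.0

    def __post_init__(self) -> None:
        if self.smoothing_window not in (0, 1) and self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd (or 0 to disable)")
        if self.smoothing_window > 1 and self.smoothing_order >= self.smoothing_window:
            raise ValueError("smoothing_order must be < smoothing_window")
        if not 0.0 < self.recovery_level < 1.0:
            raise ValueError("recovery_level must lie in (0, 1)")
        if self.baseline_mode not in ("first", "firstlast"):
            raise ValueError(f"unknown baseline_mode {self.baseline_mode!r}")
        if self.object_selection not in ("first", "largest", "augmented"):
            raise ValueError(f"unknown object_selection {self.object_selection!r}")
        if self.polarity not in ("peaks", "troughs"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.refinement_width_ms < 0:
            raise ValueError("refinement_width_ms must be >= 0")


@dataclass(frozen=True)
class SegmentedObject:
    """One contiguous above-threshold excursion within a beat segment.

    Times are fractional frames local to the segment, obtained by linear
    interpolation at the threshold crossings.
    """

    start_time: float
    end_time: float

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time


@dataclass
class ActivationFeatures:
    """Features of a single cardiac activation (AP or CaT).

    ``activation_time_ms`` and ``recovery_time_ms`` are global recording
    times at extraction; clock normalization rewrites them as offsets from
    the preceding clock boundary and fills ``bin_index``.
    """

    baseline: float
    amplitude: float
    duration_ms: float
    activation_time_ms: float
    recovery_time_ms: float
    half_time_frames: float
    bin_index: int | None = field(default=None)


def smooth_trace(trace: Sequence[float], window: int, order: int) -> np.ndarray:
    """Savitzky-Golay smoothing; ``window`` 0 or 1 is the identity.

    Savitzky-Golay was chosen because it removes noise while preserving
    sharp genuine deflections such as AP upstrokes; edge samples are
    handled by evaluating the polynomial fitted to the trailing window.
    Polynomials of degree <= ``order`` pass through unchanged.
    """
    trace = np.asarray(trace, dtype=float)
    if window in (0, 1):
        return trace.copy()
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if order >= window:
        raise ValueError("order must be < window")
    if window > len(trace):
        raise ValueError("window exceeds trace length")
    return savgol_filter(trace, window_length=window, polyorder=order, mode="interp")


def subtract_baseline_drift(trace: Sequence[float], degree: int) -> np.ndarray:
    """Remove a least-squares polynomial drift, preserving the trace mean.

    The fitted polynomial (degree ``degree`` over the whole trace) is
    subtracted and the original mean re-added, so ``mean(output) ==
    mean(input)`` exactly — the general intensity offset is kept, allowing
    photobleaching to be monitored across consecutive recordings.
    """
    trace = np.asarray(trace, dtype=float)
    if degree < 0:
        raise ValueError("degree must be >= 0")
    if len(trace) <= degree + 1:
        raise ValueError(f"trace of length {len(trace)} too short for degree {degree}")
    t = np.arange(len(trace), dtype=float)
    coeffs = npoly.polyfit(t, trace, deg=degree)
    fit = npoly.polyval(t, coeffs)
    return trace - fit + trace.mean()


def preprocess_trace(trace: Sequence[float], params: TraceParams) -> np.ndarray:
    """Apply the configured smoothing and drift removal to a raw trace."""
    out = np.asarray(trace, dtype=float)
    if params.smoothing_window > 1:
        out = smooth_trace(out, params.smoothing_window, params.smoothing_order)
    if params.drift_poly_degree >= 0:
        out = subtract_baseline_drift(out, params.drift_poly_degree)
    return out


def rectify(trace: Sequence[float]) -> np.ndarray:
    """Flip a downward-deflecting trace about its median: ``2*median - trace``."""
    trace = np.asarray(trace, dtype=float)
    return 2.0 * np.median(trace) - trace


def segment_activations(
    trace: Sequence[float], diastoles: Sequence[int]
) -> list[np.ndarray]:
    """Split a trace at its diastoles into single-beat segments.

    Segment ``k`` is ``trace[diastoles[k] .. diastoles[k+1]]`` inclusive of
    both endpoints, so ``n_diastoles - 1`` segments result.
    """
    trace = np.asarray(trace, dtype=float)
    dia = [int(d) for d in diastoles]
    if len(dia) < 2:
        raise ValueError("need at least 2 diastoles")
    if any(b <= a for a, b in zip(dia, dia[1:])):
        raise ValueError("diastoles must be strictly increasing")
    if dia[0] < 0 or dia[-1] >= len(trace):
        raise ValueError("diastoles out of trace bounds")
    return [trace[a : b + 1] for a, b in zip(dia, dia[1:])]


def threshold_objects(
    segment: Sequence[float], threshold: float
) -> list[SegmentedObject]:
    """Maximal runs of samples strictly above ``threshold``.

    Crossing times are linearly interpolated between the bracketing
    samples; a run touching the segment boundary uses the boundary sample
    time as its crossing.  Noise may split one activation into several
    objects — selection between them is a separate step.
    """
    seg = np.asarray(segment, dtype=float)
    if len(seg) < 2:
        raise ValueError("segment must have at least 2 samples")
    above = seg > threshold
    objects: list[SegmentedObject] = []
    n = len(seg)
    i = 0
    while i < n:
        if not above[i]:
            i += 1
            continue
        start_idx = i
        while i < n and above[i]:
            i += 1
        end_idx = i - 1
        if start_idx == 0:
            start = 0.0
        else:
            lo, hi = seg[start_idx - 1], seg[start_idx]
            start = (start_idx - 1) + (threshold - lo) / (hi - lo)
        if end_idx == n - 1:
            end = float(n - 1)
        else:
            hi, lo = seg[end_idx], seg[end_idx + 1]
            end = end_idx + (hi - threshold) / (hi - lo)
        objects.append(SegmentedObject(start_time=float(start), end_time=float(end)))
    return objects


def select_object(
    objects: Sequence[SegmentedObject],
    mode: ObjectSelection,
    upstroke_time: float | None = None,
) -> SegmentedObject | None:
    """Pick the object holding the true activation.

    ``first``: earliest start.  ``largest``: longest duration (ties go to
    the earliest).  ``augmented``: smallest distance from the comb-detected
    upstroke time (zero if the upstroke lies inside the object, otherwise
    the gap to the nearest edge; ties go to the earliest).  Returns None
    for an empty object list (no activation found in this beat).
    """
    if len(objects) == 0:
        return None
    if mode == "first":
        return min(objects, key=lambda o: o.start_time)
    if mode == "largest":
        return min(objects, key=lambda o: (-o.duration, o.start_time))
    if mode == "augmented":
        if upstroke_time is None:
            raise ValueError("augmented selection requires an upstroke time")

        def distance(o: SegmentedObject) -> float:
            if o.start_time <= upstroke_time <= o.end_time:
                return 0.0
            return min(abs(upstroke_time - o.start_time), abs(upstroke_time - o.end_time))

        return min(objects, key=lambda o: (distance(o), o.start_time))
    raise ValueError(f"unknown selection mode {mode!r}")


def extract_features(
    segment: Sequence[float],
    params: TraceParams,
    frame_interval_ms: float = 1.0,
    upstroke_time: float | None = None,
    segment_start_global: float = 0.0,
) -> ActivationFeatures | None:
    """Extract the five per-activation features from one beat segment.

    Baseline is the segment's first sample (or the first/last average);
    amplitude is peak minus baseline; duration is measured by thresholding
    at ``baseline + (1 - recovery_level) * amplitude`` with interpolated
    crossings; recovery time is the instant the recovery level is reached;
    activation time is the first interpolated up-crossing of half-maximal
    amplitude within the selected object.  Returns None when no sample
    exceeds the duration threshold (no activation found in this beat).

    ``upstroke_time`` is in global frames (as returned by
    ``detect_upstroke_times`` on the whole trace); ``segment_start_global``
    converts between segment-local and global frame coordinates.
    """
    seg = np.asarray(segment, dtype=float)
    if len(seg) < 2:
        raise ValueError("segment must have at least 2 samples")
    if params.polarity == "troughs":
        seg = rectify(seg)

    if params.baseline_mode == "first":
        baseline = float(seg[0])
    else:
        baseline = float((seg[0] + seg[-1]) / 2.0)
    amplitude = float(seg.max() - baseline)
    if amplitude <= 0:
        return None

    dur_threshold = baseline + (1.0 - params.recovery_level) * amplitude
    objects = threshold_objects(seg, dur_threshold)
    upstroke_local = None if upstroke_time is None else upstroke_time - segment_start_global
    obj = select_object(objects, params.object_selection, upstroke_local)
    if obj is None:
        return None

    act_threshold = baseline + 0.5 * amplitude
    activation_local = _first_upcrossing(seg, obj, act_threshold)
    if activation_local is None:
        return None

    dt = frame_interval_ms
    return ActivationFeatures(
        baseline=baseline,
        amplitude=amplitude,
        duration_ms=obj.duration * dt,
        activation_time_ms=(segment_start_global + activation_local) * dt,
        recovery_time_ms=(segment_start_global + obj.end_time) * dt,
        half_time_frames=segment_start_global + (len(seg) - 1) / 2.0,
    )


def _first_upcrossing(
    seg: np.ndarray, obj: SegmentedObject, threshold: float
) -> float | None:
    """First interpolated up-crossing of ``threshold`` within the object extent.

    Restricting the search to the selected object prevents noise crossings
    elsewhere in the segment from defining the activation time.  When the
    object starts already above the threshold (recovery level < 0.5) the
    object start is the crossing; when no sample in the object reaches the
    threshold the beat is reported missing.
    """
    lo = max(int(np.floor(obj.start_time)), 0)
    hi = min(int(np.ceil(obj.end_time)), len(seg) - 1)
    start_val = _interp_value(seg, obj.start_time)
    if start_val > threshold:
        # object already begins above half-max (recovery level < 0.5);
        # the crossing precedes the object, so its start is the instant
        return float(obj.start_time)
    for i in range(lo + 1, hi + 1):
        if seg[i - 1] <= threshold < seg[i]:
            return (i - 1) + (threshold - seg[i - 1]) / (seg[i] - seg[i - 1])
    window = seg[lo : hi + 1]
    if np.max(window) >= threshold:
        # plateau exactly at threshold: take the first sample reaching it
        return float(lo + int(np.argmax(window >= threshold)))
    return None


def _interp_value(seg: np.ndarray, t: float) -> float:
    i = int(np.floor(t))
    if i >= len(seg) - 1:
        return float(seg[-1])
    frac = t - i
    return float(seg[i] * (1 - frac) + seg[i + 1] * frac)


def normalize_to_clock(
    event_time: float, boundaries: Sequence[float]
) -> tuple[float, int] | tuple[None, None]:
    """Express an event time relative to the preceding global clock boundary.

    Returns ``(event_time - b, index of b)`` where ``b`` is the greatest
    boundary <= ``event_time``.  Events before the first boundary or at or
    after the last one are unassigned (``(None, None)``): they may belong
    to incomplete activations at the recording edges.
    """
    boundaries = np.asarray(boundaries, dtype=float)
    if len(boundaries) < 2:
        raise ValueError("clock needs at least 2 boundaries")
    if event_time < boundaries[0] or event_time >= boundaries[-1]:
        return None, None
    idx = int(np.searchsorted(boundaries, event_time, side="right")) - 1
    return float(event_time - boundaries[idx]), idx
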