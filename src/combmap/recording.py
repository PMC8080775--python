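"""Whole-recording analyses: recording clock, multi-wave, single-wave and
hybrid processing, feature maps.

Multi-wave processing segments every pass of the cardiac wave separately.
A *recording clock* — the midpoints between peak activations of the
spatially averaged trace — provides a global set of per-beat bins.  Each
pixel's trace is smoothed, detrended, split at its comb-detected diastoles
into single activations, and the five features of each activation are
extracted and assigned to the clock bin containing the activation's
half-time.  Even though diastoles differ between pixels, normalizing
activation and recovery times to the same global clock synchronizes all
pixels, which is what makes per-beat activation maps meaningful.

Single-wave processing treats the whole trace as one activation with no
rate assumption; hybrid processing splits a regular recording into
per-beat substacks, averages them frame-wise and runs single-wave analysis
on the average (robust to occasional artefacts, but blind to beat-to-beat
changes such as alternans).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .comb import Comb, Polarity, build_uniform_comb, comb_detect, detect_upstroke_times
from .io_stack import Recording
from .trace import (
    TraceParams,
    extract_features,
    normalize_to_clock,
    preprocess_trace,
    rectify,
    segment_activations,
)

__all__ = [
    "AnalysisError",
    "RecordingClock",
    "FeatureMaps",
    "FEATURE_NAMES",
    "compute_recording_clock",
    "analyze_multiwave",
    "analyze_singlewave",
    "analyze_hybrid",
    "hybrid_average",
    "temporal_sd_map",
    "estimate_custom_comb",
]

logger = logging.getLogger(__name__)

FEATURE_NAMES = ("baseline", "amplitude", "duration", "recovery_time", "activation_time")


class AnalysisError(RuntimeError):
    """The recording cannot be analyzed under the requested mode."""


def _nanmean(stack: np.ndarray, axis: int) -> np.ndarray:
    """Mean ignoring NaN; all-NaN slices give NaN without warnings."""
    counts = (~np.isnan(stack)).sum(axis=axis)
    sums = np.nansum(stack, axis=axis)
    out = np.full(counts.shape, np.nan)
    nz = counts > 0
    out[nz] = sums[nz] / counts[nz]
    return out


@dataclass(frozen=True)
class RecordingClock:
    """Global per-beat time bins: midpoints between peak activations.

    ``peak_times`` are the comb-detected peak-activation frames of the
    spatially averaged trace; ``boundaries_frames[k]`` is the midpoint of
    peaks ``k`` and ``k+1``.  The clock is not a segmentation of single
    beats — it is a shared reference that assigns every pixel's features
    to the same wave pass.
    """

    peak_times: tuple[int, ...]
    boundaries_frames: tuple[float, ...]
    frame_interval_ms: float

    @property
    def boundaries_ms(self) -> np.ndarray:
        return np.asarray(self.boundaries_frames) * self.frame_interval_ms

    @property
    def n_bins(self) -> int:
        return len(self.boundaries_frames) - 1


@dataclass
class FeatureMaps:
    """Per-beat and beat-averaged spatial maps of the extracted features.

    ``per_beat[name]`` is a ``rows x cols x n_bins`` array (NaN marks
    missing: masked pixels, failed beats, unassigned bins).  Durations,
    activation and recovery times are in ms; baseline and amplitude in the
    recording's intensity units.  Activation and recovery times are
    clock-relative in multi-wave mode and global (from frame 0) in
    single-wave/hybrid mode.
    """

    per_beat: dict[str, np.ndarray]
    frame_interval_ms: float
    clock: RecordingClock | None = None

    def beat_mean(self, feature: str) -> np.ndarray:
        """Per-pixel mean over beats, ignoring missing beats."""
        return _nanmean(self.per_beat[feature], axis=2)

    def spatial_mean_per_beat(self, feature: str) -> np.ndarray:
        """Per-beat mean over pixels, ignoring missing pixels."""
        stack = self.per_beat[feature]
        return _nanmean(stack.reshape(-1, stack.shape[2]), axis=0)

    def grand_mean(self, feature: str) -> float:
        """Scalar mean of the beat-averaged map over analyzed pixels."""
        bm = self.beat_mean(feature)
        if np.isnan(bm).all():
            return float("nan")
        return float(np.nanmean(bm))

    @property
    def n_bins(self) -> int:
        return self.per_beat[FEATURE_NAMES[0]].shape[2]


def _resolve_comb(
    rec: Recording, period_frames: int | None, comb: Comb | None
) -> Comb:
    if (period_frames is None) == (comb is None):
        raise ValueError("exactly one of period_frames or comb must be given")
    if comb is not None:
        return comb
    return build_uniform_comb(int(period_frames), rec.n_frames)


def _global_trace(rec: Recording, params: TraceParams) -> np.ndarray:
    m = rec.effective_mask()
    if not m.any():
        raise AnalysisError("no unmasked pixels")
    trace = rec.data[m].mean(axis=0)
    return preprocess_trace(trace, params)


def compute_recording_clock(
    rec: Recording,
    period_frames: int | None = None,
    comb: Comb | None = None,
    polarity: Polarity = "peaks",
    params: TraceParams | None = None,
) -> RecordingClock:
    """Build the global recording clock from the spatial average trace.

    Peak activations are found with the comb: signal maxima for
    calcium-style recordings (``polarity="peaks"``) and minima for
    voltage-style intensity (``"troughs"``).  At least three peaks are
    required so that at least one complete bin exists between the two
    resulting boundaries.
    """
    params = params or TraceParams(polarity=polarity)
    the_comb = _resolve_comb(rec, period_frames, comb)
    trace = _global_trace(rec, params)
    det = comb_detect(
        trace, the_comb, polarity, params.refinement_width_ms, rec.frame_interval_ms
    )
    peaks = det.tooth_positions
    if len(peaks) < 3:
        raise AnalysisError(
            f"insufficient waves: {len(peaks)} peak activations detected, need >= 3"
        )
    boundaries = tuple((a + b) / 2.0 for a, b in zip(peaks, peaks[1:]))
    return RecordingClock(
        peak_times=tuple(peaks),
        boundaries_frames=boundaries,
        frame_interval_ms=rec.frame_interval_ms,
    )


def _upstroke_for_segment(
    upstrokes: Sequence[int] | None, start: int, end: int
) -> float | None:
    """The comb-detected upstroke falling inside [start, end] (nearest to its
    center when the window contains none or several)."""
    if upstrokes is None or len(upstrokes) == 0:
        return None
    inside = [u for u in upstrokes if start <= u <= end]
    if len(inside) == 1:
        return float(inside[0])
    center = (start + end) / 2.0
    pool = inside if inside else list(upstrokes)
    return float(min(pool, key=lambda u: abs(u - center)))


def _empty_maps(rows: int, cols: int, n_bins: int) -> dict[str, np.ndarray]:
    return {f: np.full((rows, cols, n_bins), np.nan) for f in FEATURE_NAMES}


def analyze_multiwave(
    rec: Recording,
    params: TraceParams,
    period_frames: int | None = None,
    comb: Comb | None = None,
    clock: RecordingClock | None = None,
) -> FeatureMaps:
    """Segment and measure every wave pass of a regularly activated recording.

    Per unmasked pixel: preprocess, rectify voltage-style traces, detect
    diastoles with the comb, split into beats, extract features, and bin
    them by the global clock.  Pixels whose beats all fail simply stay
    missing; a single bad pixel never aborts the map.
    """
    the_comb = _resolve_comb(rec, period_frames, comb)
    if clock is None:
        clock = compute_recording_clock(
            rec, comb=the_comb, polarity=params.polarity, params=params
        )
    boundaries_ms = clock.boundaries_ms
    n_bins = clock.n_bins
    rows, cols, _ = rec.shape
    dt = rec.frame_interval_ms
    maps = _empty_maps(rows, cols, n_bins)
    mask = rec.effective_mask()
    params_up = replace(params, polarity="peaks")  # traces rectified below
    need_upstrokes = params.object_selection == "augmented"

    n_overwrites = 0
    for r in range(rows):
        for c in range(cols):
            if not mask[r, c]:
                continue
            work = preprocess_trace(rec.data[r, c, :], params)
            if params.polarity == "troughs":
                work = rectify(work)
            try:
                dia = comb_detect(
                    work, the_comb, "troughs", params.refinement_width_ms, dt
                ).tooth_positions
            except ValueError:
                logger.debug("pixel (%d,%d): diastole detection failed", r, c)
                continue
            if len(dia) < 2:
                continue
            upstrokes = (
                detect_upstroke_times(
                    work, the_comb, "peaks", params.refinement_width_ms, dt
                )
                if need_upstrokes
                else None
            )
            segments = segment_activations(work, dia)
            for k, seg in enumerate(segments):
                start, end = dia[k], dia[k + 1]
                feats = extract_features(
                    seg,
                    params_up,
                    frame_interval_ms=dt,
                    upstroke_time=_upstroke_for_segment(upstrokes, start, end),
                    segment_start_global=float(start),
                )
                if feats is None:
                    logger.debug("pixel (%d,%d) beat %d: no activation", r, c, k)
                    continue
                half_ms = feats.half_time_frames * dt
                _, bin_idx = normalize_to_clock(half_ms, boundaries_ms)
                if bin_idx is None:
                    continue
                act_rel, _ = normalize_to_clock(feats.activation_time_ms, boundaries_ms)
                rec_rel, _ = normalize_to_clock(feats.recovery_time_ms, boundaries_ms)
                if not np.isnan(maps["amplitude"][r, c, bin_idx]):
                    n_overwrites += 1
                maps["baseline"][r, c, bin_idx] = feats.baseline
                maps["amplitude"][r, c, bin_idx] = feats.amplitude
                maps["duration"][r, c, bin_idx] = feats.duration_ms
                maps["activation_time"][r, c, bin_idx] = (
                    np.nan if act_rel is None else act_rel
                )
                maps["recovery_time"][r, c, bin_idx] = (
                    np.nan if rec_rel is None else rec_rel
                )
    if n_overwrites:
        logger.warning(
            "%d activations landed in already-filled clock bins and overwrote them",
            n_overwrites,
        )
    result = FeatureMaps(per_beat=maps, frame_interval_ms=dt, clock=clock)
    _log_summary(result, mask)
    return result


def analyze_singlewave(rec: Recording, params: TraceParams) -> FeatureMaps:
    """Analyze a recording containing a single wave pass.

    No clock and no comb: each pixel's whole trace is one segment and
    activation/recovery times are global milliseconds from frame 0, so no
    assumption about activation rate is made.
    """
    rows, cols, _ = rec.shape
    dt = rec.frame_interval_ms
    maps = _empty_maps(rows, cols, 1)
    mask = rec.effective_mask()
    params_up = replace(params, polarity="peaks")
    for r in range(rows):
        for c in range(cols):
            if not mask[r, c]:
                continue
            work = preprocess_trace(rec.data[r, c, :], params)
            if params.polarity == "troughs":
                work = rectify(work)
            upstroke = None
            if params.object_selection == "augmented":
                upstroke = float(np.argmax(np.diff(work)))
            feats = extract_features(
                work, params_up, frame_interval_ms=dt, upstroke_time=upstroke
            )
            if feats is None:
                continue
            maps["baseline"][r, c, 0] = feats.baseline
            maps["amplitude"][r, c, 0] = feats.amplitude
            maps["duration"][r, c, 0] = feats.duration_ms
            maps["activation_time"][r, c, 0] = feats.activation_time_ms
            maps["recovery_time"][r, c, 0] = feats.recovery_time_ms
    result = FeatureMaps(per_beat=maps, frame_interval_ms=dt, clock=None)
    _log_summary(result, mask)
    return result


def hybrid_average(
    rec: Recording, period_frames: int, params: TraceParams
) -> Recording:
    """Split a regular recording into per-beat substacks and average them.

    The first split point is the first recording-clock boundary; further
    split points follow at multiples of the basic cycle length (the
    user-supplied period), so every substack holds exactly one cycle and
    the substacks are naturally aligned for frame-wise averaging.  An
    incomplete trailing substack is discarded; at least two complete
    substacks are required.
    """
    clock = compute_recording_clock(
        rec, period_frames=period_frames, polarity=params.polarity, params=params
    )
    t0 = int(round(clock.boundaries_frames[0]))
    bcl = int(period_frames)
    n_sub = (rec.n_frames - t0) // bcl
    if n_sub < 2:
        raise AnalysisError(f"insufficient complete substacks: {n_sub} (need >= 2)")
    subs = [rec.data[:, :, t0 + k * bcl : t0 + (k + 1) * bcl] for k in range(n_sub)]
    avg = np.mean(np.stack(subs, axis=0), axis=0)
    return Recording(avg, rec.frame_interval_ms, rec.mask)


def analyze_hybrid(
    rec: Recording, period_frames: int, params: TraceParams
) -> FeatureMaps:
    """Average all wave passes into one beat, then run single-wave analysis.

    Averaging suppresses noise (residual noise falls as 1/sqrt(N) over N
    substacks) and occasional per-beat artefacts, but discards beat-to-beat
    variation — alternans cannot be analyzed in this mode.
    """
    return analyze_singlewave(hybrid_average(rec, period_frames, params), params)


def temporal_sd_map(maps: FeatureMaps, feature: str) -> np.ndarray:
    """Per-pixel standard deviation of a feature over wave passes.

    Regularly activated sites have consistent per-beat features and a low
    standard deviation; sites where a periodic comb was forced onto
    nonperiodic activity segment poorly and light up.  Pixels with fewer
    than two measured beats are NaN.
    """
    stack = maps.per_beat[feature]
    counts = (~np.isnan(stack)).sum(axis=2)
    mean = _nanmean(stack, axis=2)
    sq = np.nansum((stack - mean[:, :, None]) ** 2, axis=2)
    sd = np.full(counts.shape, np.nan)
    ok = counts >= 2
    sd[ok] = np.sqrt(sq[ok] / (counts[ok] - 1))
    return sd


def estimate_custom_comb(
    rec: Recording,
    polarity: Polarity = "peaks",
    params: TraceParams | None = None,
) -> Comb:
    """Heuristically construct a comb when the activation rate is unknown.

    The spatially averaged trace is usually low-noise enough for simple
    thresholding at mid-range to work: each above-threshold excursion
    contributes its maximum as an activation time, and the intervals
    between consecutive activation times become a custom comb.  This is a
    convenience for spontaneously active preparations and is *heuristic* —
    with externally controlled pacing, supply the true period instead.
    """
    params = params or TraceParams(polarity=polarity)
    trace = _global_trace(rec, params)
    if polarity == "troughs":
        trace = rectify(trace)
    thr = (trace.max() + trace.min()) / 2.0
    above = trace > thr
    times: list[int] = []
    i = 0
    while i < len(trace):
        if not above[i]:
            i += 1
            continue
        j = i
        while j < len(trace) and above[j]:
            j += 1
        times.append(i + int(np.argmax(trace[i:j])))
        i = j
    if len(times) < 2:
        raise AnalysisError("fewer than 2 activations found; cannot build a comb")
    intervals = np.diff(times)
    from .comb import build_custom_comb

    return build_custom_comb(intervals.tolist())


def _log_summary(maps: FeatureMaps, mask: np.ndarray) -> None:
    amp = maps.per_beat["amplitude"]
    n_px = int(mask.sum())
    missing = int(np.isnan(amp[mask]).all(axis=-1).sum()) if n_px else 0
    logger.info(
        "analysis summary: %d bins, %d analyzed pixels, %.1f%% fully missing",
        maps.n_bins,
        n_px,
        100.0 * missing / max(n_px, 1),
    )
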