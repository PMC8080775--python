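"""The comb algorithm: locating one extremum per expected beat.

When the activation rate of a recording is known (external pacing, regular
sinus rhythm, or an S1-S2 protocol), the per-beat signal minima (diastoles)
or maxima (peak activations) can be found jointly rather than one by one: a
rigid "comb" with teeth at the known inter-beat intervals is slid across
the trace, the placement with the most extreme mean signal under the teeth
is kept, and each tooth is then refined by a small local search.  Because
every tooth moves together during the global search, detected events are
guaranteed to be spaced consistently with the known rate, which makes the
approach highly resistant to noise and immune to the too-close/too-far
artefacts of thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "Polarity",
    "Comb",
    "CombDetection",
    "build_uniform_comb",
    "build_custom_comb",
    "comb_detect",
    "detect_upstroke_times",
]

#: Which extrema the comb targets: "troughs" finds signal minima,
#: "peaks" finds signal maxima.
Polarity = Literal["troughs", "peaks"]


@dataclass(frozen=True)
class Comb:
    """Ordered tooth offsets (in frames) encoding the known activation pattern.

    ``tooth_offsets`` is strictly increasing and starts at 0; ``span`` is
    the last offset.  A uniform comb with period ``p`` has offsets
    ``0, p, 2p, ...``; a custom comb may use arbitrary intervals (e.g. for
    an S1-S2 protocol).
    """

    tooth_offsets: tuple[int, ...]

    def __post_init__(self) -> None:
        offs = tuple(int(t) for t in self.tooth_offsets)
        if len(offs) < 1:
            raise ValueError("comb needs at least one tooth")
        if offs[0] != 0:
            raise ValueError("first tooth offset must be 0")
        if any(b <= a for a, b in zip(offs, offs[1:])):
            raise ValueError("tooth offsets must be strictly increasing")
        object.__setattr__(self, "tooth_offsets", offs)

    @property
    def span(self) -> int:
        return self.tooth_offsets[-1]

    @property
    def n_teeth(self) -> int:
        return len(self.tooth_offsets)


@dataclass(frozen=True)
class CombDetection:
    """Result of a comb placement: global offset plus refined tooth positions."""

    best_offset: int
    tooth_positions: tuple[int, ...]
    objective: float


def build_uniform_comb(period_frames: int, n_frames: int) -> Comb:
    """Comb with evenly spaced teeth for a recording paced every ``period_frames``.

    The number of teeth is ``floor(n_frames / period_frames)``, which keeps
    the full sliding range available while covering as many beats as fit.
    At least two teeth must be representable.
    """
    period_frames = int(period_frames)
    n_frames = int(n_frames)
    if period_frames < 2:
        raise ValueError("period_frames must be >= 2")
    n_teeth = n_frames // period_frames
    if n_teeth < 2:
        raise ValueError(
            f"cannot fit 2 teeth of period {period_frames} in {n_frames} frames"
        )
    return Comb(tuple(k * period_frames for k in range(n_teeth)))


def build_custom_comb(intervals_frames: Sequence[int]) -> Comb:
    """Comb from explicit inter-tooth intervals (frames).

    ``intervals (150, 150, 60)`` yields offsets ``(0, 150, 300, 360)`` —
    e.g. three S1 beats 150 frames apart followed by an S2 coupled at 60.
    """
    intervals = [int(v) for v in intervals_frames]
    if len(intervals) == 0:
        raise ValueError("need at least one interval")
    if any(v < 1 for v in intervals):
        raise ValueError("intervals must be positive")
    return Comb((0, *np.cumsum(intervals).tolist()))


def _local_extremum(trace: np.ndarray, center: int, w: int, polarity: Polarity) -> int:
    lo = max(0, center - w)
    hi = min(len(trace) - 1, center + w)
    window = trace[lo : hi + 1]
    # earliest index wins ties (np.argmin/argmax return the first occurrence)
    if polarity == "troughs":
        return lo + int(np.argmin(window))
    return lo + int(np.argmax(window))


def comb_detect(
    trace: Sequence[float],
    comb: Comb,
    polarity: Polarity,
    refinement_width_ms: float = 10.0,
    frame_interval_ms: float = 1.0,
) -> CombDetection:
    """Slide a rigid comb over a trace and refine each tooth locally.

    The comb is placed at every offset ``o`` in ``0 .. len(trace) - span - 1``
    (all teeth inside the trace) and the mean signal under the teeth is
    evaluated; the offset minimizing it (polarity ``"troughs"``) or
    maximizing it (``"peaks"``) wins, with ties broken by the smallest
    offset.  Each tooth is then moved to the local extremum within
    ``±round(refinement_width_ms / frame_interval_ms)`` frames of its
    placed position (clipped at the trace boundaries, earliest index on
    ties).  If a refinement would break the strictly increasing ordering of
    tooth positions, the offending tooth keeps its unrefined position.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1:
        raise ValueError("trace must be 1-D")
    n = len(trace)
    if comb.span >= n:
        raise ValueError(f"comb span {comb.span} >= trace length {n}")
    teeth = np.asarray(comb.tooth_offsets)
    offsets = np.arange(n - comb.span)
    objective = trace[offsets[:, None] + teeth[None, :]].mean(axis=1)
    if polarity == "troughs":
        best = int(np.argmin(objective))
    elif polarity == "peaks":
        best = int(np.argmax(objective))
    else:
        raise ValueError(f"unknown polarity {polarity!r}")

    w = int(round(refinement_width_ms / frame_interval_ms))
    positions: list[int] = []
    for k, tooth in enumerate(comb.tooth_offsets):
        unrefined = best + tooth
        refined = _local_extremum(trace, unrefined, w, polarity) if w > 0 else unrefined
        if positions and refined <= positions[-1]:
            refined = unrefined  # monotonicity guard
        positions.append(refined)
    return CombDetection(
        best_offset=best,
        tooth_positions=tuple(positions),
        objective=float(objective[best]),
    )


def detect_upstroke_times(
    trace: Sequence[float],
    comb: Comb,
    polarity: Polarity,
    refinement_width_ms: float = 10.0,
    frame_interval_ms: float = 1.0,
) -> tuple[int, ...]:
    """Per-beat times of peak activation rate (AP/CaT upstrokes).

    The trace derivative is approximated as the difference of consecutive
    samples and the comb is applied to it.  ``polarity`` describes the
    activation deflection of the *signal*: ``"peaks"`` (upward,
    calcium-style) looks for derivative maxima, ``"troughs"`` (downward,
    voltage-style intensity) for derivative minima.  Running the comb on
    the whole derivative trace is far more robust to noise than locating
    the steepest slope within each beat separately.
    """
    trace = np.asarray(trace, dtype=float)
    if len(trace) < comb.span + 2:
        raise ValueError("trace too short for derivative comb detection")
    d = np.diff(trace)
    det = comb_detect(d, comb, polarity, refinement_width_ms, frame_interval_ms)
    return det.tooth_positions
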