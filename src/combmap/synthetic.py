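"""Synthetic recordings with exact ground truth.

Generators for AP-like and CaT-like transient trains, planar propagating
waves over a pixel grid with known conduction speed, amplitude alternans
(concordant and discordant with a nodal line), additive Gaussian noise and
slow polynomial baseline drift.  Every generator is seed-deterministic and
returns a :class:`GroundTruth` describing exactly what was synthesized, so
every downstream feature can be scored without re-derivation.

The tent-shaped AP template is piecewise linear, which makes its features
available in closed form: with rise ``R`` frames, fall ``F`` frames and
baseline 0, the duration at recovery level ``L`` is ``L * (R + F)``
frames, the half-max activation time is ``R / 2`` and the recovery time is
``R + L * F`` (all offsets from the transient onset).

These fixtures emulate fluorescence kinetics geometrically; they contain
no ionic-model biophysics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from numpy.polynomial import polynomial as npoly

from .io_stack import Recording

__all__ = [
    "GroundTruth",
    "make_transient_template",
    "make_trace",
    "make_planar_wave_stack",
    "make_discordant_alternans_stack",
    "tent_duration",
    "tent_activation_offset",
    "tent_recovery_offset",
]

TemplateKind = Literal["ap_tent", "cat_skewed"]


@dataclass
class GroundTruth:
    """Exact description of a generated fixture.

    Times are integer frames unless noted.  Per-pixel fields are 2-D
    arrays matching the stack's spatial shape; per-beat fields have one
    entry per stimulus.
    """

    stimulus_times: np.ndarray
    peak_times: np.ndarray
    amplitudes: np.ndarray
    rise_frames: int
    fall_frames: int
    template_kind: str
    alternans_a: float = 0.0
    noise_sd: float = 0.0
    drift_coeffs: tuple[float, ...] = ()
    speed_px_per_frame: float | None = None
    activation_delay_frames: np.ndarray | None = None
    alternans_sign: np.ndarray | None = None
    nodal_row: int | None = None

    def duration_at(self, level: float) -> float:
        """Closed-form tent duration (frames) at recovery level ``level``."""
        if self.template_kind != "ap_tent":
            raise ValueError("closed-form duration available for ap_tent only")
        return tent_duration(self.rise_frames, self.fall_frames, level)


def tent_duration(rise: int, fall: int, level: float) -> float:
    """Duration of a tent transient at recovery fraction ``level`` (frames)."""
    return level * (rise + fall)


def tent_activation_offset(rise: int) -> float:
    """Half-max upstroke time of a tent, as an offset from its onset (frames)."""
    return rise / 2.0


def tent_recovery_offset(rise: int, fall: int, level: float) -> float:
    """Time the tent reaches ``level`` recovery, offset from onset (frames)."""
    return rise + level * fall


def make_transient_template(
    kind: TemplateKind,
    rise_frames: int,
    fall_frames: int,
    amplitude: float = 1.0,
) -> np.ndarray:
    """A single-transient waveform of length ``rise + fall + 1`` frames.

    ``ap_tent`` rises linearly from 0 to ``amplitude`` over ``rise_frames``
    and falls linearly back over ``fall_frames``.  ``cat_skewed`` has the
    same linear rise but decays exponentially (three time constants over
    the fall), mimicking a calcium transient; its peak sits exactly at
    frame ``rise_frames``.
    """
    rise = int(rise_frames)
    fall = int(fall_frames)
    if rise < 1 or fall < 1:
        raise ValueError("rise_frames and fall_frames must be >= 1")
    t = np.arange(rise + fall + 1, dtype=float)
    if kind == "ap_tent":
        up = t / rise
        down = 1.0 - (t - rise) / fall
        shape = np.where(t <= rise, up, down)
    elif kind == "cat_skewed":
        up = t / rise
        down = np.exp(-3.0 * (t - rise) / fall)
        shape = np.where(t <= rise, up, down)
    else:
        raise ValueError(f"unknown template kind {kind!r}")
    return amplitude * shape


def make_trace(
    template: np.ndarray,
    intervals_frames: Sequence[int],
    n_frames: int,
    noise_sd: float = 0.0,
    drift_poly: Sequence[float] = (),
    alternans_a: float = 0.0,
    seed: int = 0,
    start_frame: int = 0,
    rise_frames: int | None = None,
    fall_frames: int | None = None,
    template_kind: str = "ap_tent",
) -> tuple[np.ndarray, GroundTruth]:
    """A train of transients with optional alternans, drift and noise.

    Transients are pasted at the cumulative stimulus times
    ``start_frame, start_frame + intervals[0], ...``; beat ``k`` is scaled
    by ``1 + alternans_a * (-1)**k`` (even beats large).  ``drift_poly``
    gives polynomial coefficients (ascending order) evaluated at
    normalized time ``t / (n_frames - 1)``, emulating slow baseline drift
    such as photobleaching.  Gaussian noise of ``noise_sd`` is added with
    the given seed.  Transients must not overlap.
    """
    template = np.asarray(template, dtype=float)
    if not 0.0 <= alternans_a < 1.0:
        raise ValueError("alternans_a must lie in [0, 1)")
    intervals = [int(v) for v in intervals_frames]
    stim = np.concatenate([[0], np.cumsum(intervals)]).astype(int) + int(start_frame)
    tlen = len(template)
    if any(b - a < tlen for a, b in zip(stim, stim[1:])):
        raise ValueError("transients overlap: intervals shorter than the template")
    if stim[-1] + tlen > n_frames:
        raise ValueError("transients do not fit in n_frames")
    trace = np.zeros(int(n_frames), dtype=float)
    scales = 1.0 + alternans_a * (-1.0) ** np.arange(len(stim))
    for k, s in enumerate(stim):
        trace[s : s + tlen] += scales[k] * template
    if len(drift_poly) > 0:
        tt = np.arange(n_frames, dtype=float) / max(n_frames - 1, 1)
        trace += npoly.polyval(tt, np.asarray(drift_poly, dtype=float))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        trace += rng.normal(0.0, noise_sd, size=n_frames)
    peak_offset = int(np.argmax(template))
    rise = peak_offset if rise_frames is None else int(rise_frames)
    fall = (tlen - 1 - peak_offset) if fall_frames is None else int(fall_frames)
    gt = GroundTruth(
        stimulus_times=stim,
        peak_times=stim + peak_offset,
        amplitudes=scales * float(template.max()),
        rise_frames=rise,
        fall_frames=fall,
        template_kind=template_kind,
        alternans_a=float(alternans_a),
        noise_sd=float(noise_sd),
        drift_coeffs=tuple(float(c) for c in drift_poly),
    )
    return trace, gt


def _assemble_stack(
    clean_trace_for_row,
    rows: int,
    cols: int,
    n_frames: int,
    noise_sd: float,
    seed: int,
    frame_interval_ms: float,
    mask: np.ndarray | None,
) -> Recording:
    """Broadcast one clean trace per row across columns, then add noise."""
    data = np.empty((rows, cols, n_frames), dtype=float)
    for r in range(rows):
        data[r, :, :] = clean_trace_for_row(r)[None, :]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data += rng.normal(0.0, noise_sd, size=data.shape)
    return Recording(data, frame_interval_ms, mask)


def make_planar_wave_stack(
    rows: int = 16,
    cols: int = 16,
    speed_px_per_frame: float = 1.0,
    bcl_frames: int = 150,
    n_beats: int = 6,
    template: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    frame_interval_ms: float = 1.0,
    first_stim_frame: int = 10,
    rise_frames: int = 10,
    fall_frames: int = 30,
    amplitude: float = 1.0,
    mask: np.ndarray | None = None,
) -> tuple[Recording, GroundTruth]:
    """A plane wave propagating along rows at a known conduction speed.

    Row ``r`` activates ``round(r / speed)`` frames after row 0 on every
    beat; the wave must fully traverse the field within one basic cycle
    length.  With 1 ms frames and pixel pitch ``p`` mm the true conduction
    velocity is ``speed * p`` mm/ms.  ``speed_px_per_frame = inf`` gives a
    spatially uniform flash train.
    """
    if template is None:
        template = make_transient_template("ap_tent", rise_frames, fall_frames, amplitude)
    else:
        template = np.asarray(template, dtype=float)
        rise_frames = int(np.argmax(template))
        fall_frames = len(template) - 1 - rise_frames
    if speed_px_per_frame <= 0:
        raise ValueError("speed must be positive")
    delays = np.array(
        [int(round(r / speed_px_per_frame)) for r in range(rows)], dtype=int
    )
    if delays.max() + len(template) > bcl_frames:
        raise ValueError(
            "wave does not traverse the field within one cycle "
            f"(max delay {delays.max()} + template {len(template)} > BCL {bcl_frames})"
        )
    n_frames = int(first_stim_frame) + int(n_beats) * int(bcl_frames)
    intervals = [int(bcl_frames)] * (int(n_beats) - 1)

    def row_trace(r: int) -> np.ndarray:
        tr, _ = make_trace(
            template,
            intervals,
            n_frames,
            start_frame=int(first_stim_frame) + int(delays[r]),
        )
        return tr

    recording = _assemble_stack(
        row_trace, rows, cols, n_frames, noise_sd, seed, frame_interval_ms, mask
    )
    stim0 = int(first_stim_frame) + np.arange(n_beats, dtype=int) * int(bcl_frames)
    gt = GroundTruth(
        stimulus_times=stim0,
        peak_times=stim0 + int(np.argmax(template)),
        amplitudes=np.full(n_beats, float(template.max())),
        rise_frames=rise_frames,
        fall_frames=fall_frames,
        template_kind="ap_tent",
        noise_sd=float(noise_sd),
        speed_px_per_frame=float(speed_px_per_frame),
        activation_delay_frames=np.repeat(delays[:, None], cols, axis=1).astype(float),
    )
    return recording, gt


def make_discordant_alternans_stack(
    rows: int = 16,
    cols: int = 16,
    a: float = 0.2,
    nodal_row: int = 8,
    bcl_frames: int = 150,
    n_beats: int = 8,
    template: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    frame_interval_ms: float = 1.0,
    first_stim_frame: int = 10,
    taper_px: int = 1,
    rise_frames: int = 10,
    fall_frames: int = 30,
    amplitude: float = 1.0,
) -> tuple[Recording, GroundTruth]:
    """Spatially discordant amplitude alternans with a nodal line.

    Rows above ``nodal_row`` alternate in one phase, rows below in the
    opposite phase (even beats large above, small below), and the
    alternation magnitude tapers linearly to zero over ``taper_px`` rows
    around the nodal row — the nodal line itself does not alternate.  The
    flash is spatially uniform (no propagation), isolating the alternans
    signal.
    """
    if not 0.0 <= a < 1.0:
        raise ValueError("alternans magnitude must lie in [0, 1)")
    if template is None:
        template = make_transient_template("ap_tent", rise_frames, fall_frames, amplitude)
    else:
        template = np.asarray(template, dtype=float)
    n_frames = int(first_stim_frame) + int(n_beats) * int(bcl_frames)
    intervals = [int(bcl_frames)] * (int(n_beats) - 1)
    r_idx = np.arange(rows)
    sign = np.sign(nodal_row - r_idx).astype(float)  # +1 above the line, -1 below
    a_eff = a * np.minimum(1.0, np.abs(r_idx - nodal_row) / max(int(taper_px), 1))

    def row_trace(r: int) -> np.ndarray:
        if sign[r] < 0:  # opposite phase: odd beats are the large ones
            return _flipped_parity_trace(
                template, intervals, n_frames, a_eff[r], int(first_stim_frame)
            )
        tr, _ = make_trace(
            template,
            intervals,
            n_frames,
            alternans_a=a_eff[r],
            start_frame=int(first_stim_frame),
        )
        return tr

    recording = _assemble_stack(
        row_trace, rows, cols, n_frames, noise_sd, seed, frame_interval_ms, None
    )
    stim0 = int(first_stim_frame) + np.arange(n_beats, dtype=int) * int(bcl_frames)
    gt = GroundTruth(
        stimulus_times=stim0,
        peak_times=stim0 + int(np.argmax(template)),
        amplitudes=np.full(n_beats, float(template.max())),
        rise_frames=int(np.argmax(template)),
        fall_frames=len(template) - 1 - int(np.argmax(template)),
        template_kind="ap_tent",
        alternans_a=float(a),
        noise_sd=float(noise_sd),
        alternans_sign=np.repeat(sign[:, None], cols, axis=1),
        nodal_row=int(nodal_row),
    )
    return recording, gt


def _flipped_parity_trace(
    template: np.ndarray,
    intervals: Sequence[int],
    n_frames: int,
    a: float,
    start_frame: int,
) -> np.ndarray:
    """Transient train where odd beats are the large ones (phase-flipped)."""
    stim = np.concatenate([[0], np.cumsum(list(intervals))]).astype(int) + start_frame
    trace = np.zeros(int(n_frames), dtype=float)
    scales = 1.0 - a * (-1.0) ** np.arange(len(stim))
    for k, s in enumerate(stim):
        trace[s : s + len(template)] += scales[k] * template
    return trace
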