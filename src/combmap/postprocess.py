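"""Postprocessing of feature maps: activation-map plots, conduction
velocity (point-to-point and local vector field) and alternans maps.

Local conduction velocity follows Bayly's construction: a second-order
bivariate polynomial ``T(x, y) = ax^2 + by^2 + cxy + dx + ey + f`` is
least-squares fitted to the activation times in a square window around
each pixel, the spatial gradient ``g`` of the fitted surface is evaluated
at the window center, and the velocity vector is ``v = g / (g . g)`` with
speed ``1 / |g|``.  On a planar wave the activation surface is linear and
the quadratic fit (hence the recovered velocity) is exact.

Alternans of any mapped feature is quantified from the average maps of
even and odd wave passes: ``large-to-small = max(e, o) / min(e, o)``,
``sMAPE = |e - o| / (e + o)`` and ``1 - min(e, o) / max(e, o)``.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Literal, Sequence

import matplotlib

matplotlib.use("Agg")  # headless: plots are written to files, never shown
import matplotlib.pyplot as plt
import numpy as np

__all__ = [
    "VelocityField",
    "AlternansMap",
    "AlternansMetric",
    "plot_activation_map",
    "cv_between_points",
    "bayly_local_cv",
    "alternans_map",
]

logger = logging.getLogger(__name__)

AlternansMetric = Literal["large_to_small", "smape", "one_minus_ratio"]


@dataclass
class VelocityField:
    """Local conduction-velocity vectors per pixel (units: mm/ms).

    ``valid`` is False where the window held fewer than six usable pixels
    (a quadratic surface has six coefficients) or the gradient magnitude
    was below tolerance; there ``vx``/``vy``/``speed`` are NaN.
    """

    vx: np.ndarray
    vy: np.ndarray
    speed: np.ndarray
    valid: np.ndarray


@dataclass
class AlternansMap:
    """Per-pixel alternans magnitude of one feature, plus the even/odd maps."""

    metric: AlternansMetric
    values: np.ndarray
    source_feature: str
    map_even: np.ndarray
    map_odd: np.ndarray


def plot_activation_map(
    act_map: np.ndarray,
    out_path: str | os.PathLike,
    isochrone_step_ms: float | None = None,
    title: str | None = None,
) -> None:
    """Render an activation map as filled contours with labeled isochrones.

    The map minimum is normalized to 0 ms before plotting.  With
    ``isochrone_step_ms`` given, contour levels are placed every that many
    ms; otherwise the plotting backend's default level placement is used.
    Writes a PNG (headless-safe).
    """
    act_map = np.asarray(act_map, dtype=float)
    if np.isnan(act_map).all():
        raise ValueError("activation map is entirely missing")
    shifted = act_map - np.nanmin(act_map)
    vmax = float(np.nanmax(shifted))
    levels = None
    if isochrone_step_ms is not None:
        if isochrone_step_ms <= 0:
            raise ValueError("isochrone_step_ms must be positive")
        n_levels = int(np.floor(vmax / isochrone_step_ms)) + 1
        levels = [k * isochrone_step_ms for k in range(max(n_levels, 2))]
    fig, ax = plt.subplots(figsize=(5, 4))
    try:
        if vmax <= 0:  # constant map: contouring would degenerate
            im = ax.imshow(shifted, origin="upper", cmap="jet")
            fig.colorbar(im, ax=ax, label="activation time (ms)")
        else:
            cf = ax.contourf(shifted, levels=levels, cmap="jet")
            cs = ax.contour(shifted, levels=cf.levels, colors="k", linewidths=0.6)
            ax.clabel(cs, fmt="%g")
            ax.invert_yaxis()
            fig.colorbar(cf, ax=ax, label="activation time (ms)")
        ax.set_xlabel("column (px)")
        ax.set_ylabel("row (px)")
        if title:
            ax.set_title(title)
        fig.savefig(out_path, dpi=120, bbox_inches="tight")
    finally:
        plt.close(fig)


def cv_between_points(
    act_map: np.ndarray,
    point_pairs: Sequence[tuple[tuple[int, int], tuple[int, int]]],
    pixel_pitch_mm: float,
    min_dt_ms: float = 1e-6,
) -> list[float]:
    """Conduction speed (mm/ms) between pairs of points of an activation map.

    Speed is the Euclidean pixel distance (scaled by the pixel pitch)
    divided by the absolute activation-time difference.  Pairs with a time
    difference below ``min_dt_ms`` yield NaN with a warning (the two sites
    activated simultaneously within resolution).
    """
    act_map = np.asarray(act_map, dtype=float)
    if pixel_pitch_mm <= 0:
        raise ValueError("pixel_pitch_mm must be positive")
    speeds: list[float] = []
    for (r1, c1), (r2, c2) in point_pairs:
        for r, c in ((r1, c1), (r2, c2)):
            if not (0 <= r < act_map.shape[0] and 0 <= c < act_map.shape[1]):
                raise ValueError(f"point ({r},{c}) outside map {act_map.shape}")
            if np.isnan(act_map[r, c]):
                raise ValueError(f"point ({r},{c}) has no activation time")
        dist_mm = pixel_pitch_mm * float(np.hypot(r2 - r1, c2 - c1))
        dt = abs(float(act_map[r2, c2] - act_map[r1, c1]))
        if dt < min_dt_ms:
            logger.warning(
                "points (%d,%d)-(%d,%d) activate simultaneously; CV undefined",
                r1, c1, r2, c2,
            )
            speeds.append(float("nan"))
        else:
            speeds.append(dist_mm / dt)
    return speeds


def bayly_local_cv(
    act_map: np.ndarray,
    window_radius_px: int = 3,
    pixel_pitch_mm: float = 1.0,
    min_gradient: float = 1e-9,
) -> VelocityField:
    """Local conduction-velocity field from an activation map (Bayly method).

    For every pixel, activation times in the ``(2w+1)^2`` window are fitted
    with a quadratic surface in physical coordinates (x along columns, y
    along rows, in mm); the velocity is the fitted gradient divided by its
    squared magnitude.  Pixels whose window holds fewer than six valid
    activation times, or whose gradient magnitude falls below
    ``min_gradient`` ms/mm (flat surface, undefined direction), are marked
    invalid.
    """
    act_map = np.asarray(act_map, dtype=float)
    if window_radius_px < 1:
        raise ValueError("window_radius_px must be >= 1")
    if pixel_pitch_mm <= 0:
        raise ValueError("pixel_pitch_mm must be positive")
    rows, cols = act_map.shape
    w = int(window_radius_px)
    vx = np.full((rows, cols), np.nan)
    vy = np.full((rows, cols), np.nan)
    # precompute local offsets of the full window
    dr, dc = np.mgrid[-w : w + 1, -w : w + 1]
    dr = dr.ravel()
    dc = dc.ravel()
    for r in range(rows):
        for c in range(cols):
            rr = r + dr
            cc = c + dc
            inb = (rr >= 0) & (rr < rows) & (cc >= 0) & (cc < cols)
            t = act_map[rr[inb], cc[inb]]
            ok = ~np.isnan(t)
            if ok.sum() < 6:
                continue
            x = dc[inb][ok] * pixel_pitch_mm
            y = dr[inb][ok] * pixel_pitch_mm
            tt = t[ok]
            design = np.column_stack(
                [x * x, y * y, x * y, x, y, np.ones_like(x)]
            )
            coeffs, *_ = np.linalg.lstsq(design, tt, rcond=None)
            gx, gy = coeffs[3], coeffs[4]  # gradient at the window center
            g2 = gx * gx + gy * gy
            if np.sqrt(g2) < min_gradient:
                continue
            vx[r, c] = gx / g2
            vy[r, c] = gy / g2
    speed = np.hypot(vx, vy)
    valid = ~np.isnan(speed)
    return VelocityField(vx=vx, vy=vy, speed=speed, valid=valid)


def alternans_map(
    per_beat: np.ndarray,
    metric: AlternansMetric = "smape",
    source_feature: str = "amplitude",
) -> AlternansMap:
    """Quantify beat-to-beat alternation of a feature per pixel.

    Maps of even wave passes (bin indices 0, 2, 4, ...) and odd passes are
    averaged separately; the pixel's alternans is then ``max/min`` of the
    two means (large-to-small), their symmetric relative difference
    ``|e-o|/(e+o)`` (sMAPE), or ``1 - min/max``.  All three assume a
    positive-valued feature (amplitude, duration): where a mean is
    non-positive or fewer than one even and one odd beat were measured,
    the pixel is NaN.  The metrics are invariant to which parity is
    labeled "even" — dropping the first beat changes nothing.
    """
    per_beat = np.asarray(per_beat, dtype=float)
    if per_beat.ndim != 3:
        raise ValueError("per_beat must be rows x cols x bins")
    if per_beat.shape[2] < 2:
        raise ValueError("alternans needs at least 2 beats")
    if metric not in ("large_to_small", "smape", "one_minus_ratio"):
        raise ValueError(f"unknown alternans metric {metric!r}")
    from .recording import _nanmean

    e = _nanmean(per_beat[:, :, 0::2], axis=2)
    o = _nanmean(per_beat[:, :, 1::2], axis=2)
    with np.errstate(invalid="ignore"):
        lo = np.minimum(e, o)
        hi = np.maximum(e, o)
        defined = ~np.isnan(lo)
        nonpos = defined & ((lo <= 0) | ((e + o) <= 0))
        if nonpos.any():
            logger.warning(
                "alternans metric undefined for %d pixels with non-positive "
                "feature values", int(nonpos.sum()),
            )
        usable = defined & ~nonpos
        values = np.full(e.shape, np.nan)
        if metric == "large_to_small":
            values[usable] = hi[usable] / lo[usable]
        elif metric == "smape":
            values[usable] = np.abs(e - o)[usable] / (e + o)[usable]
        else:
            values[usable] = 1.0 - lo[usable] / hi[usable]
    return AlternansMap(
        metric=metric,
        values=values,
        source_feature=source_feature,
        map_even=e,
        map_odd=o,
    )
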