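"""Trajectory smoothing and finite-difference kinematics.

Displacement is smoothed with a 3-pass 4th-order Savitzky-Golay filter
(uniform weights, 143-frame span at the 250 Hz working frame rate);
velocity and acceleration come from first- and second-order central
differences of the smoothed displacement and get one further filter pass.
150 leading and 100 trailing frames are then dropped to kill edge effects.
All counts are configuration parameters with those defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "TrialMeta",
    "MarkerTrackSet",
    "SmoothedKinematicsSet",
    "SmoothConfig",
    "sgolay_smooth",
    "central_difference",
    "smooth_trial",
]


@dataclass
class TrialMeta:
    """Per-trial annotations carried alongside the coordinate arrays."""

    trial_id: str
    individual_id: str = ""
    sex: str = ""
    age_class: str = ""
    temperature_C: float = float("nan")
    handedness: str = ""


@dataclass
class MarkerTrackSet:
    """Digitized x,y,z positions: (n_frames, n_markers, 3), cm."""

    positions: np.ndarray
    frame_rate_hz: float
    meta: TrialMeta

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n_markers, 3)")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be > 0")
        if not np.isfinite(self.positions).all():
            raise ValueError("positions contain missing/non-finite values")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_markers(self) -> int:
        return self.positions.shape[1]


@dataclass
class SmoothedKinematicsSet:
    """Smoothed displacement/velocity/acceleration on the retained window."""

    displacement: np.ndarray   # (n_kept, n_markers, 3) cm
    velocity: np.ndarray       # cm/s
    acceleration: np.ndarray   # cm/s^2
    frame_rate_hz: float
    retained_range: tuple[int, int]   # [start, stop) in original frame index
    meta: TrialMeta

    def __post_init__(self) -> None:
        if not (self.displacement.shape == self.velocity.shape
                == self.acceleration.shape):
            raise ValueError("displacement/velocity/acceleration shapes differ")

    @property
    def times_s(self) -> np.ndarray:
        start, stop = self.retained_range
        return np.arange(start, stop) / self.frame_rate_hz


@dataclass(frozen=True)
class SmoothConfig:
    order: int = 4
    span: int = 143
    passes_displacement: int = 3
    passes_derivative: int = 1
    trim_head: int = 150
    trim_tail: int = 100
    frame_rate_hz: float = 250.0


def displacement_filter_gain(freq_hz: np.ndarray,
                             cfg: SmoothConfig = SmoothConfig()) -> np.ndarray:
    """Amplitude gain of the displacement smoothing at a temporal frequency.

    The multi-pass Savitzky-Golay filter is linear and zero-phase; its gain
    is the window's cosine transform raised to the number of passes.  Used
    to reason about which wave harmonics the pre-processing resolves.
    """
    from scipy.signal import savgol_coeffs

    c = savgol_coeffs(cfg.span, cfg.order)
    half = (cfg.span - 1) // 2
    j = np.arange(-half, half + 1)
    w = 2.0 * np.pi * np.atleast_1d(np.asarray(freq_hz, float)) / cfg.frame_rate_hz
    H = (c[::-1][None, :] * np.cos(w[:, None] * j[None, :])).sum(axis=1)
    return H ** cfg.passes_displacement


def sgolay_smooth(x: np.ndarray, order: int = 4, span: int = 143,
                  passes: int = 1) -> np.ndarray:
    """Apply the Savitzky-Golay local-polynomial filter ``passes`` times.

    Edge frames use a polynomial fit on the truncated window (they are
    discarded by trimming downstream anyway).  Polynomials of degree
    <= ``order`` are fixed points of the filter in the interior.
    """
    x = np.asarray(x, dtype=float)
    if span % 2 != 1:
        raise ValueError("span must be odd")
    if span <= order:
        raise ValueError("span must exceed the polynomial order")
    if x.shape[-1] < span:
        raise ValueError(
            "series of length %d is shorter than the filter span; at least "
            "%d samples are required" % (x.shape[-1], span)
        )
    for _ in range(passes):
        x = savgol_filter(x, span, order, axis=-1, mode="interp")
    return x


def central_difference(x: np.ndarray, dt: float, order: int = 1) -> np.ndarray:
    """First/second derivative via central differences (length-preserving).

    Endpoints fall back to one-sided differences of the same derivative
    order.
    """
    x = np.asarray(x, dtype=float)
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if x.shape[-1] < 3:
        raise ValueError("need at least 3 samples")
    d = np.empty_like(x)
    if order == 1:
        d[..., 1:-1] = (x[..., 2:] - x[..., :-2]) / (2.0 * dt)
        d[..., 0] = (x[..., 1] - x[..., 0]) / dt
        d[..., -1] = (x[..., -1] - x[..., -2]) / dt
    elif order == 2:
        d[..., 1:-1] = (x[..., 2:] - 2.0 * x[..., 1:-1] + x[..., :-2]) / dt ** 2
        d[..., 0] = (x[..., 2] - 2.0 * x[..., 1] + x[..., 0]) / dt ** 2
        d[..., -1] = (x[..., -1] - 2.0 * x[..., -2] + x[..., -3]) / dt ** 2
    else:
        raise ValueError("order must be 1 or 2")
    return d


def smooth_trial(tracks: MarkerTrackSet,
                 cfg: SmoothConfig = SmoothConfig()) -> SmoothedKinematicsSet:
    """Full pre-processing of one trial.

    Per marker and coordinate: multi-pass SG on displacement, central
    differences, single-pass SG on velocity and acceleration, then drop
    ``trim_head`` leading and ``trim_tail`` trailing frames from all three
    arrays.
    """
    n = tracks.n_frames
    trim = cfg.trim_head + cfg.trim_tail
    if n <= trim + cfg.span:
        raise ValueError(
            "trial has %d frames; need more than trim (%d+%d) + span (%d) = %d"
            % (n, cfg.trim_head, cfg.trim_tail, cfg.span, trim + cfg.span)
        )
    dt = 1.0 / tracks.frame_rate_hz
    # work with time on the last axis: (n_markers, 3, n_frames)
    x = np.moveaxis(tracks.positions, 0, -1)
    disp = sgolay_smooth(x, cfg.order, cfg.span, cfg.passes_displacement)
    vel = central_difference(disp, dt, order=1)
    acc = central_difference(disp, dt, order=2)
    vel = sgolay_smooth(vel, cfg.order, cfg.span, cfg.passes_derivative)
    acc = sgolay_smooth(acc, cfg.order, cfg.span, cfg.passes_derivative)

    sl = slice(cfg.trim_head, n - cfg.trim_tail)
    back = lambda a: np.moveaxis(a, -1, 0)[sl]
    return SmoothedKinematicsSet(
        displacement=back(disp),
        velocity=back(vel),
        acceleration=back(acc),
        frame_rate_hz=tracks.frame_rate_hz,
        retained_range=(cfg.trim_head, n - cfg.trim_tail),
        meta=tracks.meta,
    )
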