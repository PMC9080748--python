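"""Extraction of per-trial sidewinding kinematics from smoothed trajectories.

Eleven per-trial variables are computed: whole-animal (marker-centroid)
mean/peak speed and acceleration; mean of the mid-body markers' peak speeds;
mean height lifted; and the waveform quantities frequency, wavelength,
peak-to-peak amplitude and signed skew angle, plus the trial handedness.

Waveform geometry follows the extrema-triangle construction: a marker is at
a wave extremum when the planar angle it forms with its two neighbours is at
a temporal minimum; extrema of the same identity are chained across markers
and linearly interpolated in time; at every frame with two same-type extrema
bracketing an opposite one, wavelength is the distance between the same-type
pair, the skew angle is the signed tilt of the triangle's median from the
perpendicular of that base line, and amplitude is the median length times
the cosine of the skew.  Trial values average over all frames and triples
where the construction exists; trials too short for a complete triple yield
missing values, never fabricated ones.

Geometry is computed on the x-y (track-plane) projection; z is used only
for height lifted.  The travel direction is the direction of net centroid
displacement.  Because the extrema labelling is chiral, the raw skew sign is
only correct for right-handed trials; :func:`apply_handedness_sign` flips
left-handed trials so that positive always means head-wards tilt.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .smoothing import SmoothedKinematicsSet

__all__ = [
    "ExtremumEvent",
    "ExtremumTrack",
    "TrialKinematics",
    "KinextractConfig",
    "PEAK_SPEED_BAND",
    "HEIGHT_BAND",
    "WAVE_BAND",
    "centroid_kinematics",
    "marker_summaries",
    "zscore_select",
    "detect_extrema",
    "interpolate_extrema",
    "wave_geometry",
    "cycle_frequency",
    "apply_handedness_sign",
    "travel_direction",
    "extract_trial_kinematics",
]

#: 1-based marker bands that sit closest to the trial mean (z-score screen).
PEAK_SPEED_BAND = (3, 7)
HEIGHT_BAND = (2, 8)
#: Band used for waveform extrema (head/neck and tail tip move erratically).
WAVE_BAND = (4, 9)


@dataclass(frozen=True)
class ExtremumEvent:
    """One marker passing through a wave extremum."""

    marker: int          # 1-based marker number
    time_s: float
    position: np.ndarray  # (3,) cm
    kind: str            # 'crest' or 'trough' (chiral label)


@dataclass
class ExtremumTrack:
    """A single wave extremum followed across markers and time."""

    kind: str
    times: np.ndarray      # strictly increasing
    positions: np.ndarray  # (n_events, 3)

    def at(self, t: np.ndarray) -> np.ndarray:
        """Linearly interpolated position; NaN outside the tracked window."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.empty((t.size, 3))
        for j in range(3):
            out[:, j] = np.interp(t, self.times, self.positions[:, j])
        out[(t < self.times[0]) | (t > self.times[-1])] = np.nan
        return out


@dataclass
class TrialKinematics:
    """The per-trial kinematic variables (NaN marks a missing value)."""

    centroid_mean_speed: float = np.nan    # cm/s
    centroid_peak_speed: float = np.nan
    centroid_mean_accel: float = np.nan    # cm/s^2
    centroid_peak_accel: float = np.nan
    marker_peak_speed_mean: float = np.nan  # cm/s, band 3-7
    height_lifted_mean: float = np.nan      # cm, band 2-8
    frequency_hz: float = np.nan
    wavelength_cm: float = np.nan
    amplitude_cm: float = np.nan            # peak-to-peak
    skew_deg: float = np.nan                # signed, head-wards positive
    handedness: str = ""

    FIELDS = (
        "centroid_mean_speed", "centroid_peak_speed", "centroid_mean_accel",
        "centroid_peak_accel", "marker_peak_speed_mean", "height_lifted_mean",
        "frequency_hz", "wavelength_cm", "amplitude_cm", "skew_deg",
        "handedness",
    )


@dataclass(frozen=True)
class KinextractConfig:
    peak_speed_band: tuple[int, int] = PEAK_SPEED_BAND
    height_band: tuple[int, int] = HEIGHT_BAND
    wave_band: tuple[int, int] = WAVE_BAND
    #: minimum prominence (deg) of a temporal angle minimum to count as an
    #: extremum passage; suppresses noise-induced minima
    prominence_deg: float = 5.0
    #: angle minima flatter than this are treated as collinear (no event)
    max_angle_deg: float = 170.0


# ---------------------------------------------------------------------------
# whole-animal and per-marker summaries
# ---------------------------------------------------------------------------

def centroid_kinematics(k: SmoothedKinematicsSet):
    """Mean/peak speed and acceleration of the marker centroid.

    The centroid displacement is the mean of the smoothed marker positions;
    its velocity and acceleration come from first/second-order central
    differences, and speed is the norm of the velocity vector.
    """
    from .smoothing import central_difference

    if not np.isfinite(k.displacement).all():
        raise ValueError("centroid requires all markers present at all frames")
    dt = 1.0 / k.frame_rate_hz
    centroid = k.displacement.mean(axis=1)            # (n_t, 3)
    vel = central_difference(centroid.T, dt, order=1).T
    acc = central_difference(centroid.T, dt, order=2).T
    speed = np.linalg.norm(vel, axis=1)
    accel = np.linalg.norm(acc, axis=1)
    return (float(speed.mean()), float(speed.max()),
            float(accel.mean()), float(accel.max()))


def marker_summaries(k: SmoothedKinematicsSet):
    """Per-marker peak speed and max height above its own trial minimum z."""
    if k.displacement.shape[0] == 0:
        raise ValueError("empty retained window")
    speed = np.linalg.norm(k.velocity, axis=2)        # (n_t, n_m)
    peak_speed = speed.max(axis=0)
    z = k.displacement[:, :, 2]
    max_height = z.max(axis=0) - z.min(axis=0)
    return peak_speed, max_height


def zscore_select(values: np.ndarray,
                  candidate_range: tuple[int, int] = (1, 10),
                  use_paper_bands: str | None = None,
                  tol_z: float = 0.05) -> tuple[int, int]:
    """Pick the contiguous marker band most consistently near the trial mean.

    ``values`` is (n_trials, n_markers).  Within each trial the values are
    replaced by z-scores across markers; each marker is scored by its mean
    |z| across trials; the returned band (1-based, inclusive) minimises the
    mean score over contiguous bands inside ``candidate_range``.  Among
    bands whose mean score lies within ``tol_z`` of the optimum the longest
    is preferred (sampling noise should not shrink the band to a single
    lucky marker).  ``use_paper_bands`` short-circuits to the fixed bands:
    ``"peak_speed"`` -> markers 3-7, ``"height"`` -> markers 2-8.
    """
    if use_paper_bands is not None:
        return {"peak_speed": PEAK_SPEED_BAND, "height": HEIGHT_BAND}[
            use_paper_bands]
    v = np.asarray(values, dtype=float)
    if v.ndim != 2 or v.shape[0] < 1 or v.shape[1] < 2:
        raise ValueError("need a (n_trials>=1, n_markers>=2) matrix")
    mu = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, ddof=0, keepdims=True)
    z = np.zeros_like(v)
    ok = (sd > 0).ravel()
    if not ok.all():
        warnings.warn("trial(s) with zero across-marker sd: z-scores set to 0")
    z[ok] = (v[ok] - mu[ok]) / sd[ok]
    score = np.abs(z).mean(axis=0)                    # per marker

    lo, hi = candidate_range
    bands = [(score[a - 1:b].mean(), a, b)
             for a in range(lo, hi + 1) for b in range(a, hi + 1)]
    best_mean = min(m for m, _, _ in bands)
    near = [(a, b) for m, a, b in bands if m <= best_mean + tol_z]
    return max(near, key=lambda ab: (ab[1] - ab[0], -ab[0]))


# ---------------------------------------------------------------------------
# waveform extrema
# ---------------------------------------------------------------------------

def travel_direction(k: SmoothedKinematicsSet) -> np.ndarray:
    """Unit planar travel direction = net centroid displacement."""
    centroid = k.displacement.mean(axis=1)[:, :2]
    v = centroid[-1] - centroid[0]
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("no net displacement: travel direction undefined")
    return v / norm


def detect_extrema(k: SmoothedKinematicsSet,
                   band: tuple[int, int] = WAVE_BAND,
                   prominence_deg: float = 5.0,
                   max_angle_deg: float = 170.0) -> list[ExtremumEvent]:
    """Extremum passages: temporal minima of the three-point planar angle.

    For each interior marker m of the band, the angle at m formed by
    (m-1, m, m+1) is computed per frame; local minima (with the configured
    prominence) mark the instants the marker sits on a wave crest or trough.
    The chiral kind label comes from the sign of the planar cross product of
    the two segments in head-to-tail marker order.
    """
    lo, hi = band
    if hi - lo + 1 < 3:
        raise ValueError("band must contain at least 3 consecutive markers")
    P = k.displacement
    t = k.times_s
    events: list[ExtremumEvent] = []
    for m in range(lo + 1, hi):            # interior markers, 1-based
        a = P[:, m - 2, :2]                # m-1
        b = P[:, m - 1, :2]                # m
        c = P[:, m, :2]                    # m+1
        u = a - b
        v = c - b
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = np.einsum("ij,ij->i", u, v) / (nu * nv)
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        idx, _ = find_peaks(-ang, prominence=prominence_deg)
        idx = idx[ang[idx] < max_angle_deg]
        cross = (b - a)[:, 0] * (c - b)[:, 1] - (b - a)[:, 1] * (c - b)[:, 0]
        for i in idx:
            kind = "crest" if cross[i] > 0 else "trough"
            events.append(ExtremumEvent(
                marker=m, time_s=float(t[i]),
                position=P[i, m - 1].copy(), kind=kind,
            ))
    return events


def _median_period(events: Sequence[ExtremumEvent]) -> float:
    gaps = []
    keys = {(e.marker, e.kind) for e in events}
    for key in keys:
        ts = sorted(e.time_s for e in events
                    if (e.marker, e.kind) == key)
        gaps.extend(np.diff(ts))
    return float(np.median(gaps)) if gaps else np.inf


def interpolate_extrema(events: Sequence[ExtremumEvent],
                        max_lag_periods: float = 0.75) -> list[ExtremumTrack]:
    """Chain same-identity extrema across markers into continuous tracks.

    Chaining heuristic (nearest-in-phase): markers are processed head to
    tail; an event joins the open chain of its kind whose most recent event
    came from a more head-ward marker within ``max_lag_periods`` wave
    periods, preferring the closest in time.  Chains with fewer than two
    events cannot be interpolated and are dropped with a warning.
    """
    tracks: list[ExtremumTrack] = []
    n_dropped = 0
    for kind in ("crest", "trough"):
        evs = [e for e in events if e.kind == kind]
        if not evs:
            continue
        T = _median_period(evs)
        max_lag = max_lag_periods * T
        chains: list[list[ExtremumEvent]] = []
        for e in sorted(evs, key=lambda e: (e.marker, e.time_s)):
            best = None
            for ch in chains:
                last = ch[-1]
                if last.marker >= e.marker:
                    continue
                lag = e.time_s - last.time_s
                gap = e.marker - last.marker
                if 0 < lag <= max_lag * gap:
                    if best is None or lag < best[0]:
                        best = (lag, ch)
            if best is None:
                chains.append([e])
            else:
                best[1].append(e)
        for ch in chains:
            if len(ch) < 2:
                n_dropped += 1
                continue
            ch.sort(key=lambda e: e.time_s)
            tracks.append(ExtremumTrack(
                kind=kind,
                times=np.array([e.time_s for e in ch]),
                positions=np.vstack([e.position for e in ch]),
            ))
    if n_dropped:
        warnings.warn(f"{n_dropped} unchainable single extremum event(s) dropped")
    return tracks


def wave_geometry(tracks: Sequence[ExtremumTrack],
                  times: np.ndarray,
                  travel: np.ndarray):
    """Trial wavelength, peak-to-peak amplitude and raw signed skew angle.

    At each time, interpolated extremum positions are ordered along the
    body-wave axis (the perpendicular of ``travel``); every consecutive
    triple (same kind, opposite kind, same kind) contributes one estimate:
    wavelength = planar distance between the same-kind pair; the median runs
    from that base's midpoint to the middle extremum; skew is the signed
    angle between median and base-perpendicular (chiral sign, right-handed
    convention); amplitude = |median| * cos(skew).  Returns the means over
    all frames and triples, or NaNs when no complete triple exists.
    """
    if len(tracks) < 3:
        return np.nan, np.nan, np.nan, 0
    d_hat = np.array([travel[1], -travel[0]])         # right of travel
    times = np.asarray(times, dtype=float)
    interp = [tr.at(times)[:, :2] for tr in tracks]   # list of (n_t, 2)
    kinds = [tr.kind for tr in tracks]

    wls, amps, skews = [], [], []
    for i, t in enumerate(times):
        pos = np.array([p[i] for p in interp])
        alive = ~np.isnan(pos[:, 0])
        if alive.sum() < 3:
            continue
        pos_a = pos[alive]
        kind_a = [kk for kk, al in zip(kinds, alive) if al]
        order = np.argsort(pos_a @ d_hat)
        pos_a = pos_a[order]
        kind_a = [kind_a[j] for j in order]
        for j in range(len(kind_a) - 2):
            k1, k2, k3 = kind_a[j], kind_a[j + 1], kind_a[j + 2]
            if k1 != k3 or k2 == k1:
                continue
            p1, q, p2 = pos_a[j], pos_a[j + 1], pos_a[j + 2]
            base = p2 - p1
            bl = np.linalg.norm(base)
            if bl == 0:
                continue
            b_hat = base / bl
            if b_hat @ d_hat < 0:
                b_hat = -b_hat
            M = q - 0.5 * (p1 + p2)
            along = M @ b_hat
            perp = abs(M[0] * b_hat[1] - M[1] * b_hat[0])
            if perp == 0 and along == 0:
                continue
            # sign convention: the raw skew is signed as if the trial were
            # right-handed (head-wards = positive); the apex side relative
            # to the travel direction disambiguates the median direction
            side = M @ travel
            if side == 0:
                continue
            s = 1.0 if side > 0 else -1.0
            skew = s * np.degrees(np.arctan2(along, perp))
            amp = np.linalg.norm(M) * np.cos(np.radians(skew))
            wls.append(bl)
            amps.append(amp)
            skews.append(skew)
    if not wls:
        return np.nan, np.nan, np.nan, 0
    return (float(np.mean(wls)), float(np.mean(amps)),
            float(np.mean(skews)), len(wls))


def cycle_frequency(events: Sequence[ExtremumEvent]) -> float:
    """Reciprocal of the median wave period.

    Periods are the gaps between successive same-kind extremum passages of
    each marker, pooled across markers and kinds.
    """
    T = _median_period(events)
    return 1.0 / T if np.isfinite(T) and T > 0 else np.nan


def apply_handedness_sign(skew_deg: float, handedness: str) -> float:
    """Make positive skew mean head-wards tilt regardless of handedness.

    The chiral extraction convention is correct for right-handed trials;
    left-handed trials have their sign flipped.
    """
    if handedness == "right":
        return skew_deg
    if handedness == "left":
        return -skew_deg
    raise ValueError(
        f"handedness must be annotated 'left' or 'right', got {handedness!r}"
    )


# ---------------------------------------------------------------------------
# per-trial driver
# ---------------------------------------------------------------------------

def _band_slice(band: tuple[int, int]) -> slice:
    return slice(band[0] - 1, band[1])


def extract_trial_kinematics(
    k: SmoothedKinematicsSet,
    cfg: KinextractConfig = KinextractConfig(),
) -> TrialKinematics:
    """Compute all per-trial kinematic variables from smoothed data."""
    out = TrialKinematics(handedness=k.meta.handedness)
    (out.centroid_mean_speed, out.centroid_peak_speed,
     out.centroid_mean_accel, out.centroid_peak_accel) = centroid_kinematics(k)
    peak_speed, max_height = marker_summaries(k)
    out.marker_peak_speed_mean = float(
        peak_speed[_band_slice(cfg.peak_speed_band)].mean())
    out.height_lifted_mean = float(
        max_height[_band_slice(cfg.height_band)].mean())

    events = detect_extrema(k, cfg.wave_band, cfg.prominence_deg,
                            cfg.max_angle_deg)
    out.frequency_hz = cycle_frequency(events)
    tracks = interpolate_extrema(events)
    travel = travel_direction(k)
    wl, amp, skew, _n = wave_geometry(tracks, k.times_s, travel)
    out.wavelength_cm = wl
    out.amplitude_cm = amp
    if np.isfinite(skew) and k.meta.handedness:
        out.skew_deg = apply_handedness_sign(skew, k.meta.handedness)
    else:
        out.skew_deg = skew
    return out
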