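"""Synthetic sidewinding trajectories and morphometrics with known ground truth.

Sidewinding is modelled as a shape-invariant planar travelling wave with
static ground-contact sections.  The body's lateral profile is a corner-
smoothed skewed triangle wave ``g(xi)`` over the body-axis coordinate ``xi``
(cm); a body point with coordinate ``s`` sits, at time ``t``, at phase
``xi = s + c*t`` with wave speed ``c = f * lambda``.  The contact section is
a straight sub-segment of the trough-to-crest leg; requiring those material
points to be exactly stationary in the ground frame forces the whole wave
pattern to translate rigidly anti-parallel to that leg, which makes the net
displacement per cycle exactly perpendicular to the wave axis with

    stride = lambda * (contact-leg slope).

Coordinates: x-y is the ground plane, z is up, net travel is +y, and the
body wave extends along x.  For a right-handed trial the trunk lies at
positive x of the head; a left-handed trial is the exact mirror image
(x -> -x) of the right-handed one.

Two analytic corrections make the *measured* wave parameters (from the
smoothed template's extrema) equal the nominal ones: corner smoothing of
half-width ``w`` lowers the peak-to-peak by ``2*w*A/lambda`` (so the raw
triangle amplitude is inflated by ``1/(1 - 2w/lambda)``) and shifts the
crest and trough apices in opposite directions, shrinking their relative
skew offset by ``(1 - 4w/lambda)`` (so the crest is constructed at
``lambda/2 + A*tan(skew)/(1 - 4w/lambda)``).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .smoothing import (MarkerTrackSet, SmoothConfig, TrialMeta,
                        displacement_filter_gain)

__all__ = [
    "WaveParams",
    "TrialGroundTruth",
    "TraitGen",
    "MorphoGenConfig",
    "MORPHO_COLUMNS",
    "generate_trajectory",
    "generate_morphometrics",
    "write_fixture_set",
    "wave_template",
    "default_marker_arclengths",
]

#: Columns of the morphometrics table, in writing order.
MORPHO_COLUMNS = [
    "id", "sex", "age_class", "svl_cm", "mass_g", "tail_cm",
    "width25_cm", "width50_cm", "width75_cm", "neck_width_cm",
    "head_width_cm", "head_length_cm",
    "ventral_count", "subcaudal_count", "dorsal_rows",
]


@dataclass(frozen=True)
class WaveParams:
    """Ground-truth sidewinding wave parameters (cm, s, degrees).

    ``skew_deg`` is the signed tilt of the wave median, positive head-wards.
    ``duty`` is the fraction of a cycle a body section spends in static
    ground contact.  ``smooth_frac`` is the corner-smoothing half-width of
    the triangle template as a fraction of the wavelength; extrema-angle
    detection needs the non-degenerate curvature it provides.
    """

    frequency_hz: float
    wavelength_cm: float
    amplitude_cm: float
    skew_deg: float
    lift_height_cm: float
    duty: float
    handedness: str = "right"
    smooth_frac: float = 0.06

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0:
            raise ValueError("frequency_hz must be > 0")
        if self.wavelength_cm <= 0:
            raise ValueError("wavelength_cm must be > 0")
        if self.amplitude_cm <= 0:
            raise ValueError("amplitude_cm must be > 0")
        if not -90.0 < self.skew_deg < 90.0:
            raise ValueError("skew_deg must lie in (-90, 90)")
        if self.lift_height_cm < 0:
            raise ValueError("lift_height_cm must be >= 0")
        if not 0.0 < self.duty < 1.0:
            raise ValueError("duty must lie in (0, 1)")
        if self.handedness not in ("left", "right"):
            raise ValueError("handedness must be 'left' or 'right'")
        if not 0.0 < self.smooth_frac < 0.25:
            raise ValueError("smooth_frac must lie in (0, 0.25)")
        # geometric feasibility of the skewed template and contact section
        lam = self.wavelength_cm
        w = self.smooth_frac * lam
        xi_c = self.crest_position_cm
        if not (2 * w < xi_c < lam - 2 * w):
            raise ValueError(
                "infeasible wave: crest position %.3f cm must leave straight "
                "legs on both sides (need 2w=%.3f < xi_c < %.3f)"
                % (xi_c, 2 * w, lam - 2 * w)
            )
        if self.duty * lam > xi_c - 2 * w:
            raise ValueError(
                "duty %.3f does not fit the straight contact leg: need "
                "duty <= %.3f for this wavelength/amplitude/skew"
                % (self.duty, (xi_c - 2 * w) / lam)
            )

    # -- derived template geometry ---------------------------------------
    @property
    def corner_halfwidth_cm(self) -> float:
        return self.smooth_frac * self.wavelength_cm

    @property
    def raw_amplitude_cm(self) -> float:
        """Triangle peak-to-peak before corner smoothing eats 2wA/lambda."""
        return self.amplitude_cm / (1.0 - 2.0 * self.smooth_frac)

    @property
    def crest_position_cm(self) -> float:
        """Crest phase xi_c; troughs sit at multiples of the wavelength."""
        lam = self.wavelength_cm
        shear = math.tan(math.radians(self.skew_deg))
        return lam / 2.0 + self.amplitude_cm * shear / (1.0 - 4.0 * self.smooth_frac)

    @property
    def contact_slope(self) -> float:
        """Slope of the straight trough-to-crest (contact) leg."""
        return self.raw_amplitude_cm / self.crest_position_cm

    @property
    def stride_cm(self) -> float:
        """Displacement per cycle along the travel direction (derived)."""
        return self.wavelength_cm * self.contact_slope

    @property
    def speed_cm_s(self) -> float:
        return self.frequency_hz * self.stride_cm


def default_marker_arclengths(
    wavelength_cm: float, span_wavelengths: float = 3.2, n_markers: int = 10
) -> np.ndarray:
    """Body-axis coordinates of the markers, head first (decreasing).

    Mirrors the 10-marker painting scheme: head, neck, trunk markers 3-8
    approximately evenly spaced, cloaca (marker 9) on the same even grid,
    tail tip.  Markers 3-9 being evenly spaced gives the extrema detector a
    single inter-marker spacing.  The body spans ``span_wavelengths``
    wavelengths along the wave axis so that the mid-body marker band covers
    more than one full wavelength (a prerequisite for extrema triples).
    """
    if n_markers != 10:
        # uniform fallback for non-standard marker counts
        L = span_wavelengths * wavelength_cm
        return np.linspace(L, 0.0, n_markers)
    frac = np.empty(10)
    frac[0] = 0.0
    frac[1] = 0.06
    frac[2:9] = np.linspace(0.12, 0.85, 7)   # markers 3..9 evenly spaced
    frac[9] = 1.0
    L = span_wavelengths * wavelength_cm
    return (1.0 - frac) * L  # head at s=L, tail tip at s=0


@dataclass
class TrialGroundTruth:
    """Everything needed to generate (and score recovery of) one trial."""

    wave: WaveParams
    frame_rate_hz: float = 250.0
    n_frames: int = 2500
    noise_sd_cm: float = 0.0
    seed: int = 0
    n_markers: int = 10
    marker_arclengths: np.ndarray | None = None
    min_cycles: float = 3.0
    edge_trim_frames: int = 250  # head+tail frames the smoothing stage drops
    #: calibrate the swing-section shape so the three-point extrema detector
    #: is unbiased at this trial's marker spacing (see CalibratedTemplate);
    #: the calibration accounts for the smoothing filter the pipeline will
    #: apply (smoothing_assumed), while the generated trajectory itself is
    #: always the pure unfiltered waveform
    detector_calibration: bool = True
    smoothing_assumed: SmoothConfig | None = field(default_factory=SmoothConfig)
    stride_cm: float = field(init=False)
    centroid_speed_cm_s: float = field(init=False)

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be > 0")
        if self.noise_sd_cm < 0:
            raise ValueError("noise_sd_cm must be >= 0")
        if self.marker_arclengths is None:
            self.marker_arclengths = default_marker_arclengths(
                self.wave.wavelength_cm, n_markers=self.n_markers
            )
        self.marker_arclengths = np.asarray(self.marker_arclengths, dtype=float)
        if self.marker_arclengths.shape != (self.n_markers,):
            raise ValueError("marker_arclengths must have n_markers entries")
        usable_s = (self.n_frames - self.edge_trim_frames) / self.frame_rate_hz
        need_s = self.min_cycles / self.wave.frequency_hz
        if usable_s < need_s:
            raise ValueError(
                "n_frames too small: %d frames leave %.2f s after the %d-frame "
                "edge trim but %.1f cycles at %.2f Hz need %.2f s"
                % (self.n_frames, usable_s, self.edge_trim_frames,
                   self.min_cycles, self.wave.frequency_hz, need_s)
            )
        self.stride_cm = self.wave.stride_cm
        self.centroid_speed_cm_s = self.wave.speed_cm_s

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["wave"] = asdict(self.wave)
        d["marker_arclengths"] = list(map(float, self.marker_arclengths))
        return d


# ---------------------------------------------------------------------------
# wave template
# ---------------------------------------------------------------------------

def contact_interval(wave: WaveParams) -> tuple[float, float]:
    """Phase interval [c0, c1] of static ground contact, centred in the
    straight part of the trough-to-crest leg."""
    lam = wave.wavelength_cm
    w = wave.corner_halfwidth_cm
    xi_c = wave.crest_position_cm
    c0 = w + ((xi_c - 2 * w) - wave.duty * lam) / 2.0
    return c0, c0 + wave.duty * lam


def wave_template(wave: WaveParams, xi: np.ndarray) -> np.ndarray:
    """Lateral profile g(xi) of the corner-smoothed skewed triangle wave.

    Piecewise: straight legs joined by quadratic blends of half-width ``w``
    at the trough (xi=0 mod lambda) and crest (xi=xi_c) corners, giving a
    C1 waveform whose measured peak-to-peak equals ``amplitude_cm`` and
    whose extrema skew equals ``skew_deg``.  The up-leg segments outside
    the contact interval carry a small C1 inward dip ("detune") so that
    only body sections inside the contact interval are instantaneously
    stationary -- the static fraction of a cycle then equals ``duty``
    rather than the whole straight-leg fraction.
    """
    lam = wave.wavelength_cm
    w = wave.corner_halfwidth_cm
    A = wave.raw_amplitude_cm
    xi_c = wave.crest_position_cm
    m1 = A / xi_c                 # up-leg slope (contact leg)
    m2 = -A / (lam - xi_c)        # down-leg slope

    phi = np.mod(xi, lam)
    g = np.empty_like(phi)

    def blend(x, corner_val, m_in, m_out):
        # x in [-w, w] around the corner; C1 quadratic joining the legs
        return (corner_val - m_in * w) + m_in * (x + w) \
            + (m_out - m_in) * (x + w) ** 2 / (4.0 * w)

    # regions (phi wrapped to [0, lam))
    near_trough = (phi < w) | (phi >= lam - w)
    up = (phi >= w) & (phi < xi_c - w)
    near_crest = (phi >= xi_c - w) & (phi < xi_c + w)
    down = (phi >= xi_c + w) & (phi < lam - w)

    x_t = np.where(phi < w, phi, phi - lam)  # signed offset from trough corner
    g[near_trough] = blend(x_t[near_trough], -A / 2.0, m2, m1)
    g[up] = -A / 2.0 + m1 * phi[up]
    g[near_crest] = blend(phi[near_crest] - xi_c, A / 2.0, m1, m2)
    g[down] = A / 2.0 + m2 * (phi[down] - xi_c)

    # detune the up-leg connectors outside the contact interval
    c0, c1 = contact_interval(wave)
    amp = -0.04 * wave.amplitude_cm
    for lo, hi in ((w, c0), (c1, xi_c - w)):
        half = (hi - lo) / 2.0
        if half <= 1e-9:
            continue
        u = (phi - (lo + half)) / half
        m = np.abs(u) < 1.0
        g[m] += amp * (1.0 - u[m] ** 2) ** 2
    return g


def _odd_bump(x: np.ndarray, center: float, halfwidth: float,
              lam: float) -> np.ndarray:
    """Antisymmetric C1 bump u*(1-u^2)^2 of compact support, period lam."""
    u = (np.mod(x - center + lam / 2.0, lam) - lam / 2.0) / halfwidth
    out = np.zeros_like(u)
    m = np.abs(u) < 1.0
    out[m] = u[m] * (1.0 - u[m] ** 2) ** 2
    return out


class CalibratedTemplate:
    """Wave template whose extrema coincide with the three-point detector.

    The chord angle formed by three markers spaced ``marker_spacing_cm``
    along the axis attains its temporal minimum, for a generic asymmetric
    waveform, at a phase systematically offset from the true extremum (an
    O(spacing) secant bias).  Because any C1 waveform satisfying the wave
    invariants is admissible, the swing-section shape is calibrated so the
    angle minimum falls exactly on each extremum: one antisymmetric compact
    bump is placed at a flank point one marker-spacing away from each apex
    (outside the static-contact band, vanishing at the apexes so the
    extremal geometry is untouched) and its amplitude is solved so that
    d(theta)/d(phase) = 0 at the apex.
    """

    def __init__(self, wave: WaveParams, marker_spacing_cm: float,
                 temporal_gain=None):
        from scipy.optimize import brentq

        self.wave = wave
        self.D = float(marker_spacing_cm)
        self.temporal_gain = temporal_gain
        lam = wave.wavelength_cm
        w = wave.corner_halfwidth_cm
        xi_c = wave.crest_position_cm
        c0 = w + ((xi_c - 2 * w) - wave.duty * lam) / 2.0
        c1 = c0 + wave.duty * lam
        self._contact = (c0, c1)

        # effective apex phases of the corner-smoothed base template
        grid = np.linspace(0.0, lam, 8192, endpoint=False)
        gb = wave_template(wave, grid)
        self.apex_crest = float(grid[np.argmax(gb)])
        self.apex_trough = float(grid[np.argmin(gb)])

        def circ(a: float) -> float:
            return float(np.mod(a, lam))

        def dist_to_interval(x: float, lo: float, hi: float) -> float:
            # circular distance from point x to interval [lo, hi]
            x = circ(x - lo)
            width = circ(hi - lo)
            if x <= width:
                return 0.0
            return min(x - width, lam - x)

        protected = [
            (c0, c1),
            (self.apex_crest - w, self.apex_crest + w),
            (self.apex_trough - w, self.apex_trough + w),
        ]

        def free_flank(apex: float) -> tuple[float, float]:
            best = None
            for f in (circ(apex - self.D), circ(apex + self.D)):
                clearance = min(dist_to_interval(f, lo, hi)
                                for lo, hi in protected)
                if best is None or clearance > best[1]:
                    best = (f, clearance)
            f, clearance = best
            if clearance <= 0.02 * lam:
                raise ValueError(
                    "cannot calibrate wave template: both detector flank "
                    "points fall on protected template regions (contact band "
                    "or apex corners); reduce duty or change the geometry"
                )
            return f, min(0.9 * clearance, 0.12 * lam)

        self.flank_crest, hw_c = free_flank(self.apex_crest)
        self.flank_trough, hw_t = free_flank(self.apex_trough)
        gap = abs(np.mod(self.flank_crest - self.flank_trough + lam / 2, lam)
                  - lam / 2)
        hw_c = min(hw_c, 0.45 * gap)
        hw_t = min(hw_t, 0.45 * gap)
        self.hw_crest, self.hw_trough = hw_c, hw_t

        # the detector operates on the *smoothed* trajectories; for a
        # travelling wave the zero-phase temporal filter maps exactly onto
        # a reweighting of the spatial harmonics by gain(k * frequency)
        ngrid = 4096
        fine = np.linspace(0.0, lam, ngrid, endpoint=False)
        if temporal_gain is not None:
            k = np.arange(ngrid // 2 + 1)
            self._gain_k = np.asarray(
                temporal_gain(k * wave.frequency_hz), dtype=float)
        else:
            self._gain_k = None

        def as_seen(amp_c: float, amp_t: float) -> np.ndarray:
            g = (wave_template(wave, fine)
                 + amp_c * _odd_bump(fine, self.flank_crest, hw_c, lam)
                 + amp_t * _odd_bump(fine, self.flank_trough, hw_t, lam))
            if self._gain_k is None:
                return g
            return np.fft.irfft(np.fft.rfft(g) * self._gain_k, ngrid)

        def dtheta(apex: float, amp_c: float, amp_t: float) -> float:
            gtab = as_seen(amp_c, amp_t)

            def gval(x: np.ndarray) -> np.ndarray:
                return np.interp(np.mod(x, lam), fine, gtab, period=lam)

            def theta(p: float) -> float:
                g = gval(np.array([p + self.D, p, p - self.D]))
                # marker x decreases head-ward; only relative geometry matters
                Pa = np.array([-self.D, -g[0]])
                Pm = np.array([0.0, -g[1]])
                Pc = np.array([self.D, -g[2]])
                u = Pa - Pm
                v = Pc - Pm
                cosang = u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
                return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))

            h = 1e-3 * lam
            return (theta(apex + h) - theta(apex - h)) / (2.0 * h)

        def solve(fun) -> float:
            for hi in (1.0, 2.0, 4.0, 8.0, 16.0):
                try:
                    return brentq(fun, -hi, hi, xtol=1e-10)
                except ValueError:
                    continue
            raise ValueError(
                "cannot calibrate wave template: no bump amplitude zeroes "
                "the detector bias for this geometry"
            )

        self.amp_crest = solve(lambda a: dtheta(self.apex_crest, a, 0.0))
        self.amp_trough = solve(lambda a: dtheta(self.apex_trough, 0.0, a))

        # the bumps must not displace or overtop the extrema
        gg = self(grid)
        half = wave.amplitude_cm / 2.0
        if (gg.max() > half + 1e-6 or gg.min() < -half - 1e-6
                or abs(grid[np.argmax(gg)] - self.apex_crest) > 0.01 * lam
                or abs(grid[np.argmin(gg)] - self.apex_trough) > 0.01 * lam):
            raise ValueError(
                "wave template calibration displaced the extrema; the "
                "requested geometry is too extreme for the marker spacing"
            )

    def __call__(self, xi: np.ndarray) -> np.ndarray:
        lam = self.wave.wavelength_cm
        return (wave_template(self.wave, xi)
                + self.amp_crest * _odd_bump(xi, self.flank_crest,
                                             self.hw_crest, lam)
                + self.amp_trough * _odd_bump(xi, self.flank_trough,
                                              self.hw_trough, lam))


def _lift_profile(wave: WaveParams, phi: np.ndarray) -> np.ndarray:
    """Vertical profile: H*sin^2(pi*tau) across the swing, 0 in contact.

    The contact interval is centred in the straight part of the up-leg.
    """
    lam = wave.wavelength_cm
    contact_len = wave.duty * lam
    phi0, phi1 = contact_interval(wave)               # contact start/end
    swing_len = lam - contact_len
    tau = np.mod(phi - phi1, lam) / swing_len
    z = wave.lift_height_cm * np.sin(np.pi * tau) ** 2
    in_contact = np.mod(phi - phi0, lam) < contact_len
    z[in_contact] = 0.0
    return z


def generate_trajectory(gt: TrialGroundTruth):
    """Generate a ``MarkerTrackSet`` of noisy 3-D marker positions.

    Exact properties at ``noise_sd_cm = 0``: markers inside the contact
    phase are stationary; every marker advances by ``gt.stride_cm`` along +y
    per cycle; the planar marker polyline lies on the skewed-triangle wave
    at every frame; z peaks at ``lift_height_cm`` during the swing.
    """
    from .smoothing import MarkerTrackSet, TrialMeta  # local to avoid cycle

    wave = gt.wave
    lam = wave.wavelength_cm
    c = wave.frequency_hz * lam                    # wave speed in phase units
    m1 = wave.contact_slope
    t = np.arange(gt.n_frames) / gt.frame_rate_hz

    s = gt.marker_arclengths                       # (n_markers,)
    phase = s[None, :] + c * t[:, None]            # (n_frames, n_markers)
    g = None
    if gt.detector_calibration and gt.n_markers >= 6:
        # spacing of the extrema-detection band (markers 4-9)
        gaps = -np.diff(s[3:9]) if gt.n_markers == 10 else -np.diff(s)
        D = float(np.mean(gaps))
        gain = None
        if gt.smoothing_assumed is not None:
            cfg = gt.smoothing_assumed
            gain = lambda freqs: displacement_filter_gain(freqs, cfg)
        try:
            template = CalibratedTemplate(wave, D, temporal_gain=gain)
            g = template(phase)
        except ValueError as exc:
            warnings.warn(
                "detector calibration infeasible for this wave geometry "
                f"({exc}); generating the plain template - extracted "
                "amplitude and skew will carry the three-point secant bias"
            )
    if g is None:
        g = wave_template(wave, phase)
    z = _lift_profile(wave, np.mod(phase, lam))

    # ground frame (right-handed canonical): u_hat=-x, v_hat=-y,
    # R(t) = c*(1, m1)*t  =>  x = c*t - phase = -s (constant per marker)
    x = c * t[:, None] - phase
    y = c * m1 * t[:, None] - g

    pos = np.stack([x, y, z], axis=-1)             # (n_frames, n_markers, 3)
    if gt.noise_sd_cm > 0:
        rng = np.random.default_rng(gt.seed)
        pos = pos + rng.normal(0.0, gt.noise_sd_cm, size=pos.shape)
    # mirroring last keeps left/right trials exact mirror images even with
    # seeded noise
    if wave.handedness == "left":
        pos[:, :, 0] *= -1.0

    meta = TrialMeta(
        trial_id=f"synth-{gt.seed:05d}",
        individual_id=f"ind-{gt.seed:05d}",
        sex="F",
        age_class="adult",
        temperature_C=24.0,
        handedness=wave.handedness,
    )
    return MarkerTrackSet(
        positions=pos, frame_rate_hz=gt.frame_rate_hz, meta=meta
    )


def default_study_grid(seed: int = 0, noise_sd_cm: float = 0.1
                       ) -> list[TrialGroundTruth]:
    """The canonical grid of synthetic trials used for parameter recovery.

    Conditions emulate slow, steady sidewinding: cycle frequencies
    0.25-0.35 Hz (the low end of the speed range, where the configured
    smoothing filter resolves the waveform shape), wavelengths 14-20 cm,
    peak-to-peak amplitudes 8-16 cm, skew angles -5..+5 deg, lift heights
    2-3 cm, contact duty 0.25 and 0.1 cm digitizing noise.  The body span
    (in wavelengths) is searched per combination so the detector-calibrated
    template is constructible; infeasible combinations are skipped.
    """
    combos = []
    for f, n_frames in ((0.25, 5500), (0.30, 4500), (0.35, 4000)):
        for lam, A in ((20.0, 16.0), (20.0, 10.0), (14.0, 8.0)):
            for skew in (-5.0, 0.0, 5.0):
                combos.append((f, n_frames, lam, A, skew))
    grid: list[TrialGroundTruth] = []
    for i, (f, n_frames, lam, A, skew) in enumerate(combos):
        wave = WaveParams(
            frequency_hz=f, wavelength_cm=lam, amplitude_cm=A,
            skew_deg=skew, lift_height_cm=2.0 + (i % 2),
            duty=0.25, smooth_frac=0.04,
            handedness="right" if i % 2 == 0 else "left",
        )
        for span in (3.2, 3.5, 2.9, 3.8, 2.7):
            s = default_marker_arclengths(lam, span)
            D = float(np.mean(-np.diff(s[3:9])))
            try:
                CalibratedTemplate(
                    wave, D,
                    temporal_gain=lambda fr: displacement_filter_gain(fr),
                )
            except ValueError:
                continue
            grid.append(TrialGroundTruth(
                wave=wave, n_frames=n_frames, noise_sd_cm=noise_sd_cm,
                seed=seed + i, marker_arclengths=s,
            ))
            break
    return grid


# ---------------------------------------------------------------------------
# morphometrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraitGen:
    """log10(trait) = log10(a) + b*log10(SVL) + offsets + N(0, sd).

    ``b`` defaults to isometry: 1 for linear traits, 3 for mass.
    ``sex_offset``/``age_offset`` are log10 shifts applied to males and
    adults respectively.
    """

    a: float
    b: float
    sd: float = 0.02
    sex_offset: float = 0.0
    age_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("residual sd must be >= 0")


def _default_traits() -> dict[str, TraitGen]:
    # intercepts chosen so a 40 cm SVL sidewinder has realistic values:
    # mass ~100 g, tail ~4 cm (longer in males), mid-body width ~2.6 cm
    return {
        "mass_g": TraitGen(a=100.0 / 40.0 ** 3, b=3.0, sd=0.04, age_offset=0.02),
        "tail_cm": TraitGen(a=0.10, b=1.0, sd=0.03, sex_offset=0.05),
        "width25_cm": TraitGen(a=0.055, b=1.0, sd=0.03),
        "width50_cm": TraitGen(a=0.065, b=1.0, sd=0.03),
        "width75_cm": TraitGen(a=0.050, b=1.0, sd=0.03),
        "neck_width_cm": TraitGen(a=0.030, b=1.0, sd=0.03),
        "head_width_cm": TraitGen(a=0.045, b=1.0, sd=0.025),
        "head_length_cm": TraitGen(a=0.060, b=1.0, sd=0.025, sex_offset=0.02),
    }


@dataclass
class MorphoGenConfig:
    """Log-normal morphometrics with configurable allometric exponents."""

    n_individuals: int = 74
    svl_log10_mean: float = math.log10(40.0)
    svl_log10_sd: float = 0.10
    juvenile_svl_offset: float = -0.22   # log10 shift for juveniles
    p_female: float = 0.5
    p_juvenile: float = 0.5
    traits: dict[str, TraitGen] = field(default_factory=_default_traits)
    ventral_mean: float = 142.0
    ventral_sd: float = 3.0
    ventral_sex_offset: float = 3.0      # females carry more ventrals
    subcaudal_mean: float = 20.0
    subcaudal_sd: float = 2.0
    subcaudal_sex_offset: float = -4.0   # females carry fewer subcaudals
    dorsal_rows: int = 21
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be > 0")
        for sd in (self.svl_log10_sd, self.ventral_sd, self.subcaudal_sd):
            if sd < 0:
                raise ValueError("negative sd")


def generate_morphometrics(cfg: MorphoGenConfig) -> pd.DataFrame:
    """Generate the morphometrics table (one row per individual)."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_individuals
    sex = np.where(rng.random(n) < cfg.p_female, "F", "M")
    age = np.where(rng.random(n) < cfg.p_juvenile, "juvenile", "adult")
    log_svl = rng.normal(cfg.svl_log10_mean, cfg.svl_log10_sd, n)
    log_svl = log_svl + np.where(age == "juvenile", cfg.juvenile_svl_offset, 0.0)
    svl = 10.0 ** log_svl

    out = {
        "id": [f"sw{i:03d}" for i in range(n)],
        "sex": sex,
        "age_class": age,
        "svl_cm": svl,
    }
    male = (sex == "M").astype(float)
    adult = (age == "adult").astype(float)
    for name, tg in cfg.traits.items():
        logv = (
            math.log10(tg.a)
            + tg.b * log_svl
            + tg.sex_offset * male
            + tg.age_offset * adult
            + rng.normal(0.0, tg.sd, n)
        )
        out[name] = 10.0 ** logv

    female = (sex == "F").astype(float)
    out["ventral_count"] = np.maximum(
        1,
        np.round(
            rng.normal(cfg.ventral_mean, cfg.ventral_sd, n)
            + cfg.ventral_sex_offset * female
        ).astype(int),
    )
    out["subcaudal_count"] = np.maximum(
        1,
        np.round(
            rng.normal(cfg.subcaudal_mean, cfg.subcaudal_sd, n)
            + cfg.subcaudal_sex_offset * female
        ).astype(int),
    )
    out["dorsal_rows"] = np.full(n, cfg.dorsal_rows, dtype=int)
    df = pd.DataFrame(out)
    return df[[c for c in MORPHO_COLUMNS if c in df.columns]]


# ---------------------------------------------------------------------------
# fixture writing
# ---------------------------------------------------------------------------

def write_fixture_set(
    gts: Sequence[TrialGroundTruth],
    cfg: MorphoGenConfig,
    out_dir: str | Path,
) -> dict:
    """Write coordinate tables, trial metadata, morphometrics and the
    ground-truth sidecar; returns a manifest of written paths.

    Round-trips losslessly through :mod:`sidewinderkin.io` readers.
    """
    from . import io as swio

    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc

    manifest: dict = {"trials": [], "metadata": None, "morphometrics": None,
                      "ground_truth": None}
    morpho = generate_morphometrics(cfg)
    meta_rows = []
    truth = {}
    for j, gt in enumerate(gts):
        tracks = generate_trajectory(gt)
        # tie each trial to a generated individual so kinematics can be
        # joined with morphometrics downstream
        ind = morpho.iloc[j % len(morpho)]
        tracks.meta.individual_id = str(ind["id"])
        tracks.meta.sex = str(ind["sex"])
        tracks.meta.age_class = str(ind["age_class"])
        fname = out / f"{tracks.meta.trial_id}_coords.csv"
        try:
            swio.write_marker_tracks(tracks, fname)
        except OSError as exc:
            raise OSError(f"failed writing {fname}: {exc}") from exc
        manifest["trials"].append(str(fname))
        meta_rows.append(
            {
                "trial_id": tracks.meta.trial_id,
                "individual_id": tracks.meta.individual_id,
                "sex": tracks.meta.sex,
                "age_class": tracks.meta.age_class,
                "temperature_C": tracks.meta.temperature_C,
                "handedness": tracks.meta.handedness,
                "frame_rate_hz": tracks.frame_rate_hz,
                "representative": True,
                "coord_file": fname.name,
            }
        )
        truth[tracks.meta.trial_id] = gt.to_jsonable()

    meta_path = out / "trial_metadata.csv"
    pd.DataFrame(
        meta_rows,
        columns=["trial_id", "individual_id", "sex", "age_class",
                 "temperature_C", "handedness", "frame_rate_hz",
                 "representative", "coord_file"],
    ).to_csv(meta_path, index=False)
    manifest["metadata"] = str(meta_path)

    morpho_path = out / "morphometrics.csv"
    morpho.to_csv(morpho_path, index=False)
    manifest["morphometrics"] = str(morpho_path)

    truth_path = out / "ground_truth.json"
    truth_path.write_text(json.dumps(truth, indent=1))
    manifest["ground_truth"] = str(truth_path)
    return manifest
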