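"""Synthetic single-endosome time-lapse generator.

Stands in for the microscope: it produces ground-truth marker kinetics and
luminal-pH trajectories for enlarged (nigericin-washout-like) endosomes,
renders them as noisy multi-channel image stacks, and generates calibration
image sets for the ratiometric pH sensor.  Every quantity the analysis
pipeline later estimates (event times, amplitudes, pH) is recorded exactly,
so the generator doubles as the oracle for parameter-recovery tests.

The kinetic model encodes the canonical Rab-conversion choreography on a
maturing endosome:

* Rab5 is recruited transiently: a piecewise-linear rise to its peak,
  an optional hold, then a linear decline to baseline.
* Rab7 rises as a logistic to a stable plateau.
* The two are coupled: Rab5 starts declining at the instant Rab7 first
  reaches ``conversion_coupling`` (default 50%) of its plateau, and returns
  to baseline within ``conversion_duration_min`` (default 4 min) of Rab7's
  10%-of-plateau crossing.
* Luminal pH falls along a sigmoid from an early-endosomal ~6.6 to a
  late-endosomal ~5.7, centered by default on the Rab7 half-max time.

Accessory markers (sorting-nexin subdomains, recycling cargo, degradative
cargo) follow template patterns selected by ``accessory_pattern``.

The two-channel pH sensor emulates a tandem YFP/CFP (pHlemon-like) probe:
YFP brightness falls steeply with acidification along a pKa-type sigmoid
while CFP brightens mildly, so the YFP/CFP ratio decreases monotonically as
the lumen acidifies.  The per-channel forms are a modelling choice pinned
here; only self-consistency with the calibration module is asserted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.special import expit

from .io import RoiSeries, TimeLapseStack
from .rim import Circle, PolylineRoi, signed_distance

__all__ = [
    "MarkerKineticsParams",
    "PhTrajectoryParams",
    "SensorModel",
    "RenderParams",
    "AngularSpot",
    "GroundTruth",
    "CalibrationScene",
    "ACCESSORY_PATTERNS",
    "simulate_truth",
    "render_timelapse",
    "generate_calibration_set",
    "render_golgi_ribbon",
]

ACCESSORY_PATTERNS = ("single_peak", "double_peak", "persistent",
                      "transient_cargo", "constant_cargo",
                      "early_removal_cargo", "none")

# Default Rab7 logistic time constant: 1/ln(9) min, so that the
# 10%-of-plateau crossing sits exactly one frame interval before the
# half-max time at the default 1-min sampling.  With recruitment onsets on
# the frame grid this keeps every conversion landmark (10% crossing,
# half-max, baseline return) on the grid, where linearly interpolated
# crossing detection is exact — the generator's events stay closed-form
# recoverable.  The corresponding Rab7 10-90% rise takes 2 min, well within
# the 4-min conversion window.
RAB7_TAU_DEFAULT = 1.0 / float(np.log(9.0))


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerKineticsParams:
    """Ground-truth kinetic parameters of one endosome.

    Times are minutes from the start of the recording, amplitudes arbitrary
    fluorescence units (a.u., expected photon counts at the rim center).
    ``rab7_plateau_amp = 0`` encodes a conversion-incompetent endosome
    (no Rab7 recruitment, Rab5 never displaced), as in fusion-machinery
    (Ccz1) knockouts.
    """

    rab5_onset_min: float = 10.0
    rab5_rise_min: float = 5.0
    rab5_plateau_min: float = 0.0
    rab5_peak_amp: float = 150.0
    rab7_plateau_amp: float = 150.0
    rab7_tau_min: float = RAB7_TAU_DEFAULT
    conversion_coupling: float = 0.5
    conversion_duration_min: float = 4.0
    accessory_pattern: str = "none"
    accessory_amp: float = 120.0
    multi_peak_count: int = 1

    def __post_init__(self) -> None:
        if self.rab5_rise_min <= 0 or self.rab7_tau_min <= 0:
            raise ValueError("durations must be > 0")
        if self.rab5_plateau_min < 0 or self.rab5_onset_min < 0:
            raise ValueError("onset/plateau times must be >= 0")
        if self.conversion_duration_min <= 0:
            raise ValueError("conversion duration must be > 0")
        if not 0 < self.conversion_coupling < 1:
            raise ValueError("conversion_coupling must lie in (0, 1)")
        if self.rab5_peak_amp <= 0 or self.accessory_amp <= 0:
            raise ValueError("amplitudes must be > 0")
        if self.rab7_plateau_amp < 0:
            raise ValueError("rab7_plateau_amp must be >= 0")
        if self.accessory_pattern not in ACCESSORY_PATTERNS:
            raise ValueError(
                f"unknown accessory_pattern {self.accessory_pattern!r}; "
                f"choose from {ACCESSORY_PATTERNS}"
            )
        if self.multi_peak_count < 1:
            raise ValueError("multi_peak_count must be >= 1")


@dataclass(frozen=True)
class PhTrajectoryParams:
    """Luminal pH trajectory: sigmoidal drop across Rab conversion."""

    ph_pre_rab5: float = 6.6
    ph_post_conversion: float = 5.7
    ph_endolysosome: float = 4.5
    drop_center_min: float | None = None  # default: Rab7 half-max time
    drop_width_min: float = 4.0  # 10-90% transition width

    def __post_init__(self) -> None:
        for v in (self.ph_pre_rab5, self.ph_post_conversion,
                  self.ph_endolysosome):
            if not 3.5 <= v <= 8.0:
                raise ValueError(f"pH value {v} outside the physiological "
                                 "range [3.5, 8.0]")
        if not (self.ph_pre_rab5 > self.ph_post_conversion
                >= self.ph_endolysosome):
            raise ValueError("require ph_pre_rab5 > ph_post_conversion "
                             ">= ph_endolysosome")
        if self.drop_width_min <= 0:
            raise ValueError("drop width must be > 0")


@dataclass(frozen=True)
class SensorModel:
    """Two-channel ratiometric pH sensor (tandem YFP/CFP).

    YFP brightness factor f_Y(pH) = 1 / (1 + 10^((pKa - pH) * hill)) is
    strictly increasing in pH; the CFP factor increases mildly with
    acidification (non-increasing in pH), floored at a small positive value.
    Pixel expectations are brightness * factor.
    """

    yfp_pka: float = 6.3
    yfp_hill: float = 1.0
    cfp_acid_gain: float = 0.05
    brightness_yfp: float = 300.0
    brightness_cfp: float = 300.0
    cfp_ref_ph: float = 7.5
    ph_range: tuple[float, float] = (3.5, 8.0)

    def __post_init__(self) -> None:
        if self.yfp_hill <= 0:
            raise ValueError("yfp_hill must be > 0")
        if self.cfp_acid_gain < 0:
            raise ValueError("cfp_acid_gain must be >= 0")
        if self.brightness_yfp <= 0 or self.brightness_cfp <= 0:
            raise ValueError("brightnesses must be > 0")

    def f_yfp(self, ph) -> np.ndarray:
        ph = np.asarray(ph, dtype=float)
        return 1.0 / (1.0 + 10.0 ** ((self.yfp_pka - ph) * self.yfp_hill))

    def f_cfp(self, ph) -> np.ndarray:
        ph = np.asarray(ph, dtype=float)
        return np.maximum(1.0 + self.cfp_acid_gain * (self.cfp_ref_ph - ph),
                          0.05)

    def ratio(self, ph) -> np.ndarray:
        """Noise-free background-corrected YFP/CFP ratio at a given pH."""
        return (self.brightness_yfp * self.f_yfp(ph)
                / (self.brightness_cfp * self.f_cfp(ph)))


@dataclass(frozen=True)
class AngularSpot:
    """Angular subdomain on the rim: Gaussian bump of relative amplitude
    ``rel_amp`` centered at ``theta_deg`` (degrees from the top of the
    endosome, clockwise on screen), width ``sigma_deg``."""

    theta_deg: float
    sigma_deg: float = 20.0
    rel_amp: float = 1.0


@dataclass(frozen=True)
class RenderParams:
    """Imaging geometry and noise for the forward render.

    Noise model: Poisson shot noise on the expected counts, then additive
    Gaussian read noise, clipped at zero.  Default amplitudes put the
    per-pixel SNR at the rim around 10.
    """

    image_size: tuple[int, int] = (64, 64)
    frame_interval_min: float | None = None  # default: taken from the truth
    n_frames: int | None = None
    endosome_radius_px: float = 10.0
    center: tuple[float, float] | None = None  # (cy, cx); default image center
    rim_sigma_px: float = 1.0
    background_level: float = 20.0
    read_noise_sigma: float = 3.0
    shot_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h < 16 or w < 16:
            raise ValueError("image must be at least 16x16")
        if self.endosome_radius_px < 3:
            raise ValueError("endosome radius must be >= 3 px")
        if self.n_frames is not None and self.n_frames < 10:
            raise ValueError("n_frames must be >= 10")
        if self.rim_sigma_px <= 0:
            raise ValueError("rim_sigma_px must be > 0")
        if self.background_level < 0 or self.read_noise_sigma < 0:
            raise ValueError("background and read noise must be >= 0")
        cy, cx = self.resolved_center
        margin = min(cy, cx, h - 1 - cy, w - 1 - cx)
        if margin < self.endosome_radius_px + 6:
            raise ValueError(
                f"ring of radius {self.endosome_radius_px} px needs >= 6 px "
                f"margin inside the {h}x{w} image (background annulus room); "
                f"center {self.resolved_center} leaves {margin:.1f} px"
            )

    @property
    def resolved_center(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        h, w = self.image_size
        return ((h - 1) / 2.0, (w - 1) / 2.0)


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Exact per-endosome truth: amplitude functions, pH, event times.

    ``amplitude_funcs`` maps channel name -> vectorized a_c(t); ``events``
    records the analytic event times in minutes (None where the event does
    not occur, e.g. no conversion without Rab7).
    """

    kin: MarkerKineticsParams
    ph_params: PhTrajectoryParams
    n_frames: int
    frame_interval_min: float
    seed: int
    amplitude_funcs: dict[str, Callable[[np.ndarray], np.ndarray]]
    ph_func: Callable[[np.ndarray], np.ndarray]
    events: dict[str, float | None]

    @property
    def times_min(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_min

    @property
    def channel_names(self) -> list[str]:
        return list(self.amplitude_funcs)

    def amplitudes(self, channel: str) -> np.ndarray:
        return self.amplitude_funcs[channel](self.times_min)

    @property
    def ph_values(self) -> np.ndarray:
        return self.ph_func(self.times_min)

    def to_dict(self) -> dict:
        """JSON-serializable truth record (sampled arrays + events)."""
        return {
            "n_frames": self.n_frames,
            "frame_interval_min": self.frame_interval_min,
            "seed": self.seed,
            "events": self.events,
            "times_min": self.times_min.tolist(),
            "amplitudes": {c: self.amplitudes(c).tolist()
                           for c in self.channel_names},
            "ph": self.ph_values.tolist(),
        }


def _linear_pulse(t: np.ndarray, t0: float, t1: float, t2: float, t3: float,
                  amp: float) -> np.ndarray:
    """Trapezoid: 0 before t0, rise to amp by t1, hold to t2, 0 after t3."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    rising = (t >= t0) & (t < t1)
    out[rising] = amp * (t[rising] - t0) / max(t1 - t0, 1e-12)
    hold = (t >= t1) & (t <= t2)
    out[hold] = amp
    falling = (t > t2) & (t < t3)
    out[falling] = amp * (t3 - t[falling]) / max(t3 - t2, 1e-12)
    return out


def _logistic(t: np.ndarray, amp: float, midpoint: float,
              tau: float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return amp * expit((t - midpoint) / tau)


def simulate_truth(kin: MarkerKineticsParams,
                   ph: PhTrajectoryParams | None = None,
                   n_frames: int = 40,
                   frame_interval_min: float = 1.0,
                   seed: int = 0) -> GroundTruth:
    """Build the analytic ground truth for one endosome.

    Event bookkeeping (all closed-form):

    * ``rab5_peak``  — end of the Rab5 rise (tallest peak for multi-peak).
    * ``rab5_decline_start`` — instant Rab7 first reaches
      ``conversion_coupling`` of its plateau; equal to the end of the Rab5
      hold phase by construction.
    * ``rab7_halfmax`` — midpoint of the Rab7 logistic.
    * ``conversion_start`` — Rab7's 10%-of-plateau crossing.
    * ``conversion_end`` — Rab5 back at baseline,
      ``conversion_start + conversion_duration_min``.
    """
    if ph is None:
        ph = PhTrajectoryParams()
    if n_frames < 10:
        raise ValueError("n_frames must be >= 10")
    if frame_interval_min <= 0:
        raise ValueError("frame interval must be > 0")
    span = (n_frames - 1) * frame_interval_min

    t_rise_end = kin.rab5_onset_min + kin.rab5_rise_min
    c, tau = kin.conversion_coupling, kin.rab7_tau_min
    converting = kin.rab7_plateau_amp > 0

    if converting:
        t_decline = t_rise_end + kin.rab5_plateau_min
        # Rab7 midpoint chosen so Rab7(t_decline) = coupling * plateau.
        midpoint = t_decline - tau * np.log(c / (1.0 - c))
        t_conv_start = midpoint - tau * np.log(9.0)  # 10% of plateau
        t_conv_end = t_conv_start + kin.conversion_duration_min
        if t_conv_end <= t_decline:
            need = t_decline - t_conv_start
            raise ValueError(
                "conversion_duration_min too short: Rab5 decline starts at "
                f"{t_decline:.2f} min but conversion would already end at "
                f"{t_conv_end:.2f} min; need a duration > {need:.2f} min"
            )
        if t_conv_end > span:
            raise ValueError(
                f"conversion window ends at {t_conv_end:.2f} min, beyond the "
                f"simulated span of {span:.2f} min; extend n_frames"
            )

        def rab5(t):
            main = _linear_pulse(t, kin.rab5_onset_min, t_rise_end,
                                 t_decline, t_conv_end, kin.rab5_peak_amp)
            for j in range(1, kin.multi_peak_count):
                center = kin.rab5_onset_min - 6.0 * j
                pre = _linear_pulse(t, center - 2.0, center, center,
                                    center + 2.0, 0.6 * kin.rab5_peak_amp)
                main = np.maximum(main, pre)
            return main

        def rab7(t):
            return _logistic(t, kin.rab7_plateau_amp, midpoint, tau)

        events = {
            "rab5_onset": kin.rab5_onset_min,
            "rab5_peak": t_rise_end,
            "rab5_decline_start": t_decline,
            "rab7_halfmax": midpoint,
            "conversion_start": t_conv_start,
            "conversion_end": t_conv_end,
        }
    else:
        # Conversion-incompetent endosome: Rab5 persists, no Rab7.
        midpoint = None

        def rab5(t):
            return _linear_pulse(t, kin.rab5_onset_min, t_rise_end,
                                 np.inf, np.inf, kin.rab5_peak_amp)

        def rab7(t):
            return np.zeros_like(np.asarray(t, dtype=float))

        events = {
            "rab5_onset": kin.rab5_onset_min,
            "rab5_peak": t_rise_end,
            "rab5_decline_start": None,
            "rab7_halfmax": None,
            "conversion_start": None,
            "conversion_end": None,
        }

    funcs: dict[str, Callable] = {"rab5": rab5, "rab7": rab7}
    if kin.accessory_pattern != "none":
        anchor = midpoint if midpoint is not None else span + 60.0
        funcs["accessory"] = _accessory_func(kin, anchor, span)

    drop_center = ph.drop_center_min
    if drop_center is None:
        drop_center = midpoint if midpoint is not None else span + 60.0
    w = ph.drop_width_min / (2.0 * np.log(9.0))
    lo, hi = ph.ph_post_conversion, ph.ph_pre_rab5

    def ph_func(t):
        t = np.asarray(t, dtype=float)
        return lo + (hi - lo) * expit(-(t - drop_center) / w)

    return GroundTruth(kin=kin, ph_params=ph, n_frames=n_frames,
                       frame_interval_min=frame_interval_min, seed=seed,
                       amplitude_funcs=funcs, ph_func=ph_func, events=events)


def _accessory_func(kin: MarkerKineticsParams, conv: float,
                    span: float) -> Callable[[np.ndarray], np.ndarray]:
    """Template accessory-marker kinetics anchored on the conversion time."""
    amp = kin.accessory_amp
    pattern = kin.accessory_pattern
    onset = kin.rab5_onset_min
    if pattern == "single_peak":
        return lambda t: _linear_pulse(t, conv - 4, conv, conv, conv + 4, amp)
    if pattern == "double_peak":
        def f(t):
            a = _linear_pulse(t, conv - 6.5, conv - 4, conv - 4, conv - 1.5,
                              amp)
            b = _linear_pulse(t, conv + 1.5, conv + 4, conv + 4, conv + 6.5,
                              0.9 * amp)
            return np.maximum(a, b)
        return f
    if pattern == "persistent":
        return lambda t: _logistic(t, amp, conv - 2.0, 1.0)
    if pattern == "transient_cargo":
        # present from the start, removed across the conversion window
        return lambda t: _linear_pulse(t, -np.inf, -np.inf, conv - 2,
                                       conv + 2, amp)
    if pattern == "constant_cargo":
        return lambda t: np.full_like(np.asarray(t, dtype=float), amp)
    if pattern == "early_removal_cargo":
        # removed already around Rab5 recruitment, before conversion
        return lambda t: _linear_pulse(t, -np.inf, -np.inf, onset,
                                       onset + kin.rab5_rise_min, amp)
    raise ValueError(f"unknown accessory pattern {pattern!r}")


# ---------------------------------------------------------------------------
# Forward render
# ---------------------------------------------------------------------------

def _angles_from_top(yy: np.ndarray, xx: np.ndarray, cy: float,
                     cx: float) -> np.ndarray:
    """Angle of each pixel around (cy, cx), 0 at the top of the endosome,
    increasing clockwise on screen, in radians [0, 2pi)."""
    return np.mod(np.arctan2(xx - cx, -(yy - cy)), 2.0 * np.pi)


def _angular_modulation(theta: np.ndarray,
                        spots: Sequence[AngularSpot]) -> np.ndarray:
    mod = np.ones_like(theta)
    for spot in spots:
        t0 = np.deg2rad(spot.theta_deg)
        sig = np.deg2rad(spot.sigma_deg)
        d = np.angle(np.exp(1j * (theta - t0)))  # wrapped difference
        mod = mod + spot.rel_amp * np.exp(-0.5 * (d / sig) ** 2)
    return mod


def _apply_noise(expected: np.ndarray, rp: RenderParams,
                 rng: np.random.Generator) -> np.ndarray:
    out = rng.poisson(expected).astype(float) if rp.shot_noise else expected
    if rp.read_noise_sigma > 0:
        out = out + rng.normal(0.0, rp.read_noise_sigma, size=out.shape)
    return np.clip(out, 0.0, None)


def render_timelapse(truth: GroundTruth, sensor: SensorModel | None = None,
                     rp: RenderParams = RenderParams(),
                     angular_spots: Mapping[str, Sequence[AngularSpot]]
                     | None = None,
                     endosome_id: str = "endo_0",
                     ) -> tuple[TimeLapseStack, RoiSeries]:
    """Render the ground truth as a noisy multi-channel time-lapse.

    Marker channels are drawn as rings: a Gaussian radial profile of width
    ``rim_sigma_px`` at the endosome radius, scaled by a_c(t), on top of a
    uniform background.  If ``sensor`` is given, two extra channels ('yfp',
    'cfp') render the luminal sensor pool as a filled disk whose expectation
    follows brightness * f(pH(t)).  Optional angular spots modulate named
    ring channels to emulate rim subdomains.

    Returns the stack together with the true ROI geometry (a circle per
    frame), which downstream measurement consumes in place of manual ROIs.
    """
    n_frames = rp.n_frames or truth.n_frames
    if n_frames != truth.n_frames:
        raise ValueError("RenderParams.n_frames disagrees with the truth")
    interval = rp.frame_interval_min or truth.frame_interval_min
    if interval != truth.frame_interval_min:
        raise ValueError("RenderParams.frame_interval_min disagrees with "
                         "the truth")

    h, w = rp.image_size
    cy, cx = rp.resolved_center
    r = rp.endosome_radius_px
    yy, xx = np.mgrid[0:h, 0:w]
    dist = np.hypot(yy - cy, xx - cx)
    ring = np.exp(-0.5 * ((dist - r) / rp.rim_sigma_px) ** 2)
    disk = (dist < r).astype(float)
    if angular_spots:
        theta = _angles_from_top(yy, xx, cy, cx)

    channels = list(truth.channel_names)
    if sensor is not None:
        channels += ["yfp", "cfp"]

    rng = np.random.default_rng(rp.seed)
    times = truth.times_min
    pixels = np.empty((n_frames, len(channels), h, w), dtype=float)
    for ci, ch in enumerate(channels):
        if ch in truth.amplitude_funcs:
            profile = ring
            if angular_spots and ch in angular_spots:
                profile = ring * _angular_modulation(theta, angular_spots[ch])
            amps = truth.amplitudes(ch)
            expected = rp.background_level + amps[:, None, None] * profile
        elif ch == "yfp":
            f = sensor.brightness_yfp * sensor.f_yfp(truth.ph_values)
            expected = rp.background_level + f[:, None, None] * disk
        elif ch == "cfp":
            f = sensor.brightness_cfp * sensor.f_cfp(truth.ph_values)
            expected = rp.background_level + f[:, None, None] * disk
        else:  # pragma: no cover
            raise ValueError(f"no render rule for channel {ch!r}")
        pixels[:, ci] = _apply_noise(expected, rp, rng)

    stack = TimeLapseStack(pixels, channels, interval)
    roi = RoiSeries(endosome_id,
                    {f: Circle(cy, cx, r) for f in range(n_frames)})
    return stack, roi


# ---------------------------------------------------------------------------
# Calibration sets and Golgi ribbon
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationScene:
    """One calibration-buffer scene: the whole structure clamped at a known
    pH, with its ROI and the true pH recorded."""

    stack: TimeLapseStack
    ph_truth: float
    roi: Circle


def generate_calibration_set(ph_values: Sequence[float],
                             sensor: SensorModel = SensorModel(),
                             rp: RenderParams = RenderParams(),
                             n_frames: int = 3,
                             ) -> list[CalibrationScene]:
    """Render one two-channel (YFP/CFP) scene per calibration-buffer pH.

    Emulates clamping intracellular pH with ionophores: the entire structure
    sits at a single known pH.  Fewer than 5 pH values triggers a warning
    because the downstream four-parameter fit will be under-determined.
    """
    ph_values = list(ph_values)
    lo, hi = sensor.ph_range
    for v in ph_values:
        if not lo <= v <= hi:
            raise ValueError(f"calibration pH {v} outside sensor range "
                             f"[{lo}, {hi}]")
    if len(ph_values) < 5:
        warnings.warn("fewer than 5 calibration pH values: the "
                      "four-parameter fit downstream will fail",
                      stacklevel=2)

    h, w = rp.image_size
    cy, cx = rp.resolved_center
    r = rp.endosome_radius_px
    yy, xx = np.mgrid[0:h, 0:w]
    disk = (np.hypot(yy - cy, xx - cx) < r).astype(float)

    scenes = []
    for i, ph in enumerate(ph_values):
        rng = np.random.default_rng(rp.seed + 7919 * i)
        ey = rp.background_level + sensor.brightness_yfp * float(
            sensor.f_yfp(ph)) * disk
        ec = rp.background_level + sensor.brightness_cfp * float(
            sensor.f_cfp(ph)) * disk
        pixels = np.empty((n_frames, 2, h, w), dtype=float)
        for t in range(n_frames):
            pixels[t, 0] = _apply_noise(ey, rp, rng)
            pixels[t, 1] = _apply_noise(ec, rp, rng)
        stack = TimeLapseStack(pixels, ["yfp", "cfp"], 1.0)
        scenes.append(CalibrationScene(stack, float(ph), Circle(cy, cx, r)))
    return scenes


def render_golgi_ribbon(ph_truth: float = 6.2,
                        sensor: SensorModel = SensorModel(),
                        rp: RenderParams = RenderParams(),
                        n_frames: int = 3,
                        ribbon_halfwidth_px: float = 3.0,
                        ) -> tuple[TimeLapseStack, PolylineRoi]:
    """Render a Golgi-ribbon-like structure at a uniform pH.

    The ribbon is a wavy band (uniform sensor expectation within
    ``ribbon_halfwidth_px`` of a segmented center line) in YFP and CFP
    channels; the returned polyline follows the center line so the band ROI
    used for measurement lies fully inside the structure.
    """
    h, w = rp.image_size
    xs = np.arange(8.0, w - 8.0, 2.0)
    ys = h / 2.0 + 6.0 * np.sin(2.0 * np.pi * xs / 32.0)
    path = PolylineRoi(np.column_stack([ys, xs]))

    yy, xx = np.mgrid[0:h, 0:w]
    dist = signed_distance(path, yy, xx)
    band = (dist < ribbon_halfwidth_px).astype(float)

    rng = np.random.default_rng(rp.seed)
    ey = rp.background_level + sensor.brightness_yfp * float(
        sensor.f_yfp(ph_truth)) * band
    ec = rp.background_level + sensor.brightness_cfp * float(
        sensor.f_cfp(ph_truth)) * band
    pixels = np.empty((n_frames, 2, h, w), dtype=float)
    for t in range(n_frames):
        pixels[t, 0] = _apply_noise(ey, rp, rng)
        pixels[t, 1] = _apply_noise(ec, rp, rng)
    return TimeLapseStack(pixels, ["yfp", "cfp"], 1.0), path
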