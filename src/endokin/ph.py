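"""Ratiometric pH calibration and luminal pH traces.

The tandem YFP/CFP sensor's background-corrected ratio R falls with luminal
acidification.  Calibration scenes at known buffer pH are fitted with the
standard sigmoidal four-parameter dose-response model (variable slope),
with pH playing the role of log(dose):

    R(pH) = bottom + (top - bottom) / (1 + 10**((ph50 - pH) * hill))

and inverted analytically to convert measured ratios to pH:

    pH = ph50 - (1 / hill) * log10((top - bottom) / (R - bottom) - 1)

Ratios outside the open interval (bottom, top) cannot be inverted; they are
clipped to the curve's domain edge and flagged, never silently extrapolated
(ratios near the bottom asymptote are expected for endolysosomes).

The calibrated quantity is the ratio of luminal means over one pixel set,
which equals the ratio of luminal totals — so the distinction between
"total" and "mean" luminal MFI never reaches the calibration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .rim import (Geometry, PolylineRoi, band_pixels, lumen_pixels,
                  region_pixels)

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationCurve",
    "four_param_logistic",
    "fit_calibration",
    "ratio_to_ph",
    "measure_ratio",
    "ph_trace",
]


def four_param_logistic(ph, bottom: float, top: float, ph50: float,
                        hill: float):
    """Sigmoidal four-parameter dose-response curve (variable slope)."""
    ph = np.asarray(ph, dtype=float)
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((ph50 - ph) * hill))


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted pH -> YFP/CFP ratio curve.

    ``bottom``/``top`` are the low-/high-pH ratio asymptotes, ``ph50`` the
    inflection pH, ``hill`` the (positive) slope factor.
    """

    bottom: float
    top: float
    ph50: float
    hill: float
    residual_rms: float = float("nan")
    n_points: int = 0

    def __post_init__(self) -> None:
        if not self.top > self.bottom:
            raise ValueError("top asymptote must exceed bottom")
        if self.hill <= 0:
            raise ValueError("hill slope must be positive")

    def forward(self, ph):
        return four_param_logistic(ph, self.bottom, self.top, self.ph50,
                                   self.hill)


def fit_calibration(measurements: Sequence[tuple[float, float]]
                    ) -> CalibrationCurve:
    """Least-squares fit of the four-parameter model to (pH, ratio) points.

    Requires at least 5 distinct pH values spanning at least 1.5 pH units.
    Initialization is data-driven (asymptotes from the extreme ratios, ph50
    from the median pH, hill 1), so the fit is deterministic given inputs.
    """
    pts = np.asarray(measurements, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("measurements must be (pH, ratio) pairs")
    ph, ratio = pts[:, 0], pts[:, 1]
    distinct = np.unique(ph)
    if len(distinct) < 5:
        raise ValueError(
            f"need >= 5 distinct pH values for a 4-parameter fit, got "
            f"{len(distinct)}")
    if distinct.max() - distinct.min() < 1.5:
        raise ValueError("calibration pH values must span >= 1.5 pH units")

    order = np.argsort(ph)
    lo_mean = ratio[order][:max(len(ph) // 4, 1)].mean()
    hi_mean = ratio[order][-max(len(ph) // 4, 1):].mean()
    p0 = [min(lo_mean, hi_mean), max(hi_mean, lo_mean * 1.01 + 1e-3),
          float(np.median(ph)), 1.0]
    try:
        popt, _ = curve_fit(four_param_logistic, ph, ratio, p0=p0,
                            maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"calibration fit did not converge: {exc}") from None
    bottom, top, ph50, hill = (float(v) for v in popt)
    if hill < 0:  # equivalent curve with swapped asymptotes
        bottom, top, hill = top, bottom, -hill
    if top <= bottom:
        raise RuntimeError(
            f"degenerate calibration fit: top {top:.4g} <= bottom "
            f"{bottom:.4g}")
    if not distinct.min() - 2.0 <= ph50 <= distinct.max() + 2.0:
        raise RuntimeError(
            f"calibration inflection ph50={ph50:.2f} far outside the fitted "
            f"pH range [{distinct.min()}, {distinct.max()}]")
    resid = ratio - four_param_logistic(ph, bottom, top, ph50, hill)
    return CalibrationCurve(bottom, top, ph50, hill,
                            residual_rms=float(np.sqrt(np.mean(resid ** 2))),
                            n_points=len(ph))


def ratio_to_ph(ratio, curve: CalibrationCurve,
                with_flags: bool = False):
    """Invert the calibration curve: ratio -> pH (strictly increasing).

    Ratios at or outside (bottom, top) are clipped just inside the domain
    and flagged out-of-range; request ``with_flags=True`` to receive the
    flag array alongside the pH values.
    """
    arr = np.asarray(ratio, dtype=float)
    span = curve.top - curve.bottom
    eps = 1e-6 * span
    out_of_range = (arr <= curve.bottom + eps) | (arr >= curve.top - eps)
    clipped = np.clip(arr, curve.bottom + eps, curve.top - eps)
    ph = curve.ph50 - np.log10(span / (clipped - curve.bottom) - 1.0) \
        / curve.hill
    if arr.ndim == 0:
        ph, out_of_range = float(ph), bool(out_of_range)
    if with_flags:
        return ph, out_of_range
    return ph


# ---------------------------------------------------------------------------
# Ratio measurement and pH traces
# ---------------------------------------------------------------------------

def measure_ratio(stack, roi: Geometry, field_bg_roi: Geometry,
                  yfp_channel: str = "yfp", cfp_channel: str = "cfp",
                  lumen_shrink_px: float = 1.0,
                  band_width_px: float = 2.0,
                  frames: Sequence[int] | None = None) -> pd.DataFrame:
    """Per-frame background-corrected luminal YFP/CFP ratio.

    For a closed ROI the luminal pool is the boundary eroded by
    ``lumen_shrink_px``; for a segmented-line ROI (e.g. a Golgi ribbon) a
    band of width ``band_width_px`` along the line is sampled instead.  The
    field background (a cell-free region) is subtracted channel-wise; frames
    whose corrected CFP is not positive are flagged invalid.

    Columns: frame, time_min, yfp_value, cfp_value, ratio, valid.
    """
    shape = stack.pixels.shape[2:]
    if isinstance(roi, PolylineRoi):
        meas_set = band_pixels(roi, shape, band_width_px)
    else:
        meas_set = lumen_pixels(roi, shape, lumen_shrink_px)
    bg_set = region_pixels(field_bg_roi, shape)

    iy = stack.channel_names.index(yfp_channel)
    ic = stack.channel_names.index(cfp_channel)
    if frames is None:
        frames = range(stack.n_frames)

    rows = []
    for f in frames:
        yimg, cimg = stack.pixels[f, iy], stack.pixels[f, ic]
        yv = float(meas_set.values(yimg).mean() - bg_set.values(yimg).mean())
        cv = float(meas_set.values(cimg).mean() - bg_set.values(cimg).mean())
        valid = cv > 0
        if not valid:
            logger.warning("frame %d flagged invalid: corrected CFP %.3g "
                           "<= 0", f, cv)
        rows.append({"frame": f, "time_min": f * stack.frame_interval_min,
                     "yfp_value": yv, "cfp_value": cv,
                     "ratio": yv / cv if valid else np.nan,
                     "valid": valid})
    return pd.DataFrame(rows)


def ph_trace(ratio_measurements: pd.DataFrame,
             curve: CalibrationCurve) -> pd.DataFrame:
    """Convert a per-frame ratio table to a pH time series.

    Invalid frames keep NaN pH; out-of-range ratios receive the clipped
    domain-edge pH with ``out_of_range=True``.  Raises when every frame is
    invalid.
    """
    df = ratio_measurements.copy()
    valid = df["valid"].to_numpy(bool)
    if not valid.any():
        raise ValueError("all frames invalid: no measurable ratio")
    ph = np.full(len(df), np.nan)
    flags = np.zeros(len(df), dtype=bool)
    ph_v, fl_v = ratio_to_ph(df.loc[valid, "ratio"].to_numpy(float), curve,
                             with_flags=True)
    ph[valid] = ph_v
    flags[valid] = fl_v
    df["ph"] = ph
    df["out_of_range"] = flags
    return df
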