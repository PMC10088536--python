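"""Depot appearance kinetics from intensity traces.

The injected drug is hyperechoic, so its arrival raises the image intensity.
Two scalar traces drive the analysis:

* the normalized percent intensity variation in a region of interest around
  the needle tip,

      dI(t) = 100 * (I_t - I_0) / I_0,

  where I_t is the mean ROI intensity of frame t and I_0 that of the first
  frame.  Smoothed with a 1-s moving average (to suppress heartbeat
  modulation), a video is retained for analysis only when the smoothed trace
  rises strictly above 20%;

* the background-subtracted mean cone intensity mu(t), fit from injection
  onset with the exponential-plateau uptake model

      mu(t) = c + a * (1 - exp(-b t)).

The injection duration is the time for the model to reach 95% of its
asymptote above the offset, dt = ln(20) / b, and the (assumed constant)
volumetric flow rate is Q = injected volume / dt.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import curve_fit

from .io import RegionOfInterest, VideoSequence

__all__ = [
    "IntensityTrace",
    "UptakeFit",
    "FlowEstimate",
    "intensity_variation",
    "moving_average",
    "passes_inclusion",
    "mean_cone_trace",
    "fit_uptake",
    "flow_rate",
    "detect_onset",
    "LN20",
]

LN20 = math.log(20.0)  # dt * b for the 95%-of-asymptote duration


@dataclass
class IntensityTrace:
    """Uniformly sampled scalar intensity statistic.

    values are percent for the ROI variation trace and normalized intensity
    for the cone-mean trace; ``region`` records which ("roi" | "cone").
    """

    times: np.ndarray
    values: np.ndarray
    smoothing_window: float | None = None
    region: str = "roi"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same length")
        if self.times.size >= 2:
            dt = np.diff(self.times)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
                raise ValueError("times must be strictly increasing with uniform spacing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")

    @property
    def frame_rate(self) -> float:
        if self.times.size < 2:
            raise ValueError("need at least two samples to infer a frame rate")
        return 1.0 / float(self.times[1] - self.times[0])

    def to_csv(self, path: str | Path) -> Path:
        import pandas as pd

        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {"time_s": self.times, "value": self.values, "smoothed": self.smoothing_window is not None}
        ).to_csv(path, index=False)
        return path


@dataclass
class UptakeFit:
    """Exponential-plateau fit mu(t) = c + a (1 - e^{-bt})."""

    a: float
    b: float
    c: float
    r_squared: float
    delta_t: float
    residuals: np.ndarray = field(repr=False, default=None)
    at_boundary: bool = False

    def to_json(self, path: str | Path, q_ml_per_s: float | None = None) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        d = {
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "r_squared": self.r_squared,
            "delta_t_s": self.delta_t,
        }
        if q_ml_per_s is not None:
            d["q_ml_per_s"] = q_ml_per_s
        path.write_text(json.dumps(d, indent=2))
        return path


@dataclass(frozen=True)
class FlowEstimate:
    """Constant-rate flow estimate Q = injected volume / dt."""

    q_ml_per_s: float
    injected_volume_ml: float
    delta_t_s: float


def uptake_model(t: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    """mu(t) = c + a (1 - e^{-bt})."""
    return c + a * (1.0 - np.exp(-b * np.asarray(t, dtype=np.float64)))


def intensity_variation(video: VideoSequence, roi: RegionOfInterest) -> IntensityTrace:
    """Percent intensity variation of the ROI mean relative to frame 0."""
    if video.n_frames < 2:
        raise ValueError("need at least two frames")
    sub = video.frames[(slice(None),) + roi.slices]
    means = sub.mean(axis=(1, 2))
    if means[0] == 0:
        raise ValueError("mean ROI intensity of the first frame is zero (degenerate reference)")
    values = 100.0 * (means - means[0]) / means[0]
    return IntensityTrace(times=video.times, values=values, region="roi")


def moving_average(trace: IntensityTrace, window: float = 1.0) -> IntensityTrace:
    """Centered moving mean over round(window * frame_rate) samples.

    Edges use shrinking windows (mean over the available samples), so a
    constant trace is exactly preserved.
    """
    fr = trace.frame_rate
    n = int(round(window * fr))
    if n < 1:
        raise ValueError("window must cover at least one sample")
    kernel = np.ones(n)
    num = np.convolve(trace.values, kernel, mode="same")
    den = np.convolve(np.ones_like(trace.values), kernel, mode="same")
    return IntensityTrace(
        times=trace.times, values=num / den, smoothing_window=window, region=trace.region
    )


def passes_inclusion(
    trace: IntensityTrace, threshold_pct: float = 20.0
) -> tuple[bool, float]:
    """Screening rule: keep a video iff its smoothed percent-variation trace
    rises strictly above the threshold.  Returns (decision, achieved max)."""
    if trace.smoothing_window is None:
        warnings.warn("inclusion criterion applied to an unsmoothed trace", stacklevel=2)
    peak = float(np.max(trace.values))
    return peak > threshold_pct, peak


def mean_cone_trace(
    video: VideoSequence, background: np.ndarray, t0: float
) -> IntensityTrace:
    """Background-subtracted mean cone intensity mu(t) from injection onset.

    For each frame at or after t0, the mean over the cone mask of the frame
    minus the mean over the cone mask of the background image; times are
    re-zeroed so that t0 maps to 0.
    """
    cone = video.cone_mask
    if not cone.any():
        raise ValueError("empty cone mask")
    i0 = video.frame_index(t0)
    if i0 >= video.n_frames - 1:
        raise ValueError("t0 at or beyond the last frame: no post-onset samples")
    bg_mean = float(np.asarray(background, dtype=np.float64)[cone].mean())
    vals = video.frames[i0:][:, cone].mean(axis=1) - bg_mean
    times = video.times[i0:] - t0
    return IntensityTrace(times=times, values=vals, region="cone")


def fit_uptake(trace: IntensityTrace, max_restarts: int = 3) -> UptakeFit:
    """Least-squares fit of the exponential-plateau model to a trace.

    Constraints a >= 0, b > 0.  Initialization: c0 = first sample,
    a0 = last minus first, b0 = ln(20) / (duration / 2), with a multi-start
    over b0 * {0.2, 1, 5} if the first attempt fails to converge.  R^2 is
    computed on the (unsmoothed) input trace.
    """
    t = trace.times - trace.times[0]
    y = trace.values
    if t.size < 5:
        raise ValueError("need at least 5 samples to fit the uptake model")
    duration = float(t[-1])
    c0 = float(y[0])
    a0 = max(float(y[-1] - y[0]), 1e-12)
    b_base = LN20 / (duration / 2.0)
    bounds = ([0.0, 1e-12, -np.inf], [np.inf, np.inf, np.inf])

    best = None
    errors = []
    for mult in (1.0, 0.2, 5.0)[: max_restarts]:
        try:
            popt, _ = curve_fit(
                uptake_model, t, y, p0=[a0, b_base * mult, c0], bounds=bounds, maxfev=20000
            )
        except RuntimeError as exc:
            errors.append(str(exc))
            continue
        resid = y - uptake_model(t, *popt)
        ssr = float(resid @ resid)
        if best is None or ssr < best[1]:
            best = (popt, ssr, resid)
    if best is None:
        raise RuntimeError(
            "uptake fit failed to converge after restarts: " + "; ".join(errors)
        )
    (a, b, c), ssr, resid = best
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else 1.0
    r2 = float(min(max(r2, 0.0), 1.0))
    at_boundary = b <= 2e-12
    return UptakeFit(
        a=float(a),
        b=float(b),
        c=float(c),
        r_squared=r2,
        delta_t=LN20 / float(b),
        residuals=resid,
        at_boundary=at_boundary,
    )


def flow_rate(injected_volume_ml: float, fit: UptakeFit) -> FlowEstimate:
    """Constant volumetric flow rate Q = injected volume / dt (mL/s)."""
    if injected_volume_ml <= 0:
        raise ValueError("injected_volume_ml must be positive")
    if fit.delta_t <= 0:
        raise ValueError("delta_t must be positive")
    return FlowEstimate(
        q_ml_per_s=injected_volume_ml / fit.delta_t,
        injected_volume_ml=injected_volume_ml,
        delta_t_s=fit.delta_t,
    )


def detect_onset(
    trace: IntensityTrace, rise_pct: float = 5.0, hold_s: float = 1.0
) -> float:
    """Detect injection onset from a smoothed percent-variation trace.

    Onset is the first time the trace exceeds ``rise_pct`` and stays above it
    for ``hold_s`` seconds, backtracked to the preceding local minimum.  Used
    only when the annotation does not provide t0.
    """
    fr = trace.frame_rate
    hold_n = max(int(round(hold_s * fr)), 1)
    above = trace.values > rise_pct
    # first index where `above` holds for hold_n consecutive samples
    run = 0
    start = None
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= hold_n:
            start = i - hold_n + 1
            break
    if start is None:
        raise ValueError("no sustained rise found; cannot detect injection onset")
    j = start
    while j > 0 and trace.values[j - 1] <= trace.values[j]:
        j -= 1
    return float(trace.times[j])
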