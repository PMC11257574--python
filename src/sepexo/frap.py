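"""FRAP (fluorescence recovery after photobleaching) kinetics.

A trace consists of bleach-ROI, unbleached-reference and background
intensities over time, with a handful of pre-bleach frames.  The pipeline
is: (1) correct for background and acquisition photobleaching against the
reference; (2) normalize the mean pre-bleach intensity to 100% and the
first post-bleach intensity to 0%; (3) rolling-average post-bleach points
to reduce noise; (4) fit the single-exponential recovery

    y = m1 + m2 * exp(-m3 * t)

with t = 0 at the first post-bleach frame, m3 the off-rate (1/s) and the
recovery half-time t_1/2 = ln 2 / m3.

When the fit consumes the smoothed series it applies the same rolling
average to the model prediction inside the least squares, so smoothing
introduces no parameter bias (noiseless traces are recovered exactly).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "FRAPTrace",
    "FRAPFit",
    "correct_trace",
    "normalize_trace",
    "rolling_average",
    "fit_recovery",
    "analyze_trace",
]


@dataclass
class FRAPTrace:
    """Raw FRAP measurement: acquisition times (s) and three ROI series."""

    times: np.ndarray
    bleach: np.ndarray
    reference: np.ndarray
    background: np.ndarray
    n_prebleach: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.bleach = np.asarray(self.bleach, float)
        self.reference = np.asarray(self.reference, float)
        self.background = np.asarray(self.background, float)
        n = self.times.size
        if not (self.bleach.size == self.reference.size == self.background.size == n):
            raise ValueError("all trace series must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.n_prebleach < 1:
            raise ValueError("need at least one pre-bleach frame")
        if n - self.n_prebleach < 5:
            raise ValueError("need at least 5 post-bleach points")

    @property
    def post_times(self) -> np.ndarray:
        """Post-bleach times with t = 0 at the first post-bleach frame."""
        post = self.times[self.n_prebleach:]
        return post - post[0]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "time_s": self.times,
                "bleach": self.bleach,
                "reference": self.reference,
                "background": self.background,
                "prebleach": (np.arange(self.times.size) < self.n_prebleach).astype(int),
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FRAPTrace":
        df = pd.read_csv(path)
        return cls(
            times=df["time_s"].to_numpy(),
            bleach=df["bleach"].to_numpy(),
            reference=df["reference"].to_numpy(),
            background=df["background"].to_numpy(),
            n_prebleach=int(df["prebleach"].sum()),
        )


@dataclass
class FRAPFit:
    """Fitted recovery: plateau m1, amplitude m2 (< 0), off-rate m3 (1/s)."""

    m1: float
    m2: float
    m3: float
    residual_rms: float
    converged: bool

    def __post_init__(self) -> None:
        if self.converged and self.m3 <= 0:
            raise ValueError("a converged fit must have m3 > 0")

    @property
    def t_half(self) -> float:
        return math.log(2.0) / self.m3


def correct_trace(trace: FRAPTrace) -> np.ndarray:
    """Background and acquisition-photobleaching correction.

    corrected(t) = (bleach - background) * Rbar / (reference - background),
    with Rbar the mean pre-bleach background-subtracted reference, so a
    reference decay during acquisition is divided out while the pre-bleach
    intensity scale is preserved.
    """
    ref = trace.reference - trace.background
    bad = np.nonzero(ref <= 0)[0]
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"reference does not exceed background at timepoint {i} "
            f"(t = {trace.times[i]:g} s)"
        )
    rbar = float(ref[: trace.n_prebleach].mean())
    return (trace.bleach - trace.background) * rbar / ref


def normalize_trace(corrected: np.ndarray, n_prebleach: int) -> np.ndarray:
    """Affine map sending mean pre-bleach -> 100 and first post-bleach -> 0."""
    corrected = np.asarray(corrected, float)
    if n_prebleach < 1 or n_prebleach >= corrected.size:
        raise ValueError("invalid pre-bleach frame count")
    pre = float(corrected[:n_prebleach].mean())
    first_post = float(corrected[n_prebleach])
    if pre <= first_post:
        raise ValueError(
            f"mean pre-bleach ({pre:g}) does not exceed first post-bleach "
            f"({first_post:g}); no bleach detected"
        )
    return 100.0 * (corrected - first_post) / (pre - first_post)


def rolling_average(
    values: np.ndarray, window: int = 3, n_prebleach: int = 0
) -> np.ndarray:
    """Centered moving mean over the post-bleach points only.

    Pre-bleach points pass through untouched; at the ends of the post-bleach
    segment the window shrinks to the available points.
    """
    values = np.asarray(values, float)
    if window < 1:
        raise ValueError("window must be >= 1")
    post = values[n_prebleach:]
    if post.size < window:
        raise ValueError("fewer post-bleach points than the smoothing window")
    half = (window - 1) // 2
    upper = window - 1 - half
    smoothed = np.array(
        [post[max(0, i - half): min(post.size, i + upper + 1)].mean() for i in range(post.size)]
    )
    return np.concatenate([values[:n_prebleach], smoothed])


def _initial_guess(times: np.ndarray, values: np.ndarray) -> tuple[float, float, float]:
    """Deterministic start: plateau from the tail, rate from a log-linear fit."""
    n_tail = max(1, values.size // 10)
    m1 = float(values[-n_tail:].mean())
    m2 = float(values[0] - m1)
    gap = m1 - values
    # log-linear regression of m1 - y over points still far from the plateau
    mask = gap > 0.05 * max(abs(m2), 1e-12)
    if mask.sum() >= 2 and m2 < 0:
        slope = np.polyfit(times[mask], np.log(gap[mask]), 1)[0]
        m3 = max(-float(slope), 1e-6)
    else:
        span = float(times[-1] - times[0]) or 1.0
        m3 = 5.0 * math.log(2.0) / span
    return m1, m2, m3


def fit_recovery(
    times: np.ndarray,
    values: np.ndarray,
    model_smoothing_window: int | None = None,
) -> FRAPFit:
    """Least-squares fit of y = m1 + m2 exp(-m3 t) to post-bleach data.

    ``times`` are post-bleach seconds with t = 0 at the first post-bleach
    frame.  If ``model_smoothing_window`` is given, the model prediction is
    passed through the same centered rolling average as the data before
    computing residuals, so fitting a smoothed series stays unbiased.
    Non-convergence is reported through the ``converged`` flag.
    """
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    if times.size != values.size:
        raise ValueError("times and values must have equal length")
    if times.size < 5:
        raise ValueError("need at least 5 post-bleach points to fit 3 parameters")
    if np.allclose(values, values[0]):
        raise ValueError("all values equal; recovery fit is degenerate")

    def predict(params: np.ndarray) -> np.ndarray:
        m1, m2, m3 = params
        y = m1 + m2 * np.exp(-m3 * times)
        if model_smoothing_window and model_smoothing_window > 1:
            y = rolling_average(y, window=model_smoothing_window)
        return y

    x0 = np.array(_initial_guess(times, values))
    result = least_squares(
        lambda p: predict(p) - values,
        x0,
        bounds=([-np.inf, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    m1, m2, m3 = (float(v) for v in result.x)
    rms = float(np.sqrt(np.mean(result.fun**2)))
    return FRAPFit(m1=m1, m2=m2, m3=m3, residual_rms=rms, converged=bool(result.success))


def analyze_trace(
    trace: FRAPTrace, smooth: bool = True, window: int = 3
) -> tuple[FRAPFit, np.ndarray, np.ndarray]:
    """Full pipeline: correct -> normalize -> smooth -> fit.

    Returns the fit plus the post-bleach times and the (smoothed) normalized
    post-bleach series that were fitted.  ``smooth=False`` fits the raw
    normalized series.
    """
    corrected = correct_trace(trace)
    normalized = normalize_trace(corrected, trace.n_prebleach)
    if smooth:
        normalized = rolling_average(normalized, window=window, n_prebleach=trace.n_prebleach)
    post = normalized[trace.n_prebleach:]
    times = trace.post_times
    fit = fit_recovery(times, post, model_smoothing_window=window if smooth else None)
    return fit, times, post
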