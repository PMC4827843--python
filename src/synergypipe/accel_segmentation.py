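"""Gait-event detection and acceleration metrics from tibial accelerometry.

Foot strikes are found from the impact transient: candidate minima below
an adaptive threshold estimate the stride, and the strike is then refined
to the positive derivative peak immediately preceding each minimum. Gait
cycles run from one ipsilateral strike to the next and are time-normalized
to 200 points (0-100% of the cycle).
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .core import AccelTrace, GaitCycles


class NoStrikesError(ValueError):
    """Raised when no foot-strike candidates are found."""


class InsufficientCyclesError(ValueError):
    """Raised when fewer than two strikes (one cycle) are detected."""


def lowpass_accel(trace: AccelTrace, cutoff_hz: float = 60.0, order: int = 2) -> AccelTrace:
    """Zero-lag (forward-backward) Butterworth low-pass filter.

    The default 60 Hz cutoff keeps the impact transient sharp while
    removing sensor noise.
    """
    nyq = trace.fs / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ValueError(f"cutoff must lie in (0, {nyq}) Hz")
    sos = sps.butter(order, cutoff_hz, btype="low", fs=trace.fs, output="sos")
    return AccelTrace(sps.sosfiltfilt(sos, trace.samples), trace.fs)


def detect_foot_strikes(
    trace: AccelTrace,
    threshold_sd: float = 2.0,
    min_spacing_s: float = 0.5,
    derivative_window_s: float = 0.05,
    min_period_s: float = 0.3,
    max_period_s: float = 2.0,
) -> GaitCycles:
    """Detect foot strikes in a low-pass-filtered acceleration trace.

    1. Candidate impact minima: samples below mean - threshold_sd * SD,
       separated by at least ``min_spacing_s``.
    2. The trace is differentiated (first differences).
    3. Each strike is the sample of the largest positive derivative peak
       in the ``derivative_window_s`` window immediately preceding its
       minimum (the pre-impact rise); if the window holds no positive
       derivative the minimum itself is used.
    """
    x = trace.samples
    thr = x.mean() - threshold_sd * x.std()
    distance = max(int(round(min_spacing_s * trace.fs)), 1)
    minima, _ = sps.find_peaks(-x, height=-thr, distance=distance)
    if minima.size == 0:
        raise NoStrikesError("no acceleration minima below the adaptive threshold")
    if minima.size < 2:
        raise InsufficientCyclesError("fewer than 2 strikes: no complete gait cycle")

    deriv = np.diff(x)
    win = max(int(round(derivative_window_s * trace.fs)), 1)
    strikes = []
    for m in minima:
        lo = max(m - win, 0)
        seg = deriv[lo:m]
        if seg.size and seg.max() > 0:
            strikes.append(lo + int(np.argmax(seg)))
        else:
            strikes.append(int(m))
    strikes = np.unique(strikes)
    if strikes.size < 2:
        raise InsufficientCyclesError("fewer than 2 strikes after refinement")
    return GaitCycles(strikes, trace.fs, min_period_s, max_period_s)


def peak_negative_acceleration(
    trace: AccelTrace, cycles: GaitCycles, window_s: float = 0.025
) -> np.ndarray:
    """Per-cycle magnitude of the impact dip, in g.

    For each strike bounding a cycle, the most negative filtered sample
    within +/- ``window_s`` of the strike is found and its magnitude
    returned (0 if the window never goes negative).
    """
    if cycles.n_cycles < 1:
        raise ValueError("need at least one gait cycle")
    half = max(int(round(window_s * trace.fs)), 1)
    out = np.empty(cycles.n_cycles)
    for i, s in enumerate(cycles.strike_samples[:-1]):
        lo, hi = max(s - half, 0), min(s + half + 1, trace.n_samples)
        m = trace.samples[lo:hi].min()
        out[i] = -m if m < 0 else 0.0
    return out


def normalize_cycle(segment: np.ndarray, n_points: int = 200) -> np.ndarray:
    """Resample one cycle onto ``n_points`` equally spaced samples.

    Linear interpolation over the segment, inclusive of both endpoints;
    works on 1-D segments or 2-D (time x channels) blocks.
    """
    segment = np.asarray(segment, dtype=float)
    n = segment.shape[0]
    if n < 2:
        raise ValueError("segment must contain at least 2 samples")
    u = np.linspace(0.0, n - 1, n_points)
    base = np.arange(n)
    if segment.ndim == 1:
        return np.interp(u, base, segment)
    return np.column_stack(
        [np.interp(u, base, segment[:, j]) for j in range(segment.shape[1])]
    )


def window_to_samples(window: tuple[float, float], n_points: int = 200) -> slice:
    """Map a [lo%, hi%] cycle window onto 0-based inclusive sample indices.

    [a, b] maps to samples floor(a/100 * n) .. ceil(b/100 * n) - 1, so
    0-35% covers samples 0-69 and 91-100% covers samples 182-199 of a
    200-point cycle.
    """
    a, b = window
    if not (0 <= a < b <= 100):
        raise ValueError("window must satisfy 0 <= lo < hi <= 100")
    lo = int(np.floor(a / 100.0 * n_points))
    hi = int(np.ceil(b / 100.0 * n_points))
    return slice(lo, hi)


def cycle_variability(
    cycle_stack: np.ndarray,
    window: tuple[float, float],
    mean_tol: float = 1e-12,
) -> float:
    """Stride-to-stride coefficient of variation (%) within a cycle window.

    ``cycle_stack`` is (n_cycles x n_points) of time-normalized cycles.
    The CV at each normalized time sample is the across-cycle sample SD
    (n-1 denominator) of the absolute signal divided by its across-cycle
    mean; the window average is returned as a percentage. Absolute values
    avoid near-zero-mean blowups in signed acceleration. Samples whose
    mean magnitude falls below ``mean_tol`` are excluded; if every sample
    in the window is excluded an error is raised.
    """
    stack = np.abs(np.asarray(cycle_stack, dtype=float))
    if stack.ndim != 2 or stack.shape[0] < 2:
        raise ValueError("need a 2-D stack with at least 2 cycles")
    sl = window_to_samples(window, stack.shape[1])
    seg = stack[:, sl]
    mean = seg.mean(axis=0)
    sd = seg.std(axis=0, ddof=1)
    ok = mean > mean_tol
    if not ok.any():
        raise ValueError("all samples in window have near-zero mean magnitude")
    return float((sd[ok] / mean[ok]).mean() * 100.0)
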