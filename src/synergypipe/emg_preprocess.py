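"""EMG conditioning: band-pass, envelope, cycle segmentation, normalization.

Raw EMG is band-pass filtered (10-500 Hz, second-order zero-lag
Butterworth), full-wave rectified and low-pass filtered at 10 Hz to give
the linear envelope; envelopes are cut at foot strikes, time-normalized
to 200 points per cycle, concatenated across cycles, and amplitude-
normalized per muscle to [0, 1] before factorization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import CycleTensor, EmgRecording, GaitCycles
from .accel_segmentation import normalize_cycle


@dataclass
class MuscleMetrics:
    """Single-muscle amplitude summaries on a common reference scale.

    Both conditions' mean-cycle curves are divided by the reference
    condition's mean amplitude per muscle, so peak and integrated EMG are
    dimensionless and directly comparable; the *_pct_of_reference fields
    express the analysed condition as a percentage of the reference.
    """

    channel_labels: tuple[str, ...]
    peak_emg: np.ndarray
    integrated_emg: np.ndarray
    peak_pct_of_reference: np.ndarray
    integrated_pct_of_reference: np.ndarray


def bandpass_emg(
    recording: EmgRecording, lo: float = 10.0, hi: float = 500.0, order: int = 2
) -> EmgRecording:
    """Zero-lag band-pass filter per channel.

    A second-order Butterworth design applied forward-backward
    (effective fourth order, zero phase).
    """
    nyq = recording.fs / 2.0
    if not 0 < lo < hi < nyq:
        raise ValueError(f"band edges must satisfy 0 < lo < hi < {nyq}")
    sos = sps.butter(order, [lo, hi], btype="band", fs=recording.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, recording.samples, axis=0)
    return EmgRecording(filtered, recording.fs, recording.channel_labels)


def envelope(recording: EmgRecording, lp: float = 10.0, order: int = 2) -> EmgRecording:
    """Linear envelope: full-wave rectification then zero-lag low-pass.

    Filter ringing can push the rectified-then-filtered signal slightly
    negative; negative values are clamped to zero (with a warning) since
    the factorization requires nonnegative input.
    """
    nyq = recording.fs / 2.0
    if not 0 < lp < nyq:
        raise ValueError(f"low-pass cutoff must lie in (0, {nyq})")
    sos = sps.butter(order, lp, btype="low", fs=recording.fs, output="sos")
    env = sps.sosfiltfilt(sos, np.abs(recording.samples), axis=0)
    if np.any(env < 0):
        worst = -env.min() / max(env.max(), 1e-300)
        if worst > 0.01:
            warnings.warn(
                f"envelope ringing reached {worst:.1%} of the signal maximum "
                "below zero; clamped to 0"
            )
        env = np.clip(env, 0.0, None)
    return EmgRecording(env, recording.fs, recording.channel_labels)


def segment_and_normalize(
    env: EmgRecording, cycles: GaitCycles, n_points: int = 200
) -> CycleTensor:
    """Cut envelopes at foot strikes and time-normalize each cycle.

    Each strike-to-strike interval becomes one (n_points x n_muscles)
    block via linear-interpolation resampling.
    """
    strikes = cycles.strike_samples
    if strikes.size < 2:
        raise ValueError("need at least two strikes (one complete cycle)")
    if strikes[0] < 0 or strikes[-1] > env.n_samples:
        raise ValueError("strike samples fall outside the recording")
    blocks = []
    for s0, s1 in zip(strikes[:-1], strikes[1:]):
        blocks.append(normalize_cycle(env.samples[s0:s1], n_points))
    return CycleTensor(np.stack(blocks), env.channel_labels)


def select_consecutive_cycles(tensor: CycleTensor, n: int = 20, start: int = 0) -> CycleTensor:
    """Keep ``n`` consecutive cycles starting at ``start``."""
    if tensor.n_cycles < start + n:
        raise ValueError(
            f"requested cycles {start}..{start + n - 1} but only "
            f"{tensor.n_cycles} available"
        )
    return CycleTensor(
        tensor.envelopes[start : start + n],
        tensor.channel_labels,
        tensor.normalization,
    )


def drop_outlier_cycles(tensor: CycleTensor, sd_limit: float = 3.0) -> CycleTensor:
    """Drop cycles whose envelope RMS deviates > sd_limit SDs from the median.

    An automated stand-in for visual rejection of erroneous envelopes;
    off by default in the pipeline.
    """
    rms = np.sqrt((tensor.envelopes**2).mean(axis=(1, 2)))
    med = np.median(rms)
    sd = rms.std(ddof=1) if tensor.n_cycles > 1 else 0.0
    keep = np.abs(rms - med) <= sd_limit * sd if sd > 0 else np.ones(len(rms), bool)
    if not keep.all():
        warnings.warn(f"dropped {int((~keep).sum())} outlier cycle(s)")
    return CycleTensor(tensor.envelopes[keep], tensor.channel_labels, tensor.normalization)


def amplitude_normalize(tensor: CycleTensor) -> CycleTensor:
    """Scale each muscle so its concatenated envelope peaks at 1.

    The divisor is the muscle's overall maximum over the concatenated
    series; divisors are stored on the tensor for traceability. Each
    condition is normalized separately, so both attain max 1.
    """
    maxima = tensor.envelopes.max(axis=(0, 1))
    zero = maxima <= 0
    if zero.any():
        bad = [tensor.channel_labels[i] for i in np.flatnonzero(zero)]
        raise ValueError(f"all-zero signal for channel(s): {', '.join(bad)}")
    return CycleTensor(
        tensor.envelopes / maxima,
        tensor.channel_labels,
        tensor.normalization * maxima,
    )


def muscle_metrics(tensor: CycleTensor, reference_tensor: CycleTensor) -> MuscleMetrics:
    """Peak and integrated EMG per muscle on the reference condition's scale.

    Both conditions' across-cycle mean curves are divided, per muscle, by
    the reference condition's mean-cycle mean amplitude. Peak EMG is the
    maximum of the normalized mean curve; integrated EMG is its mean over
    the normalized cycle (the dimensionless %-cycle integral). The
    *_pct_of_reference outputs give the analysed condition as a percent
    of the reference condition's corresponding value.
    """
    if tensor.channel_labels != reference_tensor.channel_labels:
        raise ValueError("tensors must share muscle labels and ordering")
    ref_mean = reference_tensor.mean_cycle  # (n_points, n_muscles)
    divisor = ref_mean.mean(axis=0)
    if np.any(divisor <= 0):
        bad = [
            tensor.channel_labels[i] for i in np.flatnonzero(divisor <= 0)
        ]
        raise ValueError(f"zero reference amplitude for: {', '.join(bad)}")
    cur = tensor.mean_cycle / divisor
    ref = ref_mean / divisor
    peak, ref_peak = cur.max(axis=0), ref.max(axis=0)
    integ, ref_integ = cur.mean(axis=0), ref.mean(axis=0)
    return MuscleMetrics(
        channel_labels=tensor.channel_labels,
        peak_emg=peak,
        integrated_emg=integ,
        peak_pct_of_reference=100.0 * peak / ref_peak,
        integrated_pct_of_reference=100.0 * integ / ref_integ,
    )
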