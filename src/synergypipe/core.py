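"""Shared containers for EMG and acceleration time series.

The canonical recording montage is 11 ipsilateral lower-limb muscles
(TA, PL, SO, GL, GM, VL, VM, RF, BF, ST, GX) sampled at 2 kHz together
with a uniaxial tibial accelerometer, but the containers are generic in
channel count and sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical muscle order used throughout: tibialis anterior, peroneus
#: longus, soleus, gastrocnemius lateralis/medialis, vastus lateralis/
#: medialis, rectus femoris, biceps femoris, semitendinosus, gluteus maximus.
CANONICAL_MUSCLES = ("TA", "PL", "SO", "GL", "GM", "VL", "VM", "RF", "BF", "ST", "GX")


@dataclass
class EmgRecording:
    """Multichannel EMG time series.

    Parameters
    ----------
    samples : ndarray, shape (n_samples, n_channels)
        Signal per channel; raw EMG or envelope-level depending on stage.
    fs : float
        Sampling rate in Hz.
    channel_labels : tuple of str
        Ordered muscle names, unique.
    """

    samples: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (time x channels)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != self.samples.shape[1]:
            raise ValueError("channel_labels length must match channel count")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def to_frame(self) -> pd.DataFrame:
        t = np.arange(self.n_samples) / self.fs
        df = pd.DataFrame(self.samples, columns=list(self.channel_labels))
        df.insert(0, "time_s", t)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, fs: float | None = None) -> "EmgRecording":
        if "time_s" not in df.columns:
            raise ValueError("expected a 'time_s' column")
        t = df["time_s"].to_numpy(dtype=float)
        if fs is None:
            if len(t) < 2:
                raise ValueError("cannot infer sampling rate from <2 samples")
            fs = 1.0 / float(np.median(np.diff(t)))
        channels = [c for c in df.columns if c != "time_s"]
        return cls(df[channels].to_numpy(dtype=float), fs, tuple(channels))


@dataclass
class AccelTrace:
    """Uniaxial acceleration time series in g."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]


@dataclass
class GaitCycles:
    """Foot-strike sample indices; consecutive strikes bound one gait cycle.

    Spacing between strikes is validated against configurable physiologic
    bounds (default 0.3-2.0 s) so spurious detections fail loudly.
    """

    strike_samples: np.ndarray
    fs: float
    min_period_s: float = 0.3
    max_period_s: float = 2.0

    def __post_init__(self) -> None:
        self.strike_samples = np.asarray(self.strike_samples, dtype=int).ravel()
        if np.any(np.diff(self.strike_samples) <= 0):
            raise ValueError("strike samples must be strictly increasing")
        periods = np.diff(self.strike_samples) / self.fs
        if periods.size and (
            periods.min() < self.min_period_s or periods.max() > self.max_period_s
        ):
            raise ValueError(
                f"strike spacing outside physiologic bounds "
                f"[{self.min_period_s}, {self.max_period_s}] s"
            )

    @property
    def n_cycles(self) -> int:
        return max(len(self.strike_samples) - 1, 0)

    @property
    def strike_times_s(self) -> np.ndarray:
        return self.strike_samples / self.fs


@dataclass
class CycleTensor:
    """Per-cycle, time-normalized EMG envelope stack.

    ``envelopes`` holds one (n_points x n_muscles) block per gait cycle;
    ``concatenated`` is the muscles x (n_cycles*n_points) matrix handed to
    the factorization. ``normalization`` records the per-muscle divisor
    applied by amplitude normalization (ones if not yet normalized).
    """

    envelopes: np.ndarray  # (n_cycles, n_points, n_muscles)
    channel_labels: tuple[str, ...]
    normalization: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.envelopes = np.asarray(self.envelopes, dtype=float)
        if self.envelopes.ndim != 3:
            raise ValueError("envelopes must be 3-D (cycles x time x muscles)")
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != self.envelopes.shape[2]:
            raise ValueError("channel_labels must match muscle axis")
        if np.any(self.envelopes < 0):
            raise ValueError("envelopes must be nonnegative")
        if self.normalization is None:
            self.normalization = np.ones(self.envelopes.shape[2])
        self.normalization = np.asarray(self.normalization, dtype=float)

    @property
    def n_cycles(self) -> int:
        return self.envelopes.shape[0]

    @property
    def n_points(self) -> int:
        return self.envelopes.shape[1]

    @property
    def n_muscles(self) -> int:
        return self.envelopes.shape[2]

    @property
    def concatenated(self) -> np.ndarray:
        """Muscles x (n_cycles * n_points) matrix, cycles in temporal order."""
        # (cycles, time, muscles) -> (muscles, cycles*time)
        return self.envelopes.transpose(2, 0, 1).reshape(self.n_muscles, -1)

    @property
    def mean_cycle(self) -> np.ndarray:
        """Across-cycle mean curve, shape (n_points, n_muscles)."""
        return self.envelopes.mean(axis=0)
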