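"""Time-domain features: per-sample power difference and per-window line length.

Both features need only two consecutive samples at a time, which is what makes
the detector cheap enough for implantable hardware:

* power difference  ``PD[n] = x[n]^2 - x[n-1]^2``  (uV^2), sensitive to abrupt
  power shifts;
* line length ``LL_w = sum_{n in window w} |x[n] - x[n-1]|``  (uV), a smooth,
  near-monotone tracker of combined amplitude/frequency increases.

The stream is treated as continuous: the first difference of each window uses
the last sample of the previous window, and the very first sample of the
recording is differenced against 0 (everything starts from zero state, like
the hardware pipeline). Windows are contiguous, non-overlapping blocks of N
samples; a trailing partial window yields no line-length value.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError
from .signals_io import Recording

__all__ = ["FeatureFrame", "power_difference", "line_length_windows", "extract"]


@dataclass
class FeatureFrame:
    """Extracted features: ``pd[c, n]`` per sample, ``ll[c, w]`` per window."""

    pd: np.ndarray
    ll: np.ndarray
    window_len_N: int
    fs: float

    @property
    def n_channels(self) -> int:
        return self.pd.shape[0]

    @property
    def n_windows(self) -> int:
        return self.ll.shape[1]

    def abs_pd_windows(self) -> np.ndarray:
        """|PD| reshaped to (n_channels, n_windows, N); drops the trailing partial window."""
        n = self.window_len_N
        w = self.n_windows
        return np.abs(self.pd[:, : w * n]).reshape(self.n_channels, w, n)

    def to_csv(self, path: str | Path) -> None:
        """Per-channel, per-window summary for inspection."""
        apw = self.abs_pd_windows()
        rows = {
            "channel": np.repeat(np.arange(self.n_channels), self.n_windows),
            "window_index": np.tile(np.arange(self.n_windows), self.n_channels),
            "abs_pd_max": apw.max(axis=2).reshape(-1),
            "abs_pd_mean": apw.mean(axis=2).reshape(-1),
            "ll": self.ll.reshape(-1),
        }
        pd.DataFrame(rows).to_csv(path, index=False)


def power_difference(x: np.ndarray) -> np.ndarray:
    """``out[n] = x[n]^2 - x[n-1]^2`` with the virtual sample ``x[-1] = 0``."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size == 0:
        raise ValidationError("power_difference needs a non-empty 1-D signal")
    sq = x * x
    out = np.empty_like(sq)
    out[0] = sq[0]
    out[1:] = sq[1:] - sq[:-1]
    return out


def line_length_windows(x: np.ndarray, N: int) -> np.ndarray:
    """Line length over contiguous non-overlapping N-sample windows.

    The difference at each window's first sample reaches back to the previous
    window's last sample (``x[-1] = 0`` before the recording starts), so the
    sum of all window values equals the line length of the whole prefix.
    """
    x = np.asarray(x, dtype=np.float64)
    if N < 2:
        raise ConfigurationError(f"window length N={N} must be >= 2")
    if x.ndim != 1 or x.size < N:
        raise ValidationError(f"signal shorter ({x.size}) than one window ({N})")
    d = np.empty_like(x)
    d[0] = abs(x[0])
    d[1:] = np.abs(np.diff(x))
    w = x.size // N
    return d[: w * N].reshape(w, N).sum(axis=1)


def extract(rec: Recording, N: int) -> FeatureFrame:
    """Compute PD and windowed LL for every channel on one shared window grid."""
    if N < 2:
        raise ConfigurationError(f"window length N={N} must be >= 2")
    if rec.n_samples < N:
        raise ValidationError(
            f"recording has {rec.n_samples} samples, shorter than one window ({N})"
        )
    pd_arr = np.stack([power_difference(rec.samples[c]) for c in range(rec.n_channels)])
    ll = np.stack(
        [line_length_windows(rec.samples[c], N) for c in range(rec.n_channels)]
    )
    return FeatureFrame(pd=pd_arr, ll=ll, window_len_N=N, fs=rec.fs)
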