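"""Threshold detector: per-channel window flags, majority voting, persistence.

Per channel and per 1-s window the detector counts how often |PD| crosses the
power threshold (the Potential Seizure Event Counter, PSEC) and compares the
window's line length against its own threshold; the window is flagged when

    PSEC >= k_c   OR   LL >= Thr_LL.

Flags are summed across channels and the window passes the vote when at least
Lambda channels agree. The output asserts only after M (default 3) consecutive
passing windows — a sustained ictal pattern rather than a transient — and
de-asserts after ``release_D`` consecutive failing windows (the software
analogue of the hardware deglitch stage). All comparisons are inclusive (>=),
and all state starts at zero.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as features_mod
from . import fir
from .exceptions import ConfigurationError, ValidationError
from .features import FeatureFrame
from .signals_io import Recording

__all__ = [
    "DetectorConfig",
    "DetectionResult",
    "SeizureEvent",
    "window_flag",
    "vote",
    "persist",
    "flags_from_features",
    "detect_from_features",
    "detect",
    "detect_streaming",
]


@dataclass
class DetectorConfig:
    """All thresholds and structural parameters of the detector.

    ``thr_p`` (uV^2) and ``thr_ll`` (uV) may be scalars (shared across
    channels) or per-channel vectors. Exactly one of ``lambda_frac`` /
    ``lambda_count`` selects the vote threshold; a fraction resolves to
    ``ceil(lambda_frac * n_channels)``.
    """

    thr_p: float | np.ndarray
    thr_ll: float | np.ndarray
    k_c: int
    window_len_N: int
    lambda_frac: float | None = 0.25
    lambda_count: int | None = None
    persistence_M: int = 3
    release_D: int = 1

    def __post_init__(self) -> None:
        if (self.lambda_frac is None) == (self.lambda_count is None):
            raise ConfigurationError(
                "exactly one of lambda_frac / lambda_count must be set"
            )
        if self.lambda_frac is not None and not (0 < self.lambda_frac <= 1):
            raise ConfigurationError(f"lambda_frac={self.lambda_frac} outside (0, 1]")
        if self.lambda_count is not None and self.lambda_count < 1:
            raise ConfigurationError("lambda_count must be >= 1")
        if self.k_c < 1:
            raise ConfigurationError("k_c must be a positive integer")
        if self.window_len_N < 2:
            raise ConfigurationError("window_len_N must be >= 2")
        if self.k_c > self.window_len_N:
            raise ConfigurationError(
                f"k_c={self.k_c} exceeds window length {self.window_len_N}"
            )
        if self.persistence_M < 1 or self.release_D < 1:
            raise ConfigurationError("persistence_M and release_D must be >= 1")

    def resolve_lambda(self, n_channels: int) -> int:
        """Effective vote threshold Lambda for a given channel count."""
        if self.lambda_count is not None:
            lam = self.lambda_count
        else:
            lam = math.ceil(self.lambda_frac * n_channels)
        if not (1 <= lam <= n_channels):
            raise ConfigurationError(
                f"resolved Lambda={lam} outside [1, {n_channels}]"
            )
        return lam

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("thr_p", "thr_ll"):
            if isinstance(d[key], np.ndarray):
                d[key] = d[key].tolist()
            else:
                d[key] = float(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DetectorConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown detector config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("thr_p", "thr_ll"):
            if isinstance(d.get(key), list):
                d[key] = np.asarray(d[key], dtype=float)
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            yaml.safe_dump(self.to_dict())
            if path.suffix in (".yaml", ".yml")
            else json.dumps(self.to_dict(), indent=2)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "DetectorConfig":
        path = Path(path)
        text = path.read_text()
        d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls.from_dict(d)


@dataclass
class SeizureEvent:
    """One assert/release pair of the detector output."""

    assert_window: int
    assert_time_s: float
    release_window: int | None = None


@dataclass
class DetectionResult:
    """Full per-window detector state plus the final asserted timeline."""

    channel_flags: np.ndarray  # (Nch, W) bool
    psec: np.ndarray  # (Nch, W) int
    vote_counts: np.ndarray  # (W,) int
    vote_pass: np.ndarray  # (W,) bool
    asserted: np.ndarray  # (W,) bool
    events: list[SeizureEvent]
    window_len_N: int
    fs: float

    @property
    def n_windows(self) -> int:
        return self.asserted.size

    def asserted_samples(self, n_samples: int | None = None) -> np.ndarray:
        """Expand the per-window assertion to a per-sample boolean timeline.

        Samples of a window inherit its asserted value; trailing samples past
        the last complete window are False.
        """
        n = self.window_len_N
        out = np.repeat(self.asserted, n)
        if n_samples is not None:
            if n_samples < out.size:
                out = out[:n_samples]
            else:
                out = np.pad(out, (0, n_samples - out.size))
        return out

    def windows_to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "window_index": np.arange(self.n_windows),
                "window_start_s": np.arange(self.n_windows) * self.window_len_N / self.fs,
                "vote_count": self.vote_counts,
                "vote_pass": self.vote_pass.astype(int),
                "asserted": self.asserted.astype(int),
            }
        )
        df.to_csv(path, index=False)

    def events_to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "fs": self.fs,
            "window_len_N": self.window_len_N,
            "n_windows": int(self.n_windows),
            "events": [
                {
                    "assert_window": e.assert_window,
                    "assert_time_s": e.assert_time_s,
                    "release_window": e.release_window,
                }
                for e in self.events
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# Stage operations
# ---------------------------------------------------------------------------

def window_flag(
    pd_window: np.ndarray, ll_value: float, cfg: DetectorConfig
) -> tuple[bool, int]:
    """Flag one channel-window: |PD| crossing count vs k_c, OR line length vs Thr_LL."""
    pd_window = np.asarray(pd_window, dtype=np.float64)
    if pd_window.shape != (cfg.window_len_N,):
        raise ValidationError(
            f"PD window has length {pd_window.size}, expected {cfg.window_len_N}"
        )
    thr_p = float(np.atleast_1d(cfg.thr_p)[0])
    thr_ll = float(np.atleast_1d(cfg.thr_ll)[0])
    psec = int(np.count_nonzero(np.abs(pd_window) >= thr_p))
    return (psec >= cfg.k_c) or (ll_value >= thr_ll), psec


def vote(channel_flags_w: np.ndarray, cfg: DetectorConfig) -> tuple[bool, int]:
    """Majority vote for one window: pass when at least Lambda channels flag."""
    flags = np.asarray(channel_flags_w, dtype=bool)
    lam = cfg.resolve_lambda(flags.size)
    count = int(flags.sum())
    return count >= lam, count


def persist(
    vote_pass: np.ndarray, cfg: DetectorConfig, fs: float | None = None
) -> tuple[np.ndarray, list[SeizureEvent]]:
    """Temporal persistence state machine over the window-wise vote outcomes.

    Asserts at the first window ending a run of ``persistence_M`` consecutive
    passes (the assert time is the END of that window, hence the detector's
    intrinsic M-second delay with 1-s windows); stays asserted until the vote
    has failed for ``release_D`` consecutive windows. When ``fs`` is given,
    each event's ``assert_time_s`` is ``(assert_window + 1) * N / fs``.
    """
    vote_pass = np.asarray(vote_pass, dtype=bool)
    asserted = np.zeros(vote_pass.size, dtype=bool)
    events: list[SeizureEvent] = []
    run = 0  # consecutive passes while idle
    fails = 0  # consecutive fails while asserted
    active: SeizureEvent | None = None
    for w, ok in enumerate(vote_pass):
        if active is None:
            run = run + 1 if ok else 0
            if run >= cfg.persistence_M:
                t = (w + 1) * cfg.window_len_N / fs if fs else float("nan")
                active = SeizureEvent(assert_window=w, assert_time_s=t)
                events.append(active)
                asserted[w] = True
                fails = 0
        else:
            fails = 0 if ok else fails + 1
            if fails >= cfg.release_D:
                active.release_window = w
                active = None
                run = 0
            else:
                asserted[w] = True
    return asserted, events


def flags_from_features(
    ff: FeatureFrame, cfg: DetectorConfig, psec: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-channel window flags for a whole recording.

    ``psec`` may be supplied pre-computed (it depends only on ``thr_p``),
    which lets the calibration grid search reuse it across candidate configs.
    """
    if ff.window_len_N != cfg.window_len_N:
        raise ConfigurationError(
            f"feature window {ff.window_len_N} != config window {cfg.window_len_N}"
        )
    if psec is None:
        thr_p = np.atleast_1d(np.asarray(cfg.thr_p, dtype=float))[:, None, None]
        psec = (ff.abs_pd_windows() >= thr_p).sum(axis=2)
    thr_ll = np.atleast_1d(np.asarray(cfg.thr_ll, dtype=float))[:, None]
    flags = (psec >= cfg.k_c) | (ff.ll >= thr_ll)
    return flags, psec


def detect_from_features(ff: FeatureFrame, cfg: DetectorConfig) -> DetectionResult:
    """Run flagging, voting and persistence on pre-extracted features."""
    flags, psec = flags_from_features(ff, cfg)
    lam = cfg.resolve_lambda(ff.n_channels)
    counts = flags.sum(axis=0).astype(int)
    vote_pass = counts >= lam
    asserted, events = persist(vote_pass, cfg, fs=ff.fs)
    return DetectionResult(
        channel_flags=flags,
        psec=psec.astype(int),
        vote_counts=counts,
        vote_pass=vote_pass,
        asserted=asserted,
        events=events,
        window_len_N=cfg.window_len_N,
        fs=ff.fs,
    )


def detect(
    rec: Recording, cfg: DetectorConfig, filter_spec: fir.FilterSpec
) -> DetectionResult:
    """Full pipeline: low-pass filter -> features -> flags -> vote -> persistence."""
    filtered = fir.apply(filter_spec, rec)
    ff = features_mod.extract(filtered, cfg.window_len_N)
    return detect_from_features(ff, cfg)


def detect_streaming(
    rec: Recording,
    cfg: DetectorConfig,
    filter_spec: fir.FilterSpec,
    chunk_samples: int = 4096,
) -> DetectionResult:
    """Chunked, state-carrying run of the same pipeline.

    Processes the recording ``chunk_samples`` at a time, carrying the filter
    delay-line state, the previous filtered sample (for PD / LL differences),
    partial-window accumulators and the persistence state across chunk
    boundaries — mirroring sample-by-sample hardware operation. Output is
    bit-identical to :func:`detect`.
    """
    from scipy.signal import lfilter

    if abs(filter_spec.fs - rec.fs) > 1e-9:
        raise ConfigurationError("filter/recording sampling-rate mismatch")
    nch = rec.n_channels
    n_taps = filter_spec.order + 1
    zi = np.zeros((nch, n_taps - 1))
    pending = np.empty((nch, 0))  # filtered samples not yet forming a window
    prev = np.zeros(nch)  # last filtered sample of the previous window block
    thr_p = np.atleast_1d(np.asarray(cfg.thr_p, dtype=float))[:, None, None]
    thr_ll = np.atleast_1d(np.asarray(cfg.thr_ll, dtype=float))[:, None]
    lam = cfg.resolve_lambda(nch)
    n = cfg.window_len_N

    flags_parts, psec_parts, counts_parts = [], [], []
    for start in range(0, rec.n_samples, chunk_samples):
        chunk = rec.samples[:, start : start + chunk_samples]
        filt, zi = lfilter(filter_spec.coefficients, [1.0], chunk, axis=1, zi=zi)
        block = np.concatenate([pending, filt], axis=1)
        w = block.shape[1] // n
        if w == 0:
            pending = block
            continue
        full, pending = block[:, : w * n], block[:, w * n :]
        with_prev = np.concatenate([prev[:, None], full], axis=1)
        sq = with_prev * with_prev
        pd_vals = (sq[:, 1:] - sq[:, :-1]).reshape(nch, w, n)
        d = np.abs(np.diff(with_prev, axis=1)).reshape(nch, w, n)
        prev = full[:, -1].copy()
        psec = (np.abs(pd_vals) >= thr_p).sum(axis=2)
        ll = d.sum(axis=2)
        flags = (psec >= cfg.k_c) | (ll >= thr_ll)
        flags_parts.append(flags)
        psec_parts.append(psec)
        counts_parts.append(flags.sum(axis=0).astype(int))

    flags = np.concatenate(flags_parts, axis=1) if flags_parts else np.zeros((nch, 0), bool)
    psec = np.concatenate(psec_parts, axis=1) if psec_parts else np.zeros((nch, 0), int)
    counts = np.concatenate(counts_parts) if counts_parts else np.zeros(0, int)
    vote_pass = counts >= lam
    asserted, events = persist(vote_pass, cfg, fs=rec.fs)
    return DetectionResult(
        channel_flags=flags,
        psec=psec.astype(int),
        vote_counts=counts,
        vote_pass=vote_pass,
        asserted=asserted,
        events=events,
        window_len_N=n,
        fs=rec.fs,
    )
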