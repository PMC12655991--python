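"""Recording and annotation containers plus EDF / CSV / JSON readers and writers.

A :class:`Recording` holds a multichannel signal as a ``(n_channels, n_samples)``
float array in microvolts together with its sampling rate. Seizure annotations
are lists of half-open ``[onset_s, offset_s)`` intervals in seconds from the
start of the recording. Sample indexing is 0-based and time is ``t = n / fs``
throughout the package.

EDF (European Data Format, 16-bit) support is implemented directly: the format
is a fixed-layout ASCII header followed by little-endian int16 data records,
and only the plain continuous variant is handled (no EDF+ annotations, one
sampling rate across requested channels).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, UnsupportedFormatError, ValidationError

__all__ = [
    "Recording",
    "Annotation",
    "SampleLabels",
    "read_edf",
    "write_edf",
    "read_annotations",
    "write_annotations",
    "labels_from_annotation",
]

_EDF_DIG_MIN = -32768
_EDF_DIG_MAX = 32767


@dataclass
class Recording:
    """A multichannel recording: ``samples[c, n]`` in microvolts at rate ``fs``."""

    samples: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValidationError("samples must be a 2-D (n_channels, n_samples) array")
        nch, t = self.samples.shape
        if nch < 1 or t < 1:
            raise ValidationError("recording needs at least one channel and one sample")
        if not self.fs > 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(nch)]
        if len(self.channel_names) != nch:
            raise ValidationError(
                f"{len(self.channel_names)} channel names for {nch} channels"
            )
        if not np.isfinite(self.samples).all():
            raise ValidationError("samples contain non-finite values")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, samples: np.ndarray) -> "Recording":
        """New Recording sharing metadata but with different sample data."""
        return Recording(samples, self.fs, list(self.channel_names), self.id)


@dataclass
class Annotation:
    """Seizure intervals as sorted, non-overlapping half-open ``[onset, offset)`` pairs."""

    intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ivs = [(float(a), float(b)) for a, b in self.intervals]
        for a, b in ivs:
            if not (0 <= a < b):
                raise ValidationError(f"invalid interval ({a}, {b}): need 0 <= onset < offset")
        ivs.sort()
        for (a0, b0), (a1, _b1) in zip(ivs, ivs[1:]):
            if a1 < b0:
                raise ValidationError(
                    f"overlapping intervals ({a0}, {b0}) and starting at {a1}"
                )
        self.intervals = ivs

    @property
    def n_seizures(self) -> int:
        return len(self.intervals)

    def total_seconds(self) -> float:
        return sum(b - a for a, b in self.intervals)


@dataclass
class SampleLabels:
    """Per-sample ground truth: ``labels[n]`` is True when sample ``n`` is ictal."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=bool)
        if self.labels.ndim != 1:
            raise ValidationError("labels must be 1-D")


def labels_from_annotation(ann: Annotation, fs: float, n_samples: int) -> SampleLabels:
    """Expand intervals to a boolean per-sample vector.

    Sample ``n`` is ictal iff ``n / fs`` falls inside some half-open
    ``[onset, offset)`` interval, i.e. samples ``ceil(onset*fs) .. ceil(offset*fs)-1``
    (with a small tolerance so exact window boundaries land deterministically).
    """
    labels = np.zeros(n_samples, dtype=bool)
    for onset, offset in ann.intervals:
        start = int(math.ceil(onset * fs - 1e-9))
        stop = int(math.ceil(offset * fs - 1e-9))
        labels[max(start, 0) : min(stop, n_samples)] = True
    return SampleLabels(labels)


# ---------------------------------------------------------------------------
# Annotation files: CSV with header ``onset_s,offset_s`` or JSON list of objects
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path, fs: float, duration_s: float) -> Annotation:
    """Read seizure intervals from CSV or JSON, validate, sort and clip to the recording."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text() or "[]")
        pairs = [(float(d["onset_s"]), float(d["offset_s"])) for d in raw]
    else:
        df = pd.read_csv(path)
        if df.empty:
            pairs = []
        else:
            if not {"onset_s", "offset_s"} <= set(df.columns):
                raise ValidationError(
                    f"{path}: expected columns onset_s,offset_s, got {list(df.columns)}"
                )
            pairs = list(zip(df["onset_s"].astype(float), df["offset_s"].astype(float)))
    clipped = []
    for a, b in pairs:
        if b <= a:
            raise ValidationError(f"{path}: offset {b} <= onset {a}")
        a, b = max(a, 0.0), min(b, duration_s)
        if b > a:
            clipped.append((a, b))
    return Annotation(clipped)  # sorting / overlap checks in the constructor


def write_annotations(ann: Annotation, path: str | Path) -> None:
    """Write intervals as a CSV with header ``onset_s,offset_s``."""
    pd.DataFrame(ann.intervals, columns=["onset_s", "offset_s"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# EDF 16-bit
# ---------------------------------------------------------------------------

def _fit8(value: float) -> str:
    """Format a number into at most 8 ASCII characters (EDF numeric field)."""
    for fmt in ("%.8g", "%.6g", "%.5g", "%.4g", "%.3g", "%.2g"):
        s = fmt % value
        if len(s) <= 8:
            return s
    raise ValidationError(f"cannot format {value} into an 8-char EDF field")


def _samples_per_record(n_samples: int, fs: float) -> int:
    """Pick a data-record size: 1 s records when they tile the signal exactly,
    otherwise the largest divisor of n_samples that keeps records under 61440 bytes."""
    ifs = int(round(fs))
    if abs(fs - ifs) < 1e-9 and n_samples % ifs == 0:
        return ifs
    best = 1
    for d in range(1, int(math.isqrt(n_samples)) + 1):
        if n_samples % d == 0:
            for cand in (d, n_samples // d):
                if 2 * cand <= 61440 and cand > best:
                    best = cand
    return best


def write_edf(rec: Recording, path: str | Path) -> None:
    """Write a Recording as plain 16-bit EDF.

    Each channel uses a symmetric physical range covering its extremes, so the
    round-trip error is bounded by one quantization step
    ``(phys_max - phys_min) / 65535``.
    """
    path = Path(path)
    nch, t = rec.samples.shape
    spr = _samples_per_record(t, rec.fs)
    n_records = t // spr
    record_dur = spr / rec.fs

    pmaxs, pmins, digital = [], [], []
    for c in range(nch):
        x = rec.samples[c]
        a = float(np.max(np.abs(x)))
        if a == 0.0:
            a = 1.0
        # header stores the formatted string; reuse its parsed value for scaling
        pmax = float(_fit8(a * (1 + 1e-6)))
        pmax = max(pmax, a)
        pmin = -pmax
        gain = (pmax - pmin) / (_EDF_DIG_MAX - _EDF_DIG_MIN)
        dig = np.round((x - pmin) / gain).astype(np.int64) + _EDF_DIG_MIN
        digital.append(np.clip(dig, _EDF_DIG_MIN, _EDF_DIG_MAX).astype("<i2"))
        pmaxs.append(pmax)
        pmins.append(pmin)

    def f(s: str, width: int) -> bytes:
        b = s.encode("ascii")
        if len(b) > width:
            b = b[:width]
        return b.ljust(width)

    header = b"".join(
        [
            f("0", 8),
            f(rec.id or "X", 80),
            f("Startdate 01-JAN-2000", 80),
            f("01.01.00", 8),
            f("00.00.00", 8),
            f(str(256 * (1 + nch)), 8),
            f("", 44),
            f(str(n_records), 8),
            f(_fit8(record_dur), 8),
            f(str(nch), 4),
        ]
    )
    sig_fields = [
        (16, [name for name in rec.channel_names]),
        (80, ["" for _ in range(nch)]),  # transducer
        (8, ["uV" for _ in range(nch)]),
        (8, [_fit8(p) for p in pmins]),
        (8, [_fit8(p) for p in pmaxs]),
        (8, [str(_EDF_DIG_MIN)] * nch),
        (8, [str(_EDF_DIG_MAX)] * nch),
        (80, ["" for _ in range(nch)]),  # prefiltering
        (8, [str(spr)] * nch),
        (32, ["" for _ in range(nch)]),
    ]
    header += b"".join(
        b"".join(f(v, width) for v in values) for width, values in sig_fields
    )

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            sl = slice(r * spr, (r + 1) * spr)
            for c in range(nch):
                fh.write(digital[c][sl].tobytes())


def read_edf(path: str | Path, channels: list[str] | None = None) -> Recording:
    """Read a plain 16-bit EDF file into a Recording.

    ``channels`` selects a subset by name, in the requested order; all selected
    channels must share one sampling rate. Digital values are converted to
    physical units using the per-channel scaling declared in the header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise UnsupportedFormatError(f"{path}: truncated EDF header")
        n_records = int(head[236:244].decode("ascii").strip())
        record_dur = float(head[244:252].decode("ascii").strip())
        nch = int(head[252:256].decode("ascii").strip())
        sig = fh.read(256 * nch)

        def col(offset: int, width: int) -> list[str]:
            base = offset * nch
            return [
                sig[base + i * width : base + (i + 1) * width].decode("ascii").strip()
                for i in range(nch)
            ]

        # cumulative per-signal field offsets: label 0, transducer 16, dim 96,
        # phys min 104, phys max 112, dig min 120, dig max 128, prefilter 136,
        # samples/record 216
        labels = col(0, 16)
        pmins = [float(v) for v in col(104, 8)]
        pmaxs = [float(v) for v in col(112, 8)]
        dmins = [int(v) for v in col(120, 8)]
        dmaxs = [int(v) for v in col(128, 8)]
        sprs = [int(v) for v in col(216, 8)]
        data = fh.read()

    if channels is not None:
        if len(channels) == 0:
            raise ConfigurationError("empty channel selection")
        missing = [c for c in channels if c not in labels]
        if missing:
            raise ConfigurationError(f"unknown channel name(s): {missing}")
        sel = [labels.index(c) for c in channels]
    else:
        sel = list(range(nch))
    if len({sprs[i] for i in sel}) != 1:
        raise UnsupportedFormatError(
            "selected channels have differing sampling rates; resampling is not supported"
        )
    if record_dur <= 0:
        raise UnsupportedFormatError("non-positive record duration")

    spr_all = sum(sprs)
    frame = np.frombuffer(
        data[: n_records * spr_all * 2], dtype="<i2"
    ).reshape(n_records, spr_all)
    offsets = np.concatenate([[0], np.cumsum(sprs)])
    out = np.empty((len(sel), n_records * sprs[sel[0]]), dtype=np.float64)
    for k, i in enumerate(sel):
        dig = frame[:, offsets[i] : offsets[i + 1]].reshape(-1).astype(np.float64)
        gain = (pmaxs[i] - pmins[i]) / (dmaxs[i] - dmins[i])
        out[k] = (dig - dmins[i]) * gain + pmins[i]
    fs = sprs[sel[0]] / record_dur
    names = [labels[i] for i in sel]
    return Recording(out, fs=fs, channel_names=names, id=path.stem)
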