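"""Synthetic multichannel EEG with exact seizure annotations.

The generator emulates just the contrast the detector exploits: an inter-ictal
background of Gaussian noise plus a per-channel-phase alpha rhythm, and ictal
segments in which a recruited subset of channels gains a strong rhythmic
oscillation and amplified background. Onset and offset transitions ramp
linearly over ``ramp_s`` inside the annotated interval, so the annotations are
exact by construction. All randomness flows from a single seeded generator,
making every recording bit-reproducible.

This deliberately ignores real-EEG complications (artifacts, non-stationary
background, spatial correlation); it exercises the detector's mathematics,
not its clinical robustness.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .exceptions import ValidationError
from .signals_io import Annotation, Recording

__all__ = ["SeizureSpec", "SyntheticSpec", "generate", "generate_suite"]


@dataclass
class SeizureSpec:
    """One ictal segment: where it happens and how strong/widespread it is."""

    onset_s: float
    duration_s: float
    amplitude_gain: float = 5.0
    recruited_fraction: float = 0.7
    rhythm_hz: float = 5.0

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class SyntheticSpec:
    """Full description of a synthetic recording."""

    n_channels: int = 20
    fs: float = 256.0
    duration_s: float = 1200.0
    seizures: list[SeizureSpec] = field(default_factory=list)
    noise_sigma: float = 15.0  # uV, background Gaussian noise
    alpha_amp: float = 20.0  # uV, background alpha rhythm amplitude
    alpha_hz: float = 10.0
    ramp_s: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.seizures = [
            SeizureSpec(**s) if isinstance(s, dict) else s for s in self.seizures
        ]
        if self.n_channels < 1 or self.duration_s <= 0 or self.fs <= 0:
            raise ValidationError("n_channels, fs and duration_s must be positive")
        last_end = -math.inf
        for sz in sorted(self.seizures, key=lambda s: s.onset_s):
            if not (0 < sz.recruited_fraction <= 1):
                raise ValidationError(
                    f"recruited_fraction {sz.recruited_fraction} outside (0, 1]"
                )
            if sz.amplitude_gain < 1:
                raise ValidationError("amplitude_gain must be >= 1")
            if sz.rhythm_hz >= self.fs / 2:
                raise ValidationError("rhythm_hz must be below Nyquist")
            if sz.onset_s < 0 or sz.offset_s > self.duration_s:
                raise ValidationError("seizure interval outside the recording")
            if sz.onset_s < last_end:
                raise ValidationError("seizure intervals overlap")
            last_end = sz.offset_s

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SyntheticSpec":
        from .fir import _read_json_source

        payload = json.loads(_read_json_source(source))
        return cls(**payload)


def _envelope(n0: int, n1: int, ramp_n: int) -> np.ndarray:
    """Trapezoidal 0->1->0 envelope over [n0, n1): linear ramps inside the interval."""
    length = n1 - n0
    env = np.ones(length)
    r = min(ramp_n, length // 2)
    if r > 0:
        env[:r] = np.linspace(0, 1, r, endpoint=False)
        env[length - r :] = np.linspace(1, 0, r, endpoint=False)
    return env


def generate(spec: SyntheticSpec) -> tuple[Recording, Annotation]:
    """Generate one annotated recording from the spec.

    Draw order (fixed for reproducibility): background noise, alpha phases,
    channel recruitment shuffle, then per-seizure rhythm phases. During a
    seizure, recruited channels have their background multiplied by
    ``1 + env*(gain-1)`` and gain an added oscillation of amplitude
    ``env * (gain-1) * alpha_amp`` at ``rhythm_hz``; at gain 1 the ictal
    segment is therefore statistically identical to background (a null
    effect by construction).
    """
    rng = np.random.default_rng(spec.seed)
    nch = spec.n_channels
    t_total = int(round(spec.duration_s * spec.fs))
    t = np.arange(t_total) / spec.fs

    noise = rng.normal(0.0, spec.noise_sigma, size=(nch, t_total))
    phases = rng.uniform(0, 2 * np.pi, size=nch)
    x = noise + spec.alpha_amp * np.sin(
        2 * np.pi * spec.alpha_hz * t[None, :] + phases[:, None]
    )

    recruit_order = rng.permutation(nch)
    intervals = []
    for sz in sorted(spec.seizures, key=lambda s: s.onset_s):
        n0 = int(round(sz.onset_s * spec.fs))
        n1 = int(round(sz.offset_s * spec.fs))
        k = math.ceil(sz.recruited_fraction * nch)
        recruited = recruit_order[:k]
        env = _envelope(n0, n1, int(round(spec.ramp_s * spec.fs)))
        ict_phases = rng.uniform(0, 2 * np.pi, size=k)
        seg_t = t[n0:n1]
        osc = np.sin(
            2 * np.pi * sz.rhythm_hz * seg_t[None, :] + ict_phases[:, None]
        )
        x[recruited, n0:n1] *= 1 + env[None, :] * (sz.amplitude_gain - 1)
        x[recruited, n0:n1] += env[None, :] * (sz.amplitude_gain - 1) * spec.alpha_amp * osc
        intervals.append((sz.onset_s, sz.offset_s))

    rec = Recording(
        x,
        fs=spec.fs,
        channel_names=[f"ch{i}" for i in range(nch)],
        id=f"synthetic-seed{spec.seed}",
    )
    return rec, Annotation(intervals)


def generate_suite(
    base: SyntheticSpec, n_recordings: int, seed: int
) -> list[tuple[Recording, Annotation]]:
    """One tuning recording plus ``n_recordings - 1`` held-out test recordings.

    All share the base spec's parameters; per-recording seeds are derived
    deterministically from the master seed (first recording = tuning).
    """
    if n_recordings < 2:
        raise ValidationError("a suite needs at least a tuning and one test recording")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_recordings)
    out = []
    for s in child_seeds:
        spec = SyntheticSpec(**{**asdict(base), "seed": int(s) & 0x7FFFFFFF})
        out.append(generate(spec))
    return out
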