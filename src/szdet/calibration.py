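"""Offline patient-specific threshold calibration.

Thresholds are anchored to the statistics of the patient's inter-ictal
activity, measured over inter-ictal windows pooled across channels (with a
guard band around annotated seizures to keep pre/post-ictal activity out of
the baseline). Candidate thresholds take the usual anomaly-detection form

    thr = mu + scale * sigma

of the baseline mean plus a scaled standard deviation, for |PD| per sample
and LL per window respectively. The mean offset matters for line length: LL
is an N-sample sum whose inter-ictal mean dwarfs its standard deviation, so
a pure multiple of sigma would sit below normal activity and flag every
window.

The search has two phases, run entirely on one tuning recording:

1. a deterministic grid search over (pd_scale, ll_scale, k_c) maximizing
   sample-level accuracy (ties broken by higher sensitivity, then lower
   latency, then larger thresholds);
2. starting from the phase-1 optimum, both thresholds are multiplied by a
   decreasing factor sequence, and the config with the highest sensitivity
   among those keeping sensitivity >= target and accuracy >= floor is
   returned. If no factor satisfies both, the best-sensitivity config with
   accuracy above the floor (or overall, if none clears the floor) is
   returned with ``converged=False``.

The vote threshold Lambda is a fixed fraction of the channel count and is not
searched. Calibration is a pure function of its inputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import features as features_mod
from . import fir
from . import metrics as metrics_mod
from .detector import DetectorConfig, persist
from .exceptions import ValidationError
from .signals_io import Annotation, Recording, SampleLabels, labels_from_annotation

__all__ = ["CalibrationSpec", "CalibrationReport", "baseline_stats", "calibrate"]

GUARD_BAND_S = 30.0  # exclusion zone around annotated seizures for the baseline


@dataclass
class CalibrationSpec:
    """Search space and targets for the two-phase calibration."""

    sensitivity_target: float = 90.0
    accuracy_floor: float = 95.0
    pd_scale_grid: list[float] = field(default_factory=lambda: [1, 2, 3, 4, 6, 8])
    ll_scale_grid: list[float] = field(default_factory=lambda: [1, 2, 3, 4, 6, 8])
    kc_grid: list[int] = field(default_factory=lambda: [2, 4, 8, 16, 32])
    shrink_factors: list[float] = field(
        default_factory=lambda: [0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3]
    )
    lambda_frac: float = 0.25
    window_s: float = 1.0
    persistence_M: int = 3
    release_D: int = 1
    match_tolerance_s: float = metrics_mod.DEFAULT_MATCH_TOLERANCE_S

    def __post_init__(self) -> None:
        if not (0 < self.sensitivity_target <= 100 and 0 < self.accuracy_floor <= 100):
            raise ValidationError("targets must lie in (0, 100]")
        if not (self.pd_scale_grid and self.ll_scale_grid and self.kc_grid):
            raise ValidationError("search grids must be non-empty")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationSpec":
        return cls(**d)


@dataclass
class TraceEntry:
    phase: int
    config: dict
    accuracy_pct: float
    sensitivity_pct: float | None
    mean_latency_s: float | None


@dataclass
class CalibrationReport:
    best_config: DetectorConfig
    achieved: metrics_mod.MetricsReport
    search_trace: list[TraceEntry]
    converged: bool
    sigma_pd: float
    sigma_ll: float

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "converged": self.converged,
            "sigma_pd": self.sigma_pd,
            "sigma_ll": self.sigma_ll,
            "best_config": self.best_config.to_dict(),
            "achieved": self.achieved.to_dict(),
            "search_trace": [asdict(t) for t in self.search_trace],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _interictal_window_mask(
    ann: Annotation, fs: float, n_windows: int, window_len: int
) -> np.ndarray:
    """True for windows lying entirely outside every seizure's guard band."""
    starts = np.arange(n_windows) * window_len / fs
    ends = starts + window_len / fs
    mask = np.ones(n_windows, dtype=bool)
    for onset, offset in ann.intervals:
        lo, hi = onset - GUARD_BAND_S, offset + GUARD_BAND_S
        mask &= (ends <= lo) | (starts >= hi)
    return mask


def baseline_moments(
    rec: Recording,
    ann: Annotation,
    filter_spec: fir.FilterSpec,
    N: int,
) -> tuple[float, float, float, float]:
    """Inter-ictal (mean, std) of |PD| per sample and of LL per window.

    Both are pooled across channels over the windows that survive the guard
    band around annotated seizures. The recording must contain at least one
    annotated seizure (there is nothing to calibrate sensitivity against
    otherwise) and at least 10 inter-ictal windows.
    """
    if ann.n_seizures == 0:
        raise ValidationError(
            "calibration recording has no annotated seizure to tune against"
        )
    filtered = fir.apply(filter_spec, rec)
    ff = features_mod.extract(filtered, N)
    mask = _interictal_window_mask(ann, rec.fs, ff.n_windows, N)
    if mask.sum() < 10:
        raise ValidationError(
            f"only {int(mask.sum())} inter-ictal windows; need at least 10"
        )
    apd = ff.abs_pd_windows()[:, mask, :]
    ll = ff.ll[:, mask]
    mu_pd, sigma_pd = float(np.mean(apd)), float(np.std(apd))
    mu_ll, sigma_ll = float(np.mean(ll)), float(np.std(ll))
    if sigma_pd == 0 or sigma_ll == 0:
        warnings.warn(
            "degenerate inter-ictal baseline (zero variance); thresholds collapse "
            "to the baseline mean",
            stacklevel=2,
        )
    return mu_pd, sigma_pd, mu_ll, sigma_ll


def baseline_stats(
    rec: Recording,
    ann: Annotation,
    filter_spec: fir.FilterSpec,
    N: int,
) -> tuple[float, float]:
    """Inter-ictal standard deviations of |PD| and LL (see :func:`baseline_moments`)."""
    _, sigma_pd, _, sigma_ll = baseline_moments(rec, ann, filter_spec, N)
    return sigma_pd, sigma_ll


def _evaluate_candidate(
    ff: features_mod.FeatureFrame,
    labels: SampleLabels,
    ann: Annotation,
    cfg: DetectorConfig,
    psec_cache: dict[float, np.ndarray],
    match_tolerance_s: float,
) -> metrics_mod.MetricsReport:
    """Fast evaluation of one threshold configuration on pre-extracted features."""
    thr_p = float(cfg.thr_p)
    if thr_p not in psec_cache:
        psec_cache[thr_p] = (ff.abs_pd_windows() >= thr_p).sum(axis=2)
    psec = psec_cache[thr_p]
    flags = (psec >= cfg.k_c) | (ff.ll >= float(cfg.thr_ll))
    lam = cfg.resolve_lambda(ff.n_channels)
    counts = flags.sum(axis=0)
    vote_pass = counts >= lam
    asserted, events = persist(vote_pass, cfg, fs=ff.fs)
    n_eval = ff.n_windows * ff.window_len_N
    timeline = np.repeat(asserted, ff.window_len_N)
    conf = metrics_mod.confusion(timeline, SampleLabels(labels.labels[:n_eval]))
    lats = metrics_mod.latency(events, ann, match_tolerance_s)
    return metrics_mod.MetricsReport(
        counts=conf,
        accuracy_pct=conf.accuracy_pct(),
        sensitivity_pct=conf.sensitivity_pct(),
        latency_s=lats,
        mean_latency_s=(sum(lats) / len(lats)) if lats else None,
        fpr_pct_per_h=metrics_mod.fpr_per_hour(conf, n_eval / ff.fs),
        n_seizures_detected=len(lats),
        n_seizures_total=ann.n_seizures,
    )


def _rank_key(rep: metrics_mod.MetricsReport, thr_sum: float, kc: int):
    """Phase-1 ordering: accuracy, then sensitivity, then lower latency, then
    larger (stricter) thresholds."""
    sens = rep.sensitivity_pct if rep.sensitivity_pct is not None else -1.0
    all_matched = rep.n_seizures_detected == rep.n_seizures_total
    lat = rep.mean_latency_s if (rep.mean_latency_s is not None and all_matched) else np.inf
    return (rep.accuracy_pct, sens, -lat, thr_sum, kc)


def calibrate(
    rec: Recording,
    ann: Annotation,
    spec: CalibrationSpec,
    filter_spec: fir.FilterSpec,
) -> CalibrationReport:
    """Two-phase deterministic threshold search on one tuning recording."""
    N = int(round(spec.window_s * rec.fs))
    mu_pd, sigma_pd, mu_ll, sigma_ll = baseline_moments(rec, ann, filter_spec, N)
    filtered = fir.apply(filter_spec, rec)
    ff = features_mod.extract(filtered, N)
    labels = labels_from_annotation(ann, rec.fs, rec.n_samples)
    psec_cache: dict[float, np.ndarray] = {}
    trace: list[TraceEntry] = []

    def make_cfg(thr_p: float, thr_ll: float, kc: int) -> DetectorConfig:
        return DetectorConfig(
            thr_p=thr_p,
            thr_ll=thr_ll,
            k_c=kc,
            window_len_N=N,
            lambda_frac=spec.lambda_frac,
            persistence_M=spec.persistence_M,
            release_D=spec.release_D,
        )

    def record(phase: int, cfg: DetectorConfig, rep: metrics_mod.MetricsReport):
        trace.append(
            TraceEntry(
                phase=phase,
                config=cfg.to_dict(),
                accuracy_pct=rep.accuracy_pct,
                sensitivity_pct=rep.sensitivity_pct,
                mean_latency_s=rep.mean_latency_s,
            )
        )

    # Phase 1: accuracy-first grid search
    best = None  # (key, cfg, report)
    for ps in spec.pd_scale_grid:
        for ls in spec.ll_scale_grid:
            for kc in spec.kc_grid:
                if kc > N:
                    continue
                cfg = make_cfg(mu_pd + ps * sigma_pd, mu_ll + ls * sigma_ll, kc)
                rep = _evaluate_candidate(
                    ff, labels, ann, cfg, psec_cache, spec.match_tolerance_s
                )
                record(1, cfg, rep)
                key = _rank_key(rep, ps + ls, kc)
                if best is None or key > best[0]:
                    best = (key, cfg, rep)
    assert best is not None
    _, base_cfg, base_rep = best

    # Phase 2: lower both thresholds until the sensitivity target is reached
    # while the accuracy floor holds; prefer the highest sensitivity among
    # the qualifying configs.
    def qualifies(rep: metrics_mod.MetricsReport) -> bool:
        return (
            rep.sensitivity_pct is not None
            and rep.sensitivity_pct >= spec.sensitivity_target
            and rep.accuracy_pct >= spec.accuracy_floor
        )

    candidates = [(base_cfg, base_rep, 1.0)]
    for f in spec.shrink_factors:
        cfg = make_cfg(float(base_cfg.thr_p) * f, float(base_cfg.thr_ll) * f, base_cfg.k_c)
        rep = _evaluate_candidate(
            ff, labels, ann, cfg, psec_cache, spec.match_tolerance_s
        )
        record(2, cfg, rep)
        candidates.append((cfg, rep, f))

    qualifying = [(c, r, f) for c, r, f in candidates if qualifies(r)]
    if qualifying:
        cfg, rep, _ = max(
            qualifying,
            key=lambda t: (t[1].sensitivity_pct, t[1].accuracy_pct, t[2]),
        )
        converged = True
    else:
        converged = False
        above_floor = [
            (c, r, f) for c, r, f in candidates if r.accuracy_pct >= spec.accuracy_floor
        ]
        pool = above_floor or candidates
        cfg, rep, _ = max(
            pool,
            key=lambda t: (
                t[1].sensitivity_pct if t[1].sensitivity_pct is not None else -1.0,
                t[1].accuracy_pct,
                t[2],
            ),
        )

    return CalibrationReport(
        best_config=cfg,
        achieved=rep,
        search_trace=trace,
        converged=converged,
        sigma_pd=sigma_pd,
        sigma_ll=sigma_ll,
    )
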