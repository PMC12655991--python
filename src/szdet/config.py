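"""Run configuration: one validated YAML/JSON document wiring filter, detector
and calibration settings for the command-line tools.

Unknown keys are rejected so typos cannot silently fall back to defaults —
the window length, persistence depth, vote fraction and every threshold are
always visible in the config that produced a run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .calibration import CalibrationSpec
from .detector import DetectorConfig
from .exceptions import ConfigurationError

__all__ = ["RunConfig", "load_run_config"]

_FILTER_KEYS = {"order", "f_stop", "f_pass", "min_stop_atten_db", "quant_bits"}


@dataclass
class FilterParams:
    order: int = 64
    f_stop: float = 50.0
    f_pass: float = 40.0
    min_stop_atten_db: float = 60.0
    quant_bits: int | None = 16


@dataclass
class RunConfig:
    filter: FilterParams = field(default_factory=FilterParams)
    detector: DetectorConfig | None = None
    calibration: CalibrationSpec = field(default_factory=CalibrationSpec)
    seed: int = 0
    log_level: str = "INFO"


def load_run_config(path: str | Path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    doc = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    doc = doc or {}
    known_top = {"filter", "detector", "calibration", "seed", "log_level"}
    unknown = set(doc) - known_top
    if unknown:
        raise ConfigurationError(f"unknown config sections/keys: {sorted(unknown)}")

    filt_doc = doc.get("filter", {}) or {}
    bad = set(filt_doc) - _FILTER_KEYS
    if bad:
        raise ConfigurationError(f"unknown filter keys: {sorted(bad)}")
    filt = FilterParams(**filt_doc)

    det_doc = doc.get("detector")
    det = DetectorConfig.from_dict(det_doc) if det_doc else None

    cal_doc = doc.get("calibration", {}) or {}
    known_cal = set(CalibrationSpec.__dataclass_fields__)
    bad = set(cal_doc) - known_cal
    if bad:
        raise ConfigurationError(f"unknown calibration keys: {sorted(bad)}")
    cal = CalibrationSpec(**cal_doc)

    return RunConfig(
        filter=filt,
        detector=det,
        calibration=cal,
        seed=int(doc.get("seed", 0)),
        log_level=str(doc.get("log_level", "INFO")),
    )
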