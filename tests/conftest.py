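import numpy as np
import pytest

from szdet import fir
from szdet.signals_io import Recording
from szdet.synthetic import SyntheticSpec, generate

FS = 256.0


@pytest.fixture(scope="session")
def filt256() -> fir.FilterSpec:
    """Default 64th-order low-pass design at 256 Hz, 16-bit quantized."""
    return fir.quantize(fir.design_lowpass(FS), 16)


@pytest.fixture(scope="session")
def filt256_float() -> fir.FilterSpec:
    return fir.design_lowpass(FS)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture()
def small_recording(rng) -> Recording:
    """4-channel, 4-second random recording."""
    return Recording(rng.normal(0, 20, size=(4, int(4 * FS))), fs=FS)


@pytest.fixture(scope="session")
def seizure_recording():
    """8-channel, 5-minute synthetic recording with one strong annotated seizure."""
    spec = SyntheticSpec(
        n_channels=8,
        duration_s=300.0,
        seizures=[
            {"onset_s": 100.0, "duration_s": 60.0, "amplitude_gain": 5.0,
             "recruited_fraction": 0.7}
        ],
        seed=42,
    )
    return generate(spec)
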