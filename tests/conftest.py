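import numpy as np
import pytest

from otloc.beats import extract_window, locate_reference
from otloc.ecg_io import TwelveLeadECG
from otloc.preprocess import denoise_record
from otloc.synth import SynthParams, generate_record


@pytest.fixture(scope="session")
def rvot_record():
    return generate_record(SynthParams(origin="RVOT", seed=1))


@pytest.fixture(scope="session")
def lvot_record():
    return generate_record(SynthParams(origin="LVOT", seed=2))


def _windows(synth_record):
    rec = denoise_record(synth_record.record)
    out = {}
    for bc in ("SR", "PVC"):
        ref = locate_reference(rec, rec.annotation(bc))
        out[bc] = extract_window(rec, ref, bc)
    return out


@pytest.fixture(scope="session")
def rvot_windows(rvot_record):
    return _windows(rvot_record)


@pytest.fixture(scope="session")
def lvot_windows(lvot_record):
    return _windows(lvot_record)


@pytest.fixture()
def zero_record():
    sig = np.zeros((12, 4096))
    return TwelveLeadECG(sig, 2000.0)
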