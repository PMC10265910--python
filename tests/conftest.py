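import numpy as np
import pytest

from gaitdmo import simgait
from gaitdmo.io import ImuRecording, SubjectInfo


@pytest.fixture(scope="session")
def subject():
    return SubjectInfo(leg_length_m=0.9, foot_length_m=0.25)


@pytest.fixture(scope="session")
def noiseless_suite():
    """Noiseless arm of the standard factorial suite (50 recordings)."""
    return simgait.standard_fixture_suite(seed=7, noises=(0.0,))


@pytest.fixture(scope="session")
def full_suite():
    """Full factorial suite including the noisy arms (150 recordings)."""
    return simgait.standard_fixture_suite(seed=7)


@pytest.fixture()
def simple_bout():
    """One noiseless symmetric bout at 100 steps/min, 20 strides."""
    spec = simgait.BoutSpec(start_s=5.0, n_strides=20, cadence_spm=100,
                            stride_length_m=0.9)
    protocol = simgait.SimProtocol(bouts=(spec,), seed=3)
    rec, truth = simgait.generate_recording(protocol)
    return rec, truth[0]


def make_recording(acc_v, acc_ap=None, acc_ml=None, fs=100.0):
    acc_v = np.asarray(acc_v, dtype=float)
    zeros = np.zeros_like(acc_v)
    return ImuRecording(sampling_rate_hz=fs, acc_v=acc_v,
                        acc_ap=zeros if acc_ap is None else np.asarray(acc_ap, float),
                        acc_ml=zeros if acc_ml is None else np.asarray(acc_ml, float))
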