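import numpy as np
import pytest

import aromams as am


def spectral_cosine(spec_a: np.ndarray, spec_b: np.ndarray) -> float:
    """Plain cosine between two (m/z, intensity) arrays on nominal-mass bins.

    Deliberately unweighted — used as an independent similarity oracle for
    comparing extracted spectra against planted truth.
    """
    da = {int(round(m)): float(i) for m, i in spec_a}
    db = {int(round(m)): float(i) for m, i in spec_b}
    keys = sorted(set(da) | set(db))
    va = np.array([da.get(k, 0.0) for k in keys])
    vb = np.array([db.get(k, 0.0) for k in keys])
    return float(va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb)))


@pytest.fixture(scope="session")
def bundled():
    return am.bundled_library()


@pytest.fixture(scope="session")
def scene20():
    return am.make_scene(20, frac_ns=0.4, seed=1)


@pytest.fixture(scope="session")
def rendered20(scene20):
    return am.render(scene20)


@pytest.fixture(scope="session")
def clean_rendered20(scene20):
    return am.render(scene20, noise_sigma=0.0, channel_noise_sigma=0.0)


@pytest.fixture()
def channel_configs():
    return am.default_channel_configs()


def channels_from_traces(traces):
    cfgs = am.default_channel_configs()
    return [(cfgs[det], trace) for det, trace in traces.items()]
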