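import numpy as np
import pytest

from filterdca import patterns, synthetic


@pytest.fixture(scope="session")
def bank9():
    """Small filter bank (k=9) built from sampled class windows."""
    hh = synthetic.sample_class_windows("HH", 300, 9, 11)
    ee = synthetic.sample_class_windows("EE", 300, 9, 12)
    return patterns.build_filters_from_windows({"HH": hh, "EE": ee}, 9, seed=0)


@pytest.fixture(scope="session")
def family():
    """One deterministic synthetic family."""
    return synthetic.generate_family("famX", 42)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
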