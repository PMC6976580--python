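import numpy as np
import pytest

from cwesr.spin_core import FieldConfig, SpinSystemSpec


@pytest.fixture(scope="session")
def spec14() -> SpinSystemSpec:
    return SpinSystemSpec.nitroxide_14n()


@pytest.fixture(scope="session")
def spec15() -> SpinSystemSpec:
    return SpinSystemSpec.nitroxide_15n()


@pytest.fixture(scope="session")
def xband14(spec14) -> FieldConfig:
    return FieldConfig.x_band(spec14.g_iso)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_unit_quaternions(rng, n):
    q = rng.normal(size=(n, 4))
    return q / np.linalg.norm(q, axis=1, keepdims=True)
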