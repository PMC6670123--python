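import warnings

import numpy as np
import pytest

from octarcd.rcd_metric import QuantifyConfig
from octarcd.synthetic_data import PhantomSpec, generate_phantom


@pytest.fixture(autouse=True)
def _quiet_pipeline_warnings():
    # the baseline-disc containment warning fires routinely on phantoms
    # whose FAZ matches the exclusion disc; tests assert it explicitly
    # where it matters
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def std_phantom():
    """A mid-density phantom reused across read-only tests."""
    return generate_phantom(PhantomSpec(seed=3, capillary_target_density=0.44))


@pytest.fixture(scope="session")
def config_512():
    return QuantifyConfig(target_px=512)


@pytest.fixture(scope="session")
def config_1024():
    return QuantifyConfig(target_px=1024)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
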