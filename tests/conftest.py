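import numpy as np
import pytest

from dualreg.pipeline import run_pipeline
from dualreg.simulate import SimConfig, simulate_two_layer


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """Default synthetic bundle (seed 1) plus a finished pipeline run."""
    data = tmp_path_factory.mktemp("bundle")
    out = tmp_path_factory.mktemp("run")
    truth = simulate_two_layer(SimConfig(seed=1), data)
    result = run_pipeline(data, out)
    return {"data": data, "out": out, "truth": truth, "result": result}


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
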