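import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lffconn import SyntheticConfig, make_atlas
from lffconn.pipeline import _preprocess
from lffconn.preprocess import PreprocessSpec
from lffconn.synthetic import simulate_run

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: Coarse grid covering the same 50 x 41 x 20 mm anatomy; cheap enough for
#: per-test cohorts while keeping all four atlas regions and both seeds valid.
TINY_GRID = (24, 24, 6)


@pytest.fixture(scope="session")
def tiny_config() -> SyntheticConfig:
    return SyntheticConfig.reduced(TINY_GRID)


@pytest.fixture(scope="session")
def tiny_atlas(tiny_config):
    return make_atlas(tiny_config.grid_shape, tiny_config.voxel_size_mm)


@pytest.fixture(scope="session")
def preop_run(tiny_config):
    """One preoperative run plus ground truth on the tiny grid."""
    rng = np.random.default_rng(42)
    return simulate_run(tiny_config, "preop", rng, rat_id="rat01")


@pytest.fixture(scope="session")
def preop_preprocessed(preop_run):
    run, _ = preop_run
    return _preprocess(run, PreprocessSpec())


@pytest.fixture(scope="session")
def d1_run(tiny_config):
    rng = np.random.default_rng(43)
    return simulate_run(tiny_config, "d1", rng, rat_id="rat01")


@pytest.fixture(scope="session")
def d1_preprocessed(d1_run):
    run, _ = d1_run
    return _preprocess(run, PreprocessSpec())
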