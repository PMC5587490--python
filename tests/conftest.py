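import warnings

import numpy as np
import pytest

from atlasbias.pipeline import PipelineConfig, run_pipeline
from atlasbias.synthetic import LandscapeConfig, generate_landscape


@pytest.fixture(scope="session")
def small_landscape():
    """A 12x12 synthetic landscape used across modules."""
    return generate_landscape(LandscapeConfig(rows=12, cols=12, seed=5))


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """A moderate full pipeline run on a 24x24 grid (shared, read-only)."""
    outdir = tmp_path_factory.mktemp("bundle")
    cfg = PipelineConfig(
        seed=7,
        outdir=outdir,
        landscape=LandscapeConfig(rows=24, cols=24),
        morans_n_perm=99,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
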