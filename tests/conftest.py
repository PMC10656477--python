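import numpy as np
import pytest
from hypothesis import settings

import elekit.evaluate as ev
import elekit.pipeline as pl

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

PIPELINE_SEED = 11


@pytest.fixture(scope="session")
def pipeline_state(tmp_path_factory):
    """One full synthetic pipeline run at default study conditions."""
    outdir = tmp_path_factory.mktemp("run")
    cfg = pl.RunConfig(outdir=str(outdir), seed=PIPELINE_SEED)
    return pl.run_all(cfg)


@pytest.fixture(scope="session")
def called_to_planted(pipeline_state):
    """Map called ELE cluster id -> planted ELE id (or None)."""
    return {
        r["ele_id"]: ev.match_planted_ele(r["annotated"], pipeline_state.truth)
        for r in pipeline_state.ele_records
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
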