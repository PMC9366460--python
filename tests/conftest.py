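import numpy as np
import pytest

import heliopipe as hp


@pytest.fixture(scope="session")
def default_net():
    return hp.synthetic_data.default_network()


@pytest.fixture(scope="session")
def small_pipeline(tmp_path_factory, default_net):
    """One shared end-to-end run: 60 noncoding loci, 6 diploid individuals."""
    cfg = hp.synthetic_data.SimConfig(n_loci=60, locus_length=(120, 250))
    out = tmp_path_factory.mktemp("pipeline")
    return hp.pipeline.run_pipeline(default_net, cfg, str(out), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
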