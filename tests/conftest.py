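import numpy as np
import pytest

from phytoalloc import synthdata


@pytest.fixture(scope="session")
def protocol():
    return synthdata.FrrProtocol()


@pytest.fixture()
def truth():
    """Noise-free ground truth for the small-diatom HN/180 treatment."""
    return synthdata.make_truth(synthdata.SMALL_DIATOM, "HN", 180.0)


@pytest.fixture(scope="session")
def zero_noise_bundle(tmp_path_factory):
    """Small zero-noise study bundle (1 replicate per treatment), shared."""
    out = tmp_path_factory.mktemp("bundle0")
    cfg = synthdata.default_study_config(
        seed=7, noise=synthdata.NoiseModel.zero(), n_replicates=1
    )
    return synthdata.gen_study(cfg, out)
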