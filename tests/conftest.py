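import pytest

from mtase_architect.motif_scan import load_motif_config, parse_motif_config
from mtase_architect.synthetic_data import synthetic_motif_config


@pytest.fixture(scope="session")
def default_motifs():
    return load_motif_config()


@pytest.fixture(scope="session")
def synthetic_motifs():
    return synthetic_motif_config()
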