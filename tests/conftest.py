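import numpy as np
import pytest

from serpinscope import screen, synth


@pytest.fixture(scope="session")
def hds_dataset():
    """The study-shaped synthetic preset: 110 proteins, 17 planted
    full-length serpins carrying the published P1 residue list."""
    spec = synth.hds_preset(seed=7)
    proteins, _, truth = synth.generate_serpins(spec, with_transcripts=False)
    return spec, proteins, truth


@pytest.fixture(scope="session")
def screened_records(hds_dataset):
    _, proteins, _ = hds_dataset
    return screen.screen_proteins(proteins)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240210)
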