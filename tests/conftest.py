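import numpy as np
import pandas as pd
import pytest

from ribomito import synth


@pytest.fixture(scope="session")
def small_cfg():
    return synth.SynthConfig(seed=11, n_transcripts=300)


@pytest.fixture(scope="session")
def transcriptome(small_cfg):
    return synth.generate_transcriptome(small_cfg)


@pytest.fixture(scope="session")
def polysome_experiment(small_cfg, transcriptome):
    exp, truth = synth.simulate_polysome_experiment(transcriptome, small_cfg)
    return exp, truth


@pytest.fixture(scope="session")
def protein_groups():
    cfg = synth.SynthConfig(seed=21, n_proteins=400)
    return synth.simulate_proteomics(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def null_matrix_3v3(rng):
    """2000-protein two-group matrix with no true differences."""
    cols = ["a_1", "a_2", "a_3", "b_1", "b_2", "b_3"]
    mat = pd.DataFrame(rng.normal(size=(2000, 6)), columns=cols)
    design = {c: c.split("_")[0] for c in cols}
    return mat, design
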