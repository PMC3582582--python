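import numpy as np
import pytest

from betasignal.extraction import Peptide
from betasignal import synthetic


def make_peptide(seq, org="org1", pid=None, cls=None, cterm=True):
    return Peptide(sequence=seq, organism_id=org,
                   protein_id=pid or f"{org}_{seq}",
                   omp_class=cls, is_protein_cterminal=cterm)


@pytest.fixture(scope="session")
def mk():
    return make_peptide


@pytest.fixture(scope="session")
def default_dataset():
    """One draw of the default four-taxon synthetic design (seed 0)."""
    return synthetic.generate(synthetic.default_spec(seed=0))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
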