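import numpy as np
import pytest

from consensustx import synthetic_data as sd


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def small_truth():
    """8 genes (two 0.96-identity isoform pairs), 4 assemblies, 6 samples."""
    truth = sd.make_truth(n_genes=8, n_isoform_pairs=2, seed=11)
    assemblies = sd.generate_assemblies(
        truth, n_assemblies=4, fragmentation_prob=0.3, dropout_prob=0.1, allele_rate=2.0
    )
    abundance = sd.generate_expression(truth, n_samples=6)
    return truth, assemblies, abundance


@pytest.fixture()
def clean_truth():
    """No fragmentation/dropout: every assembly holds every gene full length."""
    truth = sd.make_truth(n_genes=6, n_isoform_pairs=2, seed=7)
    assemblies = sd.generate_assemblies(
        truth, n_assemblies=3, fragmentation_prob=0.0, dropout_prob=0.0, allele_rate=2.0
    )
    abundance = sd.generate_expression(truth, n_samples=5)
    return truth, assemblies, abundance
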