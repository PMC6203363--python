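import numpy as np
import pytest

from mircompare.pipeline import annotate_target_genome
from mircompare.synthetic_data import GeneratorConfig, generate


@pytest.fixture(scope="session")
def dataset():
    """The frozen default synthetic bed (seed=1, ~1 Mb, 20 miRNAs)."""
    return generate(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def annotation_result(dataset):
    """Full homology+fold+compare annotation of the default bed."""
    return annotate_target_genome(
        dataset.genome, dataset.reference, exons=dataset.exons
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
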