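import numpy as np
import pytest

from paralogscope.io import CodingSequence, load_reference_pairs


@pytest.fixture(scope="session")
def reference_pairs():
    """The curated 24-row in-paralog pair table shipped with the package."""
    return load_reference_pairs()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_codon_alignment(rng, n_codons):
    """A random gap-free codon alignment over sense codons."""
    from paralogscope.evolution import CodonAlignment, GENETIC_CODE

    sense = sorted(GENETIC_CODE)
    cols = tuple(
        (sense[i], sense[j])
        for i, j in zip(
            rng.integers(0, len(sense), n_codons),
            rng.integers(0, len(sense), n_codons),
        )
    )
    return CodonAlignment(cols)


def make_cds(gene_id, codons):
    return CodingSequence(gene_id, "".join(codons))
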