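import numpy as np
import pytest

import synmotif as sm


@pytest.fixture(scope="session")
def reference_corpus() -> list[str]:
    """Synthetic CpG-depleted reference CDS corpus (in frame, stop-ended)."""
    return sm.synthetic_reference(n_seqs=40, len_codons=80, rng=2024)


@pytest.fixture(scope="session")
def ref_counts(reference_corpus):
    return sm.count_reference(reference_corpus)


@pytest.fixture(scope="session")
def icm(ref_counts):
    return sm.build_icm(ref_counts)


@pytest.fixture(scope="session")
def dcm(ref_counts):
    return sm.build_dcm(ref_counts)


@pytest.fixture(scope="session")
def uniform_icm():
    """ICM with the uniform distribution over every synonymous set (only
    Met observed in the reference, which is forced anyway)."""
    return sm.build_icm(sm.count_reference(["ATGTAA"]))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
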