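import pytest

from splicedup.motif_classifier import load_motif_models
from splicedup.splice_signals import SpliceSignalModel
from splicedup.synthetic_data import ArchitectureSpec, generate, generate_suite

SUITE_SEED = 20130314


@pytest.fixture(scope="session")
def default_model():
    return SpliceSignalModel.default()


@pytest.fixture(scope="session")
def motif_models():
    return load_motif_models()


@pytest.fixture(scope="session")
def alt3ss_locus():
    return generate(ArchitectureSpec(kind="ALT3SS", seed=7))


@pytest.fixture(scope="session")
def retention_locus():
    return generate(ArchitectureSpec(kind="RETENTION_PAIR", seed=7))


@pytest.fixture(scope="session")
def alt_tss_locus():
    return generate(ArchitectureSpec(kind="ALT_TSS", seed=7))


@pytest.fixture(scope="session")
def wgd_locus():
    return generate(ArchitectureSpec(kind="POST_WGD_PAIR", seed=7))


@pytest.fixture(scope="session")
def small_suite():
    """Two loci per architecture; shared by recovery-flavoured tests."""
    return generate_suite(2, SUITE_SEED)


@pytest.fixture(scope="session")
def acceptance_suite():
    """The full study corpus: ten loci per architecture at consensus signals."""
    return generate_suite(10, SUITE_SEED)
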