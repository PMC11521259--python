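import pytest

from rareburden import synthetic_data as sd
from rareburden import genotype_qc as qc


@pytest.fixture(scope="session")
def tiny_toy():
    return sd.make_fixture("tiny_toy")


@pytest.fixture(scope="session")
def qc_torture():
    return sd.make_fixture("qc_torture")


@pytest.fixture(scope="session")
def sf1_mirror():
    return sd.make_fixture("sf1_mirror")


@pytest.fixture(scope="session")
def sf1_qc(sf1_mirror):
    """sf1_mirror cohort after the QC chain (clean by construction)."""
    cohort, report = qc.apply_qc(sf1_mirror.cohort)
    return cohort, report
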