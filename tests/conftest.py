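import pytest

from haplochron.datasets import load_saimaa_table, saimaa_grouping
from haplochron.seqio import Alignment, SequenceRecord
from haplochron.temporal_stats import TestConfig

TestConfig.__test__ = False  # keep pytest from collecting the config dataclass


@pytest.fixture(scope="session")
def saimaa_table():
    return load_saimaa_table()


@pytest.fixture(scope="session")
def grouping():
    return saimaa_grouping()


def make_alignment(seqs, years=None, **kwargs):
    """Small helper: build an Alignment from raw sequence strings."""
    years = years or [1900 + i for i in range(len(seqs))]
    return Alignment(tuple(
        SequenceRecord.make(f"s{i}", s, years[i], **kwargs)
        for i, s in enumerate(seqs)
    ))
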