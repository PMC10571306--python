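import os

import pytest

from cfmito.quant import AlignmentRecord
from cfmito.synth import ReferenceSet, make_references


@pytest.fixture(scope="session")
def references(tmp_path_factory) -> ReferenceSet:
    """Small two-species reference set shared across tests."""
    d = tmp_path_factory.mktemp("refs")
    return make_references(
        os.path.join(d, "ref.fa"), nuclear_length=50_000, second_species=True, seed=7
    )


def record(
    qname="r",
    flag=0,
    contig="chr1",
    pos=100,
    mapq=60,
    tlen=180,
    tags=None,
) -> AlignmentRecord:
    """Hand-built alignment record with clean defaults."""
    return AlignmentRecord(qname, flag, contig, pos, mapq, tlen, tags or {})


@pytest.fixture
def hand_records():
    """10-record fixture: 2 duplicates, 1 secondary, 1 low-MAPQ, 6 clean
    of which 2 are on chrM."""
    return [
        record("c1", contig="chr1"),
        record("c2", contig="chr1"),
        record("c3", contig="chr1"),
        record("c4", contig="chr1"),
        record("m1", contig="chrM", tlen=120),
        record("m2", contig="chrM", tlen=90),
        record("d1", flag=0x400),
        record("d2", flag=0x400),
        record("s1", flag=0x100),
        record("q1", mapq=10),
    ]
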