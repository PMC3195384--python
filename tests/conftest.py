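import pytest

from drbselect.partition import bundled_partition
from drbselect.seq_io import AlleleSet
from drbselect.synthetic_data import make_fixture_panel


@pytest.fixture
def tiny_panel():
    return make_fixture_panel("tiny")


@pytest.fixture(scope="session")
def exon2_panel():
    return make_fixture_panel("exon2")


@pytest.fixture(scope="session")
def brown_mask():
    return bundled_partition("brown1993-22")


@pytest.fixture
def write_fasta(tmp_path):
    """Helper writing a dict of id->sequence as a FASTA file."""

    def _write(records: dict, name="test.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in records.items():
                fh.write(f">{rid}\n{seq}\n")
        return path

    return _write


@pytest.fixture
def monomorphic_panel():
    seq = "ATGGCTAAACCCGGGTTT"
    return AlleleSet(label="mono", ids=["m1", "m2", "m3"], sequences=[seq] * 3)
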