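import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def worked_example():
    """The four-part abstract vertex graph used in the worked example:
    parts of labelled vertices plus the stated 2d-compatibility sets.

    One listed relation (R-H) appears in only one direction; the
    predicate is the symmetric closure of the listing.
    """
    parts = [list("ABC"), list("ZEFG"), list("HIJKL"), list("MNOQRT")]
    rel = {
        "A": set("ZEGHJMORT"),
        "Z": set("AHJMT"),
        "E": set("A"),
        "G": set("AT"),
        "H": set("AZ"),
        "J": set("AZMT"),
        "M": set("AZJ"),
        "O": set("A"),
        "R": set("AH"),
        "T": set("AZGJ"),
    }

    def compatible(u, v):
        return v in rel.get(u, set()) or u in rel.get(v, set())

    return parts, compatible


def naive_hamming(u, v):
    """Independent character-loop distance used as the test oracle."""
    assert len(u) == len(v)
    count = 0
    for a, b in zip(u, v):
        if a != b:
            count += 1
    return count


@pytest.fixture
def fasta_file(tmp_path):
    def make(records, name="input.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rec_id, seq in records:
                fh.write(f">{rec_id}\n{seq}\n")
        return path

    return make
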