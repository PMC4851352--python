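import numpy as np
import pytest

from mirpost.discovery import CandidateRecord, ReadStack


@pytest.fixture
def rng():
    return np.random.default_rng(20160405)


def make_candidate(
    candidate_id="cand-1",
    score=10.0,
    stacks=(),
    contig="ctg1",
    start=100,
    strand="+",
):
    """A minimal valid candidate; matures at offsets 11 (5p) and 41 (3p)."""
    m5 = "ACGUACGUACGUACGUACGUAC"
    m3 = "UGCAUGCAUGCAUGCAUGCAUG"
    precursor = "GGGGGGGGGGG" + m5 + "AAAAAAAA" + m3 + "CCCCCCCCC"
    return CandidateRecord(
        candidate_id=candidate_id,
        precursor_seq=precursor,
        contig=contig,
        start=start,
        end=start + len(precursor) - 1,
        strand=strand,
        score=score,
        mature5p_seq=m5,
        mature3p_seq=m3,
        stacks=tuple(stacks),
    )


def stack(sample="s1", arm="5p", offset=None, count=10, length=22):
    if offset is None:
        offset = 11 if arm == "5p" else 41
    return ReadStack(sample, arm, offset, length, count)
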