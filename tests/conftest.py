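import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from preyweb.read_processing import Read, SampleSheetEntry


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_seq(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def mutate(seq: str, positions, rng) -> str:
    out = list(seq)
    for i in positions:
        out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


@pytest.fixture
def make_read():
    def _make(
        bases="A" * 200,
        quals=None,
        read_id="r1",
        fwd_index="AAAAAAAA",
        rev_index="CCCCCCCC",
        index_q=35,
    ):
        if quals is None:
            quals = [35] * len(bases)
        return Read(
            read_id=read_id,
            bases=bases,
            quals=tuple(quals),
            fwd_index=fwd_index,
            rev_index=rev_index,
            fwd_index_quals=tuple([index_q] * 8),
            rev_index_quals=tuple([index_q] * 8),
        )

    return _make


@pytest.fixture
def simple_sheet():
    return [
        SampleSheetEntry("s1", "SpiderA", "blockA", "AAAAAAAA", "CCCCCCCC"),
        SampleSheetEntry("s2", "SpiderB", "blockA", "GGGGGGGG", "TTTTTTTT"),
        SampleSheetEntry(
            "nc1", "negative_control", "blockA", "ACACACAC", "TGTGTGTG",
            is_negative_control=True,
        ),
    ]
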