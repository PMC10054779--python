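"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pytest

from lactobin.seqio import SampleDesign, SeqRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_design():
    """One donor, one control and two supplemented cultures at day 14."""
    return [
        SampleDesign("ctrl", "d1", 14, "control"),
        SampleDesign("lac1", "d1", 14, "supplemented", 1),
        SampleDesign("lac2", "d1", 14, "supplemented", 2),
    ]


def make_record(rng, n, rec_id="r", q=38):
    seq = "".join(rng.choice(list("ACGT"), size=n))
    return SeqRecord(rec_id, seq, [q] * n)


@pytest.fixture
def random_seq():
    def _make(rng, n):
        return "".join(rng.choice(list("ACGT"), size=n))

    return _make
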