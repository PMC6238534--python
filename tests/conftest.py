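"""Shared fixtures: raw-read builders and small simulated samples."""

import numpy as np
import pytest

from invtoe import FLANK3_DEFAULT, FLANK5_DEFAULT
from invtoe.process import ProcessedRead


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def raw_read(core, rid="r1", q=37, flank5=FLANK5_DEFAULT, flank3=FLANK3_DEFAULT,
             qual=None):
    """A raw merged read: flank5 + core + flank3 with constant quality."""
    seq = flank5 + core + flank3
    if qual is None:
        qual = chr(q + 33) * len(seq)
    else:
        qual = chr(q + 33) * len(flank5) + qual + chr(q + 33) * len(flank3)
    return rid, seq, qual


def processed(core, rid="r1", q=37, qual=None):
    """A trimmed read with constant (or explicit) quality."""
    return ProcessedRead(rid, core, qual if qual is not None else chr(q + 33) * len(core))


@pytest.fixture
def make_raw():
    return raw_read


@pytest.fixture
def make_processed():
    return processed
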