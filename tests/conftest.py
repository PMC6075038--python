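import numpy as np
import pytest

from pausepier.core import Interval, SignalTrack


def make_track(values, chrom="chrI", strand="+", stranded=True):
    """Single-chromosome track from a literal value list."""
    values = np.asarray(values, dtype=float)
    track = SignalTrack({chrom: values.size}, stranded=stranded)
    track.values(chrom, strand)[:] = values
    return track


@pytest.fixture
def uniform_track():
    return make_track(np.full(2000, 3.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
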