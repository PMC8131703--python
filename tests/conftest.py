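import numpy as np
import pytest

from rtcomp.genome import BinnedTrack, GenomeSpec
from rtcomp import synthgen as sg


@pytest.fixture
def small_genome() -> GenomeSpec:
    """Three chromosomes at 250 kb, enough bins for quantile analyses."""
    return GenomeSpec((("chr1", 200), ("chr2", 150), ("chr3", 120)), 250_000)


@pytest.fixture
def seg(small_genome) -> sg.DomainSegmentation:
    return sg.segment_genome(small_genome, 8.0, seed=42)


@pytest.fixture
def rt_track(seg) -> BinnedTrack:
    return sg.make_rt_track(seg, 0.2, seed=42)


def make_track(values, bin_size=50_000, mask=None, name="t") -> BinnedTrack:
    """Single-chromosome track helper for hand-built examples."""
    values = np.asarray(values, dtype=float)
    n = max(len(values), 10)
    if len(values) < 10:  # pad to the 10-bin genome minimum, masked
        pad = np.full(10 - len(values), np.nan)
        values = np.concatenate([values, pad])
        if mask is not None:
            mask = np.concatenate([np.asarray(mask, bool), np.ones(len(pad), bool)])
    g = GenomeSpec((("chr1", n),), bin_size)
    return BinnedTrack(g, values, mask, name)
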